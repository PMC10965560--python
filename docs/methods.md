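# Methods

This note records the model assumptions, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Synthetic recordings

The generator emulates the structure of a benchmark affective-EEG corpus:
32 subjects × 40 trials × 32 channels (10–20 montage, Geneva order) at
128 Hz, 58 s per trial, one continuous 1–9 VAD rating per trial.  Each
trial is a sum of five band-limited carriers per channel plus white
noise:

    x(t) = Σ_b a[ch,b] · carrier[ch,b](t) + σ · w(t)

Carriers are unit-RMS white noise band-passed with a 4th-order
Butterworth at the band edges — filtered noise rather than sinusoids, so
periodogram band powers have a realistic chi-squared spread instead of
collapsing to a point mass.  On coupled (channel, band) pairs the
amplitude is `baseline + slope · (rating − 5)`, floored at 5% of
baseline; elsewhere it is the baseline.  Units are microvolts with
baseline amplitude 10 (a plausible EEG scale that sits comfortably
inside the ±200 µV EDF physical range, so 16-bit quantization error,
~0.006 µV, is negligible).  The corpus does not state band-power
amplitude distributions, so this scale is the package's own choice,
recorded in `GeneratorConfig`/`EffectSpec` defaults.

Ratings are uniform on [1, 9] per trial unless supplied.  One rating per
trial is broadcast to all analysis windows of that trial (whole-clip
self-assessment), which is what makes the per-window correlation of
Eq.-style `r(l,b,e)` well defined.

Randomness: one master seed; per-subject streams are
`default_rng([seed, subject_index])`, so generation is bitwise
reproducible and subjects are independent of one another and of subject
count.

What the generator does **not** emulate: ocular/muscular artifacts,
volume conduction (channels are independent except through planted
couplings), non-stationarity within a trial, inter-subject amplitude
variability, and rating biases (real raters over-use the middle of the
scale).  Passing tests therefore demonstrate *correctness of the
pipeline's mechanics and recoverability of planted effects*, not
expected accuracy on real EEG.  In particular the headline accuracies of
the final trio on synthetic data say nothing about accuracy on the
restricted benchmark corpus.

## Spectral features

* Windows start at 0, step, 2·step, …; the count is
  `⌊(duration − length)/step⌋ + 1`.  Defaults: 5 s length (the real-time
  emission period), 0.125 s step for selection-stage tables, step =
  length for real-time emulation.
* PSD: a single Hann-tapered periodogram per window (density scaling,
  constant detrend).  Welch averaging is available via
  `welch_nperseg` but is off by default — at 5-s windows the
  periodogram's 0.2 Hz resolution leaves ≥ 17 bins in the narrowest
  band, and band integration already averages bins.
* Band power = Σ PSD bins with `lo ≤ f < hi`, × Δf.  Half-open bins
  prevent double counting at the shared edges 4, 8, 12, 30 Hz.
* Band powers are kept linear by default (`log10` switch provided);
  the ratio indices are always computed from the linear powers.
* Ratio indices floor their denominators at ε = 1e−12 so degenerate
  windows (e.g. an all-zero channel) yield finite values.

## Channel selection

* PCA blocks are centered per subject (no variance scaling): the
  projection assumes data centered at the origin, and per-subject
  centering also removes inter-subject offset differences.  The loading
  sign is fixed so the largest-magnitude weight is positive; the mean
  absolute correlation is sign-invariant, but a fixed sign makes
  artifacts reproducible.  A zero-variance block falls back to an
  arbitrary unit loading with zero scores and a warning.
* Subjects with a constant projected or rating series are excluded from
  the across-subject average with a log message (their correlation is
  undefined); selection fails only if all subjects are degenerate.
* Best band: the band with the largest correlation mass summed over
  lobes and the three VAD components; ties break toward the higher
  band.  The aggregation is global (sum over lobes) rather than
  per-lobe; on the benchmark's published grid both readings pick γ.
* Gini importance: per subject and component, I = 10
  `RandomForestRegressor` fits (squared-error criterion, seeds
  `seed..seed+9`), importances averaged over iterations then subjects.
  Forest size defaults to 100 trees, unlimited depth; desk-scale runs in
  the test-suite and reproduction script use 25 trees (the ranking is
  already stable there, and the importance vectors are normalized either
  way).  Each component's vector sums to 1 by construction; a defensive
  renormalization guards against split-free forests.
* EII = unweighted mean of the three components' importance vectors; its
  sum is 1 by linearity.  Ties in the ranking break alphabetically.

## Evaluation

* Shift-based folds: rotate indices by `φ(fold) = fold · ⌊n/folds⌋`,
  then cut contiguous 60/20/20 blocks.  The validation block is reserved
  for hyperparameter work and unused by default (test-block metrics are
  reported).
* Metrics are computed from explicit one-vs-rest confusion counts;
  macro-F1 is the unweighted mean over classes present in the data.  The
  implementation is cross-checked against scikit-learn in the tests.
* Default hyperparameters: ET/RF 100 trees, kNN k = 5, SVC RBF C = 1,
  XGBoost library defaults.  All configurable; none are tuned.
* Model-comparison runs decimate *training* rows by stride 16 (cost
  control mirroring the original protocol); validation/test rows are
  never decimated.  The final-trio cross-validation
  (`evaluate_final_trio`) retrains feature ranking *inside* each fold so
  selection never sees the test block.
* Sweep winners take the smallest window length / smallest feature count
  among cells whose score ties after rounding to 3 decimals.  The
  feature-count default range is 25–35 with k = 34 as the shipped final
  choice.

## Discretization and emotion map

The published low/mid/high bins (1–3.6, 3.7–6.3, 6.4–9) leave the open
gaps (3.6, 3.7) and (6.3, 6.4) unassigned on a continuous scale.  The
effective cuts default to the gap midpoints 3.65 and 6.35, making the
map total while preserving the stated classes on their stated ranges;
both cuts are configurable.  The 27-entry (A,V,D) → emotion table ships
as a packaged CSV (auditable, checksummed in the tests); 6 entries are
Descartes passions, 17 are named, 10 are "Other".

## Real-time loop

* The replay source implements the iterator contract a live board
  adapter would: fixed-size chunks at the board rate (default 250 Hz,
  Cyton-like; 0.2 s chunks).  Recordings at other rates are resampled on
  replay, exercising the same path as live acquisition.
* Preprocessing per 5-s buffer: polyphase anti-aliased resampling to
  128 Hz, zero-phase (forward–backward) 4th-order Butterworth band-pass
  0.4–45 Hz, then common average reference — the output channel mean is
  zero at every sample.
* Buffers are non-overlapping (one prediction per 5 s); a sliding mode
  is a configuration away but off by default.  A trailing partial buffer
  is dropped with a log message.
* Streaming/offline equivalence is exact by construction *and* verified
  end-to-end: the offline path featurizes the concatenated preprocessed
  buffers through the feature-table builder with 5-s non-overlapping
  windows, so both paths see identical samples and must emit identical
  triples.

## Problem sizes of the shipped validation

The test suite and `scripts/acceptance.py` run three frozen desk-scale
scenarios (see `emorec.presets`):

* **recovery** — 8 subjects × 4 trials × 12 s, eight γ-band couplings
  (slope 2.0, noise 0.3) on the reference channels; 2 s/0.5 s windows;
  RF 25 trees × 10 iterations; repeated over 10 master seeds.
* **strong** — 2 subjects × 30 trials × 10 s, three coupled channels per
  VAD component (slope 2.4, noise 0.1); 2 s/0.25 s windows; the final
  trio is cross-validated over the 8 shifted folds.
* **multi-subject normalization** — 4 subjects, ≥ 2000 windows, for the
  importance-normalization identities.

These sizes were chosen so the full pipeline (generation through
streaming) completes in minutes on one CPU while leaving each stage's
statistics comfortably resolvable; the generator's defaults remain the
full benchmark shape.

## Known limitations

* The PSD estimator of the original implementation is unpublished; a
  plain Hann periodogram is the minimal faithful reading, and Welch is
  offered as an option.  Whether band power should be a bin mean or a
  bin sum is likewise unstated; sum × Δf (a proper integral) is used.
* EDF files are written by a minimal in-package 16-bit writer (1-s data
  records, integer sampling rates and whole-second durations only) and
  read back with MNE's EDF reader.
* Statistical significance testing of per-subject correlations and
  scalp topography rendering are out of scope; channel rankings are
  emitted as tables.
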