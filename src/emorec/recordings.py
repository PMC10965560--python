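"""DEAP-shaped synthetic EEG recordings with planted band-power/rating couplings.

The generator emulates the structure of the benchmark affective-EEG dataset
(32 subjects x 40 one-minute-class trials x 32 channels at 128 Hz, one
continuous 1-9 Valence/Arousal/Dominance rating per trial) while planting a
known, recoverable ground truth: on selected (channel, band) pairs the
amplitude of a band-limited noise carrier depends linearly on a chosen VAD
component of the trial's rating.  Channel selection and classification
stages can then be validated against the planted coupling without any
external data.

Signal model, per trial and channel::

    x(t) = sum_bands a[ch, band] * carrier[ch, band](t) + noise_sd * w(t)

where each carrier is unit-RMS white noise band-passed with a 4th-order
Butterworth filter at the band edges (so PSD estimates have realistic
spread), ``a = baseline_amplitude + slope * (rating - 5)`` on coupled
channels and ``baseline_amplitude`` elsewhere, and ``w`` is white noise.
Amplitudes are in microvolts, O(10) at the default scale.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .montage import CHANNELS_32, validate_channels
from .spectral import BANDS, BandSet


@dataclasses.dataclass(frozen=True)
class TrialRating:
    """Continuous self-assessment ratings of one trial, each on the 1-9 scale."""

    valence: float
    arousal: float
    dominance: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance"):
            v = getattr(self, name)
            if not 1.0 <= v <= 9.0:
                raise ValueError(
                    f"{name} rating {v} outside the continuous 1-9 scale"
                )

    def component(self, name: str) -> float:
        return getattr(self, name)


@dataclasses.dataclass
class RecordingSet:
    """Multi-subject EEG recordings plus per-trial VAD ratings.

    ``signals`` maps (subject, trial) to a (channels, samples) float array in
    microvolts; ``ratings`` maps the same keys to a :class:`TrialRating`.
    """

    subject_ids: list[str]
    channel_names: list[str]
    fs: float
    trial_duration_s: float
    signals: dict[tuple[str, int], np.ndarray]
    ratings: dict[tuple[str, int], TrialRating]

    def __post_init__(self) -> None:
        validate_channels(self.channel_names, context="RecordingSet")
        n_expected = round(self.fs * self.trial_duration_s)
        for key, sig in self.signals.items():
            if sig.shape != (len(self.channel_names), n_expected):
                raise ValueError(
                    f"trial {key}: expected shape "
                    f"({len(self.channel_names)}, {n_expected}), got {sig.shape}"
                )
            if not np.all(np.isfinite(sig)):
                raise ValueError(f"trial {key}: non-finite samples")
            if key not in self.ratings:
                raise ValueError(f"trial {key}: missing rating")

    @property
    def trials_per_subject(self) -> int:
        return len(self.signals) // max(len(self.subject_ids), 1)

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.trial_duration_s)

    def trial_keys(self) -> list[tuple[str, int]]:
        return sorted(self.signals.keys())


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Shape of the synthetic dataset; defaults mirror the benchmark corpus."""

    n_subjects: int = 32
    trials_per_subject: int = 40
    channel_names: tuple[str, ...] = CHANNELS_32
    fs: float = 128.0
    trial_duration_s: float = 58.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial")
        if self.fs <= 0 or self.trial_duration_s <= 0:
            raise ValueError("fs and trial_duration_s must be positive")
        validate_channels(self.channel_names, context="GeneratorConfig")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Planted couplings between band amplitude and VAD components.

    Each coupling is (channel, band, vad_component, slope): the carrier
    amplitude of that channel/band becomes
    ``baseline_amplitude + slope * (rating_component - 5)``.  Slopes up to
    ``baseline_amplitude / 4`` keep amplitudes positive over the whole 1-9
    rating range; larger slopes are clipped at a small positive floor.
    """

    couplings: tuple[tuple[str, str, str, float], ...] = ()
    noise_sd: float = 1.0
    baseline_amplitude: float = 10.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ch, band, comp, slope in self.couplings:
            if ch not in CHANNELS_32:
                raise ValueError(f"coupling references unknown channel {ch!r}")
            if band not in BANDS.names:
                raise ValueError(
                    f"coupling references unknown band {band!r}; "
                    f"valid: {list(BANDS.names)}"
                )
            if comp not in ("valence", "arousal", "dominance"):
                raise ValueError(f"unknown VAD component {comp!r}")
            if not np.isfinite(slope):
                raise ValueError("coupling slope must be finite")

    def amplitude(self, channel: str, band: str, rating: TrialRating) -> float:
        a = self.baseline_amplitude
        for ch, b, comp, slope in self.couplings:
            if ch == channel and b == band:
                a += slope * (rating.component(comp) - 5.0)
        return max(a, 0.05 * self.baseline_amplitude)


def _band_sos(band, fs: float):
    lo = max(band.lo_hz, 1e-3)
    hi = min(band.hi_hz, 0.499 * fs)
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def generate_recordings(
    config: GeneratorConfig = GeneratorConfig(),
    effect: EffectSpec = EffectSpec(),
    seed: int = 0,
    *,
    bands: BandSet = BANDS,
    ratings: Mapping[tuple[str, int], TrialRating] | None = None,
) -> RecordingSet:
    """Generate a synthetic recording set; deterministic for a fixed seed.

    Per-subject random streams are derived from the master seed with fixed
    spawn offsets (``default_rng([seed, subject_index])``), so subjects are
    reproducible independently of one another.  Ratings are drawn uniformly
    on [1, 9] per trial unless supplied via ``ratings``.
    """
    n_samp = round(config.fs * config.trial_duration_s)
    sos = {b.name: _band_sos(b, config.fs) for b in bands}
    subject_ids = [f"s{j + 1:02d}" for j in range(config.n_subjects)]
    signals: dict[tuple[str, int], np.ndarray] = {}
    out_ratings: dict[tuple[str, int], TrialRating] = {}

    for j, subject in enumerate(subject_ids):
        rng = np.random.default_rng([seed, j])
        for trial in range(config.trials_per_subject):
            key = (subject, trial)
            if ratings is not None and key in ratings:
                rating = ratings[key]
                rng.uniform(1.0, 9.0, size=3)  # keep stream position fixed
            else:
                v, a, d = rng.uniform(1.0, 9.0, size=3)
                rating = TrialRating(valence=v, arousal=a, dominance=d)
            out_ratings[key] = rating

            sig = np.zeros((len(config.channel_names), n_samp))
            for c, ch in enumerate(config.channel_names):
                for b in bands:
                    carrier = rng.standard_normal(n_samp)
                    carrier = sps.sosfiltfilt(sos[b.name], carrier)
                    rms = np.sqrt(np.mean(carrier**2))
                    if rms > 0:
                        carrier /= rms
                    sig[c] += effect.amplitude(ch, b.name, rating) * carrier
                if effect.noise_sd > 0:
                    sig[c] += effect.noise_sd * rng.standard_normal(n_samp)
            signals[key] = sig

    return RecordingSet(
        subject_ids=subject_ids,
        channel_names=list(config.channel_names),
        fs=config.fs,
        trial_duration_s=config.trial_duration_s,
        signals=signals,
        ratings=out_ratings,
    )
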