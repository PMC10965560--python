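"""Real-time emotion recognition loop over a replayed 8-channel stream.

The loop emulates a portable dry-electrode headset: a chunked source
streams the 8-channel montage at the board rate; every 5 seconds the
accumulated buffer is preprocessed (anti-aliased resampling to 128 Hz,
zero-phase 4th-order Butterworth band-pass 0.4-45 Hz, common average
reference), featurized (5 band powers + 4 ratio indices per channel),
subset to each VAD model's stored feature list, classified, and the
discrete (A, V, D) triple is mapped to its named emotion.  Hardware
acquisition is replaced by a replay source implementing the same iterator
contract a live board adapter would.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emotion_map import triple_to_emotion
from .montage import OPTIMAL_CHANNELS_8
from .spectral import BANDS, INDEX_NAMES, band_powers, band_ratios, compute_psd

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class StreamConfig:
    """Stream geometry and preprocessing parameters."""

    montage: tuple[str, ...] = OPTIMAL_CHANNELS_8
    source_fs: float = 250.0  # board-like acquisition rate
    target_fs: float = 128.0
    buffer_s: float = 5.0
    emit_period_s: float = 5.0
    chunk_s: float = 0.2
    bandpass_hz: tuple[float, float] = (0.4, 45.0)

    def __post_init__(self) -> None:
        if len(self.montage) != 8:
            raise ValueError("montage must list exactly 8 channels")
        if self.target_fs > self.source_fs:
            raise ValueError("target_fs must not exceed source_fs")
        if abs(self.buffer_s * self.target_fs - round(self.buffer_s * self.target_fs)) > 1e-9:
            raise ValueError("buffer_s * target_fs must be an integer sample count")

    @property
    def buffer_samples_source(self) -> int:
        return int(round(self.buffer_s * self.source_fs))

    @property
    def buffer_samples_target(self) -> int:
        return int(round(self.buffer_s * self.target_fs))


@dataclasses.dataclass(frozen=True)
class Prediction:
    """One emitted VAD estimate with its mapped emotion."""

    timestamp_s: float
    vad_classes: tuple[int, int, int]  # (arousal, valence, dominance)
    emotion: str
    descartes: bool
    features: pd.Series | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "t": self.timestamp_s,
                "vad": list(self.vad_classes),
                "emotion": self.emotion,
                "descartes": self.descartes,
            }
        )


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if abs(fs_in - fs_out) < 1e-9:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def stream_from_recording(
    rs, subject: str, trial: int, cfg: StreamConfig = StreamConfig()
) -> Iterator[np.ndarray]:
    """Replay one trial's montage channels as fixed-size chunks at source_fs.

    The recording is resampled to the board rate first (exercising the same
    resampling path a live board would feed), then yielded in
    ``chunk_s``-second chunks; total samples are conserved.
    """
    missing = [c for c in cfg.montage if c not in rs.channel_names]
    if missing:
        raise ValueError(f"montage channel(s) {missing} absent from recording")
    idx = [rs.channel_names.index(c) for c in cfg.montage]
    sig = _resample(rs.signals[(subject, trial)][idx], rs.fs, cfg.source_fs)
    chunk = int(round(cfg.chunk_s * cfg.source_fs))
    for start in range(0, sig.shape[1] - chunk + 1, chunk):
        yield sig[:, start : start + chunk]


def preprocess_buffer(
    buffer: np.ndarray, cfg: StreamConfig = StreamConfig()
) -> np.ndarray:
    """Resample to target_fs, zero-phase band-pass, common average reference.

    Output across-channel mean is zero at every sample (CAR identity).
    """
    buffer = np.asarray(buffer, dtype=float)
    lo, hi = cfg.bandpass_hz
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=cfg.target_fs, output="sos")
    # forward-backward filtering needs a few filter lengths of signal
    if buffer.shape[1] < 0.5 * cfg.source_fs:
        raise ValueError("buffer shorter than the filter warm-up (0.5 s)")
    x = _resample(buffer, cfg.source_fs, cfg.target_fs)
    x = sps.sosfiltfilt(sos, x, axis=-1)
    x = x - x.mean(axis=0, keepdims=True)
    return x


def _buffer_features(buffer: np.ndarray, fs: float, montage: Sequence[str]) -> pd.Series:
    """The 72 candidate features of one preprocessed buffer, named like the
    offline feature-table columns."""
    freqs, psd = compute_psd(buffer, fs)
    powers = band_powers(psd, freqs, BANDS)  # (n_ch, 5)
    ratios = band_ratios(powers)  # (n_ch, 4)
    values: dict[str, float] = {}
    for j, ch in enumerate(montage):
        for k, b in enumerate(BANDS.names):
            values[f"{ch}_{b}"] = powers[j, k]
    for j, ch in enumerate(montage):
        for k, ix in enumerate(INDEX_NAMES):
            values[f"{ch}_{ix}"] = ratios[j, k]
    return pd.Series(values)


def predict_buffer(
    buffer: np.ndarray,
    models,
    cfg: StreamConfig = StreamConfig(),
    timestamp_s: float = 0.0,
) -> Prediction:
    """Featurize one preprocessed 5-s buffer and classify it.

    ``models`` is a fitted :class:`~emorec.evaluate.VADClassifier`; each
    component's classifier sees only its stored feature list.  The feature
    set available here must cover those lists, otherwise the montage or
    window settings disagree with the model bundle and the call refuses.
    """
    expected = cfg.buffer_samples_target
    if buffer.shape != (len(cfg.montage), expected):
        raise ValueError(
            f"expected preprocessed buffer of shape "
            f"({len(cfg.montage)}, {expected}), got {buffer.shape}"
        )
    feats = _buffer_features(buffer, cfg.target_fs, cfg.montage)
    for comp, cols in models.feature_lists_.items():
        unknown = [c for c in cols if c not in feats.index]
        if unknown:
            raise ValueError(
                f"model/{comp} expects feature(s) {unknown} the stream cannot "
                "compute; montage or window settings mismatch the bundle"
            )
    row = feats.to_frame().T
    triple = tuple(int(v) for v in models.predict_triples(row)[0])
    entry = triple_to_emotion(triple)
    return Prediction(
        timestamp_s=timestamp_s,
        vad_classes=triple,
        emotion=entry.emotion,
        descartes=entry.descartes,
        features=feats,
    )


def run_stream(
    source: Iterable[np.ndarray],
    models,
    cfg: StreamConfig = StreamConfig(),
    sink=None,
) -> list[Prediction]:
    """Consume a chunk source, emit one prediction per 5 s of stream time.

    ``sink`` may be a callable or a writable text stream (JSON-lines).  A
    trailing partial buffer is dropped with a log message.  Deterministic
    on replayed input.
    """
    need = cfg.buffer_samples_source
    held: list[np.ndarray] = []
    held_n = 0
    t = 0.0
    out: list[Prediction] = []
    for chunk in source:
        held.append(np.asarray(chunk, dtype=float))
        held_n += chunk.shape[-1]
        while held_n >= need:
            buf = np.concatenate(held, axis=-1)
            window, rest = buf[:, :need], buf[:, need:]
            held = [rest] if rest.size else []
            held_n = rest.shape[-1] if rest.size else 0
            t += cfg.emit_period_s
            pred = predict_buffer(preprocess_buffer(window, cfg), models, cfg, t)
            out.append(pred)
            if callable(sink):
                sink(pred)
            elif sink is not None:
                sink.write(pred.to_json() + "\n")
    if held_n:
        logger.info("dropping trailing partial buffer of %d samples", held_n)
    return out


def offline_predictions(
    rs, subject: str, trial: int, models, cfg: StreamConfig = StreamConfig()
) -> list[Prediction]:
    """Offline reference path for the same windows the stream would see.

    The trial is replayed through the identical resampling/preprocessing,
    but featurization goes through the offline feature-table builder
    (:func:`~emorec.spectral.build_feature_table`) on the concatenated
    preprocessed buffers with non-overlapping windows, and classification
    through the same fitted trio.  Used to verify streaming/offline
    equivalence.
    """
    from .recordings import RecordingSet, TrialRating
    from .spectral import WindowSpec, build_feature_table

    idx = [rs.channel_names.index(c) for c in cfg.montage]
    sig = _resample(rs.signals[(subject, trial)][idx], rs.fs, cfg.source_fs)
    need = cfg.buffer_samples_source
    n_buffers = sig.shape[1] // need
    if n_buffers == 0:
        return []
    blocks = [
        preprocess_buffer(sig[:, i * need : (i + 1) * need], cfg)
        for i in range(n_buffers)
    ]
    concat = np.concatenate(blocks, axis=-1)
    one = RecordingSet(
        subject_ids=[subject],
        channel_names=list(cfg.montage),
        fs=cfg.target_fs,
        trial_duration_s=concat.shape[1] / cfg.target_fs,
        signals={(subject, 0): concat},
        ratings={(subject, 0): rs.ratings[(subject, trial)]},
    )
    table = build_feature_table(
        one, WindowSpec(length_s=cfg.buffer_s, step_s=cfg.buffer_s)
    )
    triples = models.predict_triples(table)
    preds = []
    for i, triple in enumerate(triples):
        triple = tuple(int(v) for v in triple)
        entry = triple_to_emotion(triple)
        preds.append(
            Prediction(
                timestamp_s=(i + 1) * cfg.emit_period_s,
                vad_classes=triple,
                emotion=entry.emotion,
                descartes=entry.descartes,
            )
        )
    return preds
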