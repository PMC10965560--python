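"""Spectral feature engineering: windowing, PSD, band powers and band ratios.

Trials are segmented into (possibly overlapping) analysis windows; each
window's one-sided power spectral density is estimated with a Hann-windowed
periodogram (Welch averaging optional); the PSD is integrated over the five
canonical EEG bands; and four per-channel band-ratio indices are derived.
The result is a tidy feature table, one row per analysis window, that every
downstream stage (channel selection, classification, streaming) consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .montage import validate_channels

#: Denominator floor for the band-ratio indices; keeps ratios finite on
#: degenerate (e.g. all-zero) windows.
RATIO_FLOOR = 1e-12


@dataclasses.dataclass(frozen=True)
class Band:
    name: str
    lo_hz: float
    hi_hz: float


@dataclasses.dataclass(frozen=True)
class BandSet:
    """The five canonical EEG bands, ordered by lower edge.

    Band membership of a PSD bin uses the half-open convention
    ``lo <= f < hi`` so shared edges (4, 8, 12, 30 Hz) are never counted
    twice.
    """

    bands: tuple[Band, ...] = (
        Band("delta", 0.5, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 12.0),
        Band("beta", 12.0, 30.0),
        Band("gamma", 30.0, 45.0),
    )

    def __post_init__(self) -> None:
        los = [b.lo_hz for b in self.bands]
        if los != sorted(los):
            raise ValueError("bands must be ordered by lower edge")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lo_hz < a.hi_hz:
                raise ValueError(f"bands {a.name} and {b.name} overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


BANDS = BandSet()

#: Band-ratio indices computed per channel from that channel's band powers.
INDEX_NAMES: tuple[str, ...] = ("relaxation", "excitement", "fatigue", "engagement")


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry in seconds.

    The default 5 s length matches the real-time emission period; the
    0.125 s step is the dense stride used for the channel-selection tables.
    """

    length_s: float = 5.0
    step_s: float = 0.125

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.length_s:
            raise ValueError("require 0 < step_s <= length_s")

    def n_windows(self, duration_s: float) -> int:
        """Number of windows that fit a trial of the given duration."""
        if duration_s < self.length_s:
            return 0
        return int(np.floor((duration_s - self.length_s) / self.step_s + 1e-9)) + 1


def segment_windows(
    trial_signal: np.ndarray, fs: float, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a (channels, samples) trial into overlapping analysis windows.

    Returns
    -------
    windows : ndarray, shape (n_windows, channels, window_samples)
        Views into the input; windows start at 0, step, 2*step, ...
    starts_s : ndarray, shape (n_windows,)
        Start time of each window in seconds.
    """
    trial_signal = np.asarray(trial_signal)
    if trial_signal.ndim != 2:
        raise ValueError("trial_signal must be (channels, samples)")
    wlen = int(round(fs * spec.length_s))
    step = int(round(fs * spec.step_s))
    n = trial_signal.shape[1]
    if n < wlen:
        raise ValueError(
            f"trial of {n} samples is shorter than one {wlen}-sample window"
        )
    sw = sliding_window_view(trial_signal, wlen, axis=1)  # (ch, n-wlen+1, wlen)
    windows = sw[:, ::step, :].swapaxes(0, 1)
    starts_s = np.arange(windows.shape[0]) * step / fs
    return windows, starts_s


def compute_psd(
    window: np.ndarray,
    fs: float,
    *,
    taper: str = "hann",
    welch_nperseg: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD per channel of one analysis window.

    A single Hann-tapered periodogram per window by default; pass
    ``welch_nperseg`` to average shorter segments instead (Welch).  Density
    scaling is used, so the integral of the PSD over frequency equals the
    taper-weighted mean square of the (detrended) signal.

    Returns ``(freqs, psd)`` with ``psd.shape[-1] == len(freqs)``.
    """
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite samples")
    if window.shape[-1] < 2:
        raise ValueError("window must contain at least 2 samples")
    if welch_nperseg is not None:
        return sps.welch(window, fs=fs, window=taper, nperseg=welch_nperseg, axis=-1)
    return sps.periodogram(window, fs=fs, window=taper, axis=-1)


def band_powers(
    psd: np.ndarray, freqs: np.ndarray, bands: BandSet = BANDS
) -> np.ndarray:
    """Integrate the PSD over each band: sum of bins with lo <= f < hi, times df.

    Works on any leading shape; the last axis of ``psd`` indexes frequency.
    """
    freqs = np.asarray(freqs)
    psd = np.asarray(psd)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    nyquist = freqs[-1]
    too_high = [b.name for b in bands if b.hi_hz > nyquist + df / 2]
    if too_high:
        raise ValueError(
            f"band(s) {too_high} exceed the Nyquist frequency {nyquist:g} Hz"
        )
    out = np.empty(psd.shape[:-1] + (len(bands),))
    for j, b in enumerate(bands):
        mask = (freqs >= b.lo_hz) & (freqs < b.hi_hz)
        out[..., j] = psd[..., mask].sum(axis=-1) * df
    return out


def band_ratios(powers: np.ndarray, floor: float = RATIO_FLOOR) -> np.ndarray:
    """Four band-ratio indices from the five band powers of one channel.

    relaxation = theta/delta, excitement = beta/alpha, fatigue = alpha/theta,
    engagement = beta/(theta+alpha).  Denominators are floored at ``floor``.
    Accepts any leading shape with the last axis of length 5
    (delta, theta, alpha, beta, gamma).
    """
    p = np.asarray(powers, dtype=float)
    if p.shape[-1] != 5:
        raise ValueError("expected 5 band powers (delta..gamma) on the last axis")
    if np.any(p < 0):
        raise ValueError("band powers must be nonnegative")
    delta, theta, alpha, beta = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    out = np.stack(
        [
            theta / np.maximum(delta, floor),
            beta / np.maximum(alpha, floor),
            alpha / np.maximum(theta, floor),
            beta / np.maximum(theta + alpha, floor),
        ],
        axis=-1,
    )
    return out


def feature_columns(montage: Sequence[str], bands: BandSet = BANDS) -> list[str]:
    """Feature column names: all ``<ch>_<band>`` then all ``<ch>_<index>``."""
    cols = [f"{ch}_{b}" for ch in montage for b in bands.names]
    cols += [f"{ch}_{ix}" for ch in montage for ix in INDEX_NAMES]
    return cols


def build_feature_table(
    rs,
    spec: WindowSpec = WindowSpec(),
    bands: BandSet = BANDS,
    montage: Sequence[str] | None = None,
    rule=None,
    *,
    log10: bool = False,
    welch_nperseg: int | None = None,
) -> pd.DataFrame:
    """Featurize every trial of a recording set into one tidy table.

    One row per (subject, trial, window); columns are the per-channel band
    powers and band-ratio indices, plus the continuous VAD ratings broadcast
    from the trial and their discrete classes.

    Parameters
    ----------
    rs : RecordingSet
    spec : WindowSpec
        Window length and step.
    montage : sequence of channel names, optional
        Subset of channels to featurize (default: all channels of ``rs``).
    rule : DiscretizationRule, optional
        Thresholds for the discrete VAD classes.
    log10 : bool
        Apply log10 to band powers (indices are computed from the raw
        powers either way).
    """
    from .emotion_map import DiscretizationRule, discretize_vad

    if rule is None:
        rule = DiscretizationRule()
    if montage is None:
        montage = list(rs.channel_names)
    else:
        montage = list(montage)
        missing = [c for c in montage if c not in rs.channel_names]
        if missing:
            raise ValueError(
                f"montage channel(s) {missing} not in recording; valid names: "
                f"{list(rs.channel_names)}"
            )
    ch_idx = [rs.channel_names.index(c) for c in montage]

    frames = []
    for (subject, trial), sig in rs.signals.items():
        windows, starts = segment_windows(sig[ch_idx], rs.fs, spec)
        freqs, psd = compute_psd(windows, rs.fs, welch_nperseg=welch_nperseg)
        powers = band_powers(psd, freqs, bands)  # (n_win, n_ch, 5)
        ratios = band_ratios(powers)  # (n_win, n_ch, 4)
        if log10:
            powers = np.log10(np.maximum(powers, RATIO_FLOOR))
        n_win = windows.shape[0]
        data = {
            "subject": np.repeat(subject, n_win),
            "trial": np.repeat(trial, n_win),
            "window_index": np.arange(n_win),
            "start_time_s": starts,
        }
        for j, ch in enumerate(montage):
            for k, b in enumerate(bands.names):
                data[f"{ch}_{b}"] = powers[:, j, k]
        for j, ch in enumerate(montage):
            for k, ix in enumerate(INDEX_NAMES):
                data[f"{ch}_{ix}"] = ratios[:, j, k]
        r = rs.ratings[(subject, trial)]
        for comp, val in (
            ("valence", r.valence),
            ("arousal", r.arousal),
            ("dominance", r.dominance),
        ):
            data[comp] = np.repeat(float(val), n_win)
            data[f"{comp}_class"] = np.repeat(discretize_vad(val, rule), n_win)
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True)
    return table
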