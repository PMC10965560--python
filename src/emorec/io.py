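"""EDF persistence of recording sets, with a CSV ratings sidecar.

Signals are written as standard EDF (16-bit, one file per subject/trial,
1-second data records, physical range +/-200 microvolts) and read back with
MNE's EDF reader, which serves as an independent check on the writer.  The
per-trial VAD ratings travel in a ``ratings.csv`` sidecar with header
``subject,trial,valence,arousal,dominance``.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_32
from .recordings import RecordingSet, TrialRating

PHYS_MIN, PHYS_MAX = -200.0, 200.0  # microvolts
DIG_MIN, DIG_MAX = -32768, 32767

#: Quantization step of the 16-bit encoding over the physical range.
QUANT_STEP = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _write_edf_file(path: Path, channel_names, fs: float, data: np.ndarray) -> None:
    """Write one (channels, samples) array as EDF with 1-second records."""
    n_ch, n_samp = data.shape
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n_samp % spr != 0:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_rec = n_samp // spr

    header = b""
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)  # local patient id
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("", 44)
    header += _ascii(n_rec, 8)
    header += _ascii(1, 8)  # record duration, seconds
    header += _ascii(n_ch, 4)

    for field, width in (
        (channel_names, 16),
        (["" for _ in channel_names], 80),
        (["uV" for _ in channel_names], 8),
        ([f"{PHYS_MIN:g}" for _ in channel_names], 8),
        ([f"{PHYS_MAX:g}" for _ in channel_names], 8),
        ([str(DIG_MIN) for _ in channel_names], 8),
        ([str(DIG_MAX) for _ in channel_names], 8),
        (["" for _ in channel_names], 80),
        ([str(spr) for _ in channel_names], 8),
        (["" for _ in channel_names], 32),
    ):
        for v in field:
            header += _ascii(v, width)

    gain = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    clipped = np.clip(data, PHYS_MIN, PHYS_MAX)
    digital = np.round((clipped - PHYS_MIN) * gain + DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within the record


def _trial_filename(subject: str, trial: int) -> str:
    return f"{subject}_t{trial:02d}.edf"


def write_recording_edf(rs: RecordingSet, path) -> None:
    """Write a recording set as one EDF per trial plus ``ratings.csv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject, trial), sig in sorted(rs.signals.items()):
        _write_edf_file(
            path / _trial_filename(subject, trial), rs.channel_names, rs.fs, sig
        )
        r = rs.ratings[(subject, trial)]
        rows.append(
            {
                "subject": subject,
                "trial": trial,
                "valence": r.valence,
                "arousal": r.arousal,
                "dominance": r.dominance,
            }
        )
    pd.DataFrame(rows).to_csv(path / "ratings.csv", index=False)


def read_recording_edf(path, expected_channels=CHANNELS_32) -> RecordingSet:
    """Read a directory written by :func:`write_recording_edf`.

    Raises
    ------
    FileNotFoundError
        If the ``ratings.csv`` sidecar is absent (signals without labels).
    ValueError
        If a file's channel labels do not match ``expected_channels`` (the
        missing labels are named), or a sidecar rating is outside [1, 9].
    """
    import mne

    path = Path(path)
    sidecar = path / "ratings.csv"
    if not sidecar.exists():
        raise FileNotFoundError(
            f"labelled-data error: ratings sidecar {sidecar} not found; "
            "EDF signals alone carry no VAD labels"
        )
    table = pd.read_csv(sidecar)

    signals: dict[tuple[str, int], np.ndarray] = {}
    ratings: dict[tuple[str, int], TrialRating] = {}
    fs = None
    n_samp = None
    channel_names: list[str] | None = None
    for row in table.itertuples():
        subject, trial = str(row.subject), int(row.trial)
        try:
            ratings[(subject, trial)] = TrialRating(
                valence=float(row.valence),
                arousal=float(row.arousal),
                dominance=float(row.dominance),
            )
        except ValueError as exc:
            raise ValueError(f"sidecar row ({subject}, {trial}): {exc}") from exc
        raw = mne.io.read_raw_edf(
            path / _trial_filename(subject, trial), preload=True, verbose="error"
        )
        missing = [c for c in expected_channels if c not in raw.ch_names]
        if missing:
            raise ValueError(
                f"{_trial_filename(subject, trial)}: channel label mismatch; "
                f"missing {missing}"
            )
        if channel_names is None:
            channel_names = list(raw.ch_names)
            fs = float(raw.info["sfreq"])
        signals[(subject, trial)] = raw.get_data(picks=channel_names) * 1e6
        n_samp = signals[(subject, trial)].shape[1]

    assert fs is not None and n_samp is not None and channel_names is not None
    subject_ids = sorted({s for s, _ in signals})
    return RecordingSet(
        subject_ids=subject_ids,
        channel_names=channel_names,
        fs=fs,
        trial_duration_s=n_samp / fs,
        signals=signals,
        ratings=ratings,
    )
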