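"""Discretization of continuous VAD ratings and the 27-cell emotion map.

Continuous 1-9 self-assessment ratings of Valence, Arousal and Dominance are
discretized to three levels {-1, 0, 1} (low / medium / high) and the
resulting (Arousal, Valence, Dominance) triple is looked up in a 27-entry
table of named emotions.  Six of the entries are Descartes' fundamental
passions: Admiration, Love, Hate, Desire, Joy and Sadness.

The published bins (low 1-3.6, medium 3.7-6.3, high 6.4-9) leave the open
intervals (3.6, 3.7) and (6.3, 6.4) unassigned on a continuous scale; the
effective thresholds default to the bin midpoints 3.65 and 6.35 so the
mapping is total, and are configurable.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

#: Descartes' six fundamental passions.
DESCARTES_PASSIONS = frozenset(
    {"Admiration", "Love", "Hate", "Desire", "Joy", "Sadness"}
)


@dataclasses.dataclass(frozen=True)
class DiscretizationRule:
    """Three-level binning of a 1-9 rating.

    ``low_upper``..``high_lower`` are the published bin edges; ``t1`` and
    ``t2`` are the effective cut points actually applied to continuous
    input (default: midpoints of the unassigned gaps).
    """

    low_upper: float = 3.6
    mid_lower: float = 3.7
    mid_upper: float = 6.3
    high_lower: float = 6.4
    t1: float | None = None
    t2: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.low_upper < self.mid_lower <= self.mid_upper < self.high_lower <= 9):
            raise ValueError("bin edges must satisfy 1 <= low < mid <= mid < high <= 9")
        t1, t2 = self.cuts
        if not (self.low_upper < t1 <= self.mid_lower):
            raise ValueError("t1 must lie in (low_upper, mid_lower]")
        if not (self.mid_upper < t2 <= self.high_lower):
            raise ValueError("t2 must lie in (mid_upper, high_lower]")

    @property
    def cuts(self) -> tuple[float, float]:
        t1 = round((self.low_upper + self.mid_lower) / 2, 9) if self.t1 is None else self.t1
        t2 = round((self.mid_upper + self.high_lower) / 2, 9) if self.t2 is None else self.t2
        return t1, t2


@dataclasses.dataclass(frozen=True)
class EmotionMapEntry:
    triple: tuple[int, int, int]  # (arousal, valence, dominance)
    emotion: str
    descartes: bool


def discretize_vad(rating, rule: DiscretizationRule | None = None):
    """Map rating(s) in [1, 9] to class(es) in {-1, 0, 1}.

    rating < t1 -> -1; t1 <= rating < t2 -> 0; rating >= t2 -> 1.
    Scalar in, scalar (int) out; array in, int array out.
    """
    if rule is None:
        rule = DiscretizationRule()
    r = np.asarray(rating, dtype=float)
    if np.any(r < 1) or np.any(r > 9):
        raise ValueError(f"rating {rating} outside the 1-9 scale")
    t1, t2 = rule.cuts
    out = np.where(r < t1, -1, np.where(r < t2, 0, 1))
    if np.isscalar(rating) or out.ndim == 0:
        return int(out)
    return out.astype(int)


def _load_table() -> pd.DataFrame:
    with resources.files("emorec").joinpath("data/emotion_map.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


_TABLE: pd.DataFrame | None = None
_LOOKUP: dict[tuple[int, int, int], EmotionMapEntry] | None = None


def emotion_inventory() -> list[EmotionMapEntry]:
    """All 27 entries of the packaged emotion table, in table order."""
    global _TABLE, _LOOKUP
    if _TABLE is None:
        _TABLE = _load_table()
        entries = [
            EmotionMapEntry(
                (int(row.arousal), int(row.valence), int(row.dominance)),
                str(row.emotion),
                bool(row.descartes),
            )
            for row in _TABLE.itertuples()
        ]
        _LOOKUP = {e.triple: e for e in entries}
        if len(_LOOKUP) != 27:
            raise RuntimeError("packaged emotion map must have 27 unique triples")
    return [_LOOKUP[e] for e in _iter_table_order()]


def _iter_table_order():
    assert _TABLE is not None
    for row in _TABLE.itertuples():
        yield (int(row.arousal), int(row.valence), int(row.dominance))


def triple_to_emotion(triple) -> EmotionMapEntry:
    """Look up the named emotion for an (arousal, valence, dominance) triple."""
    a, v, d = (int(x) for x in triple)
    for x in (a, v, d):
        if x not in (-1, 0, 1):
            raise ValueError(f"triple components must be in {{-1,0,1}}, got {triple}")
    emotion_inventory()  # ensure loaded
    assert _LOOKUP is not None
    return _LOOKUP[(a, v, d)]


def rating_to_emotion(
    valence: float, arousal: float, dominance: float,
    rule: DiscretizationRule | None = None,
) -> EmotionMapEntry:
    """Convenience: discretize three continuous ratings and map them."""
    triple = (
        discretize_vad(arousal, rule),
        discretize_vad(valence, rule),
        discretize_vad(dominance, rule),
    )
    return triple_to_emotion(triple)
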