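"""Channel selection: lobe-wise PCA, mean absolute correlation, Gini importance
and the Emotion Importance Index (EII).

The procedure reduces 32 channels x 5 bands of band-power features to a
ranked channel list in four steps:

1. per subject, lobe and band, project the member channels' band powers onto
   the first principal component (SVD of the column-centered matrix);
2. per (lobe, band, VAD component), compute the Pearson correlation between
   the projected series and the broadcast continuous ratings for each
   subject, take absolute values, and average across subjects;
3. identify the best band (largest correlation mass summed over lobes and
   components), then fit random-forest *regressors* (MSE criterion) of each
   continuous VAD component on that band's 32 channel powers, averaging
   impurity-based Gini importances over random initializations and subjects
   -- each component's importance vector sums to 1;
4. average the three components' importances into the EII and keep the
   top-k channels (k = 8 for the portable headset).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from .montage import CHANNELS_32, LOBE_MAP
from .spectral import BANDS, BandSet

logger = logging.getLogger(__name__)

VAD_COMPONENTS = ("arousal", "valence", "dominance")


@dataclasses.dataclass
class LobeProjection:
    """First-PC projection of one subject/lobe/band block."""

    loading: np.ndarray  # unit-norm weight per member channel
    scores: np.ndarray  # one projected value per window
    explained_ratio: float


def lobe_pca_first_component(features: np.ndarray) -> LobeProjection:
    """First principal component of a (windows, channels) block.

    Columns are centered (per-subject mean removed), no variance scaling.
    The loading sign is fixed so the largest-magnitude weight is positive.
    A zero-variance block degenerates to an arbitrary unit loading and
    all-zero scores, with a warning.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a (windows >= 2, channels >= 1) matrix")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        warnings.warn("zero-variance block: falling back to arbitrary unit loading")
        v1 = np.zeros(X.shape[1])
        v1[0] = 1.0
        return LobeProjection(v1, np.zeros(X.shape[0]), 0.0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    total = float(np.sum(s**2))
    return LobeProjection(v1, Xc @ v1, float(s[0] ** 2 / total))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation by the definitional sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if denom == 0:
        return np.nan
    return float(np.sum(xd * yd) / denom)


def mean_abs_corr(
    projections: Sequence[np.ndarray], labels: Sequence[np.ndarray]
) -> float:
    """Mean across subjects of |Pearson r| between projection and labels.

    Subjects whose projection or label series is constant are excluded from
    the average (their correlation is undefined) and logged.
    """
    if len(projections) != len(labels):
        raise ValueError("need one label series per projection")
    rs = []
    for i, (z, y) in enumerate(zip(projections, labels)):
        if len(z) != len(y):
            raise ValueError(f"subject {i}: len(Z) != len(labels)")
        r = _pearson(z, y)
        if np.isnan(r):
            logger.warning("subject %d: constant series, excluded from Eq-4 average", i)
            continue
        rs.append(abs(r))
    if not rs:
        raise ValueError("all subjects had constant series")
    return float(np.mean(rs))


def correlation_table(
    features: pd.DataFrame,
    lobes: Mapping[str, Sequence[str]] = LOBE_MAP,
    bands: BandSet = BANDS,
) -> pd.DataFrame:
    """Mean absolute correlation r(lobe, band, component), plus the VAD sum.

    ``features`` is a window-level table with a ``subject`` column, band
    power columns named ``<channel>_<band>`` for all lobe members, and
    continuous ``valence``/``arousal``/``dominance`` columns.
    """
    for lobe, members in lobes.items():
        for ch in members:
            for b in bands.names:
                if f"{ch}_{b}" not in features.columns:
                    raise ValueError(f"missing lobe member column {ch}_{b} ({lobe})")
    subjects = sorted(features["subject"].unique())
    rows = []
    for lobe, members in lobes.items():
        for b in bands.names:
            cols = [f"{ch}_{b}" for ch in members]
            zs, ys = [], {e: [] for e in VAD_COMPONENTS}
            for s in subjects:
                block = features.loc[features["subject"] == s]
                proj = lobe_pca_first_component(block[cols].to_numpy())
                zs.append(proj.scores)
                for e in VAD_COMPONENTS:
                    ys[e].append(block[e].to_numpy())
            row = {"lobe": lobe, "band": b}
            for e in VAD_COMPONENTS:
                row[e] = mean_abs_corr(zs, ys[e])
            row["sum"] = row["arousal"] + row["valence"] + row["dominance"]
            rows.append(row)
    return pd.DataFrame(rows)


def best_band(table: pd.DataFrame, bands: BandSet = BANDS) -> str:
    """Band with the largest VAD correlation sum aggregated over lobes.

    Ties break toward the higher-frequency band.
    """
    sums = table.groupby("band")["sum"].sum()
    if set(sums.index) != set(bands.names):
        raise ValueError("correlation table does not cover all bands")
    best, best_val = None, -np.inf
    for b in bands.names:  # ordered low -> high; >= keeps the higher band on ties
        if sums[b] >= best_val:
            best, best_val = b, sums[b]
    return best


def gi_table(
    features: pd.DataFrame,
    band: str,
    *,
    channels: Sequence[str] = CHANNELS_32,
    n_iterations: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int | None = None,
) -> pd.DataFrame:
    """Per-channel Gini importance of the chosen band's powers for each VAD
    component, averaged over random-forest initializations and subjects.

    For each subject and component, ``n_iterations`` random-forest
    regressors (MSE criterion, seeds ``seed .. seed+n_iterations-1``) are
    fitted on the (windows, 32 channels) band-power matrix; their
    impurity-based importances are averaged over iterations, then subjects.
    Each component's importance column sums to 1.
    """
    cols = [f"{ch}_{band}" for ch in channels]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"missing band-power columns: {missing}")
    subjects = sorted(features["subject"].unique())
    per_component = {e: [] for e in VAD_COMPONENTS}
    for s in subjects:
        block = features.loc[features["subject"] == s]
        if len(block) < 10:
            raise ValueError(
                f"subject {s}: {len(block)} windows; need >= 10 to fit forests"
            )
        X = block[cols].to_numpy()
        for e in VAD_COMPONENTS:
            y = block[e].to_numpy()
            imps = np.zeros(len(cols))
            for i in range(n_iterations):
                rf = RandomForestRegressor(
                    n_estimators=n_estimators,
                    criterion="squared_error",
                    max_depth=max_depth,
                    random_state=seed + i,
                    n_jobs=1,
                )
                rf.fit(X, y)
                imps += rf.feature_importances_
            per_component[e].append(imps / n_iterations)
    out = pd.DataFrame(index=list(channels))
    for e in VAD_COMPONENTS:
        gi = np.mean(per_component[e], axis=0)
        total = gi.sum()
        if total > 0:  # guard against forests with no splits
            gi = gi / total
        out[e] = gi
    return out


@dataclasses.dataclass
class EIIRanking:
    """EII per channel, the descending ranking, and the selected top-k set."""

    eii: pd.Series
    ranking: list[str]
    selected: list[str]


def eii_ranking(table: pd.DataFrame, k: int = 8) -> EIIRanking:
    """Average the three components' GI into the EII and take the top k.

    Ties in EII break alphabetically by channel name.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} available channels")
    eii = table[list(VAD_COMPONENTS)].mean(axis=1)
    order = sorted(eii.index, key=lambda c: (-eii[c], c))
    return EIIRanking(eii=eii, ranking=order, selected=order[:k])


class EIIChannelSelector(BaseEstimator):
    """Sklearn-style transformer selecting the top-k channels by EII.

    ``fit`` expects a window-level feature table (DataFrame) holding a
    ``subject`` column, ``<channel>_<band>`` power columns for the full
    montage, and continuous ``valence``/``arousal``/``dominance`` columns.
    ``transform`` restricts a feature table to the selected channels'
    columns.

    Attributes
    ----------
    correlation_table_ : DataFrame
        r(lobe, band, component) grid with the VAD sum column.
    best_band_ : str
        Band carrying the largest correlation mass.
    gi_table_ : DataFrame
        Per-channel Gini importance for each VAD component.
    eii_ : Series
        Emotion Importance Index per channel.
    channels_ : list of str
        Selected top-k channels, EII-descending.
    """

    def __init__(
        self,
        k: int = 8,
        n_iterations: int = 10,
        n_estimators: int = 100,
        random_state: int = 0,
        channels: Sequence[str] = CHANNELS_32,
    ):
        self.k = k
        self.n_iterations = n_iterations
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.channels = channels

    def fit(self, X: pd.DataFrame, y=None):
        self.correlation_table_ = correlation_table(X)
        self.best_band_ = best_band(self.correlation_table_)
        self.gi_table_ = gi_table(
            X,
            self.best_band_,
            channels=self.channels,
            n_iterations=self.n_iterations,
            seed=self.random_state,
            n_estimators=self.n_estimators,
        )
        ranking = eii_ranking(self.gi_table_, k=self.k)
        self.eii_ = ranking.eii
        self.ranking_ = ranking.ranking
        self.channels_ = ranking.selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "channels_"):
            raise RuntimeError("selector is not fitted")
        def is_dropped(col: str) -> bool:
            prefix = col.split("_", 1)[0]
            return prefix in self.channels and prefix not in self.channels_

        return X[[c for c in X.columns if not is_dropped(c)]]
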