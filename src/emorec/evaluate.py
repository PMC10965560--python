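"""Shift-based cross-validation, classifier comparison and the final VAD trio.

Evaluation uses an intra-subject 60:20:20 train/validation/test split that
is repeated over eight folds by circularly rotating the sample indices by a
fold-dependent offset (phi = fold * floor(n / folds)) before cutting the
contiguous blocks.  Five classifier families are compared (Extra-Trees,
Random Forest, XGBoost, kNN, SVC) on the three-level VAD classes; accuracy
and macro-F1 are computed from one-vs-rest confusion counts.  Sweeps over
window length and feature count pick the operating point; the final model
is an Extra-Trees trio (one classifier per VAD component), each with its
own top-k feature list taken from the ensemble's impurity importances.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .spectral import BANDS, INDEX_NAMES, WindowSpec, build_feature_table

logger = logging.getLogger(__name__)

COMPONENTS = ("valence", "arousal", "dominance")
MODEL_FAMILIES = ("extra_trees", "random_forest", "xgboost", "knn", "svc")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """60:20:20 intra-subject split repeated over shifted folds."""

    train: float = 0.60
    validation: float = 0.20
    test: float = 0.20
    folds: int = 8
    stride: int = 16  # training-row decimation for model-selection runs

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.folds < 1 or self.stride < 1:
            raise ValueError("folds and stride must be >= 1")


def shift_split(
    n: int, spec: SplitSpec = SplitSpec(), fold: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circularly rotate 0..n-1 by phi(fold) and cut 60/20/20 blocks.

    phi(fold) = fold * floor(n / folds).  The three index sets are disjoint
    and cover all n samples.
    """
    if not 0 <= fold < spec.folds:
        raise ValueError(f"fold {fold} outside 0..{spec.folds - 1}")
    if n < spec.folds:
        raise ValueError(f"n={n} too small for {spec.folds} folds")
    n_train = int(np.floor(spec.train * n))
    n_val = int(np.floor(spec.validation * n))
    if n_train == 0 or n_val == 0 or n - n_train - n_val == 0:
        raise ValueError(f"n={n} gives an empty split block")
    phi = fold * (n // spec.folds)
    rotated = (np.arange(n) + phi) % n
    return (
        rotated[:n_train],
        rotated[n_train : n_train + n_val],
        rotated[n_train + n_val :],
    )


class ShiftSplit:
    """Sklearn-compatible CV splitter yielding (train, test) per shifted fold.

    The validation block is cut but withheld from both sets, matching the
    60:20:20 scheme; use :func:`shift_split` directly to retrieve it.
    """

    def __init__(self, spec: SplitSpec = SplitSpec()):
        self.spec = spec

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.spec.folds

    def split(self, X, y=None, groups=None):
        n = len(X)
        for fold in range(self.spec.folds):
            train, _val, test = shift_split(n, self.spec, fold)
            yield train, test


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    family: str = "extra_trees"
    params: Mapping | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; valid: {MODEL_FAMILIES}"
            )


def make_model(spec: ModelSpec):
    """Instantiate the sklearn/xgboost estimator for a model spec."""
    params = dict(spec.params or {})
    if spec.family == "extra_trees":
        params.setdefault("n_estimators", 100)
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("n_estimators", 100)
        return XGBClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "knn":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if spec.family == "svc":
        params.setdefault("kernel", "rbf")
        params.setdefault("C", 1.0)
        return SVC(random_state=spec.seed, **params)
    raise AssertionError(spec.family)


# Classifiers are fitted on labels shifted to 0..2 (XGBoost requires
# nonnegative label codes); predictions are shifted back to -1..1.
def _fit(model, X, y):
    model.fit(X, np.asarray(y) + 1)
    return model


def _predict(model, X):
    return np.asarray(model.predict(X)) - 1


@dataclasses.dataclass
class MetricSet:
    """Accuracy plus one-vs-rest precision/recall/F1 per class and macro-F1."""

    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    macro_f1: float
    counts: dict[int, tuple[int, int, int, int]]  # class -> (TP, TN, FP, FN)
    n: int


def compute_metrics(y_true, y_pred, classes: Sequence[int] = (-1, 0, 1)) -> MetricSet:
    """Confusion-count metrics on three-level labels.

    Accuracy is the fraction of correct predictions; precision, recall and
    F1 are one-vs-rest per class; macro-F1 is the unweighted mean over
    classes present in the data (a class absent from both truth and
    prediction is skipped and logged).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = y_true.size
    accuracy = float(np.mean(y_true == y_pred))
    precision, recall, f1, counts = {}, {}, {}, {}
    f1_for_macro = []
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        counts[c] = (tp, tn, fp, fn)
        if tp + fn == 0 and tp + fp == 0:
            logger.info("class %d absent from truth and prediction; skipped", c)
            continue
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision[c], recall[c] = p, r
        f1[c] = 2 * p * r / (p + r) if p + r else 0.0
        f1_for_macro.append(f1[c])
    macro_f1 = float(np.mean(f1_for_macro)) if f1_for_macro else 0.0
    return MetricSet(accuracy, precision, recall, f1, macro_f1, counts, n)


def _feature_cols(table: pd.DataFrame) -> list[str]:
    """Columns of the form <channel>_<band-or-index>."""
    suffixes = set(BANDS.names) | set(INDEX_NAMES)
    return [
        c
        for c in table.columns
        if "_" in c and c.rsplit("_", 1)[1] in suffixes
    ]


def evaluate_models(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
    split: SplitSpec = SplitSpec(),
    *,
    feature_cols: Sequence[str] | None = None,
    components: Sequence[str] = COMPONENTS,
    decimate: bool = True,
) -> pd.DataFrame:
    """Fit each model on each component over the shifted folds.

    Returns a tidy frame (model, component, fold, accuracy, macro_f1).
    Training rows are decimated by ``split.stride`` when ``decimate`` is
    true; validation and test rows never are.
    """
    cols = list(feature_cols) if feature_cols is not None else _feature_cols(table)
    X = table[cols].to_numpy()
    n = len(table)
    rows = []
    for spec in specs:
        for comp in components:
            y = table[f"{comp}_class"].to_numpy()
            for fold in range(split.folds):
                tr, _va, te = shift_split(n, split, fold)
                if decimate:
                    tr = tr[:: split.stride]
                if len(np.unique(y[tr])) < 2:
                    logger.warning(
                        "%s/%s fold %d: single-class training block, skipped",
                        spec.family, comp, fold,
                    )
                    continue
                model = _fit(make_model(spec), X[tr], y[tr])
                m = compute_metrics(y[te], _predict(model, X[te]))
                rows.append(
                    {
                        "model": spec.family,
                        "component": comp,
                        "fold": fold,
                        "accuracy": m.accuracy,
                        "macro_f1": m.macro_f1,
                    }
                )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SweepResult:
    grid: pd.DataFrame
    winner: object


def window_sweep(
    rs,
    lengths: Sequence[float] = (2.0, 4.0, 5.0, 8.0, 10.0),
    specs: Sequence[ModelSpec] = (ModelSpec("extra_trees"),),
    split: SplitSpec = SplitSpec(),
    *,
    montage: Sequence[str] | None = None,
    step_s: float | None = None,
) -> SweepResult:
    """Mean test accuracy per (window length, model), features rebuilt per length.

    ``step_s`` defaults to the window length (non-overlapping windows).
    Winner: the smallest length attaining the maximal score rounded to 3
    decimals, averaged across models, folds and components.
    """
    rows = []
    for length in lengths:
        spec = WindowSpec(length_s=length, step_s=step_s or length)
        table = build_feature_table(rs, spec, montage=montage)
        res = evaluate_models(table, specs, split)
        for model, acc in res.groupby("model")["accuracy"].mean().items():
            rows.append({"window_s": length, "model": model, "accuracy": acc})
    grid = pd.DataFrame(rows)
    overall = grid.groupby("window_s")["accuracy"].mean().round(3)
    winner = min(w for w in overall.index if overall[w] == overall.max())
    return SweepResult(grid=grid, winner=winner)


def feature_count_sweep(
    table: pd.DataFrame,
    model: ModelSpec = ModelSpec("extra_trees"),
    counts: Sequence[int] = tuple(range(25, 36)),
    split: SplitSpec = SplitSpec(),
    *,
    components: Sequence[str] = COMPONENTS,
) -> SweepResult:
    """Accuracy of per-component top-k feature subsets, k over ``counts``.

    Features are ranked per component by the tree ensemble's impurity
    importance (fitted on the full decimated table); for each k the model is
    refitted on the top-k columns over the shifted folds.  Winner: the
    smallest k attaining the maximal component-averaged accuracy rounded to
    3 decimals.
    """
    cols = _feature_cols(table)
    if max(counts) > len(cols):
        raise ValueError(
            f"requested up to {max(counts)} features but only {len(cols)} exist"
        )
    X_all = table[[*cols]].to_numpy()
    rankings = {}
    for comp in components:
        y = table[f"{comp}_class"].to_numpy()
        ranker = _fit(
            make_model(model), X_all[:: split.stride], y[:: split.stride]
        )
        if not hasattr(ranker, "feature_importances_"):
            raise ValueError(
                f"{model.family} exposes no impurity importances; "
                "use a tree-ensemble family for the feature sweep"
            )
        order = np.argsort(ranker.feature_importances_)[::-1]
        rankings[comp] = [cols[i] for i in order]
    rows = []
    for k in counts:
        for comp in components:
            sub = table[rankings[comp][:k] + [f"{comp}_class"]]
            res = evaluate_models(
                sub, [model], split,
                feature_cols=rankings[comp][:k], components=[comp],
            )
            rows.append(
                {"k": k, "component": comp, "accuracy": res["accuracy"].mean()}
            )
    grid = pd.DataFrame(rows)
    avg = grid.groupby("k")["accuracy"].mean().round(3)
    winner = min(k for k in avg.index if avg[k] == avg.max())
    return SweepResult(grid=grid, winner=winner)


class VADClassifier(BaseEstimator, ClassifierMixin):
    """Trio of 3-class classifiers, one per VAD component.

    ``fit`` takes the feature table (DataFrame) and uses its
    ``<component>_class`` columns as targets.  When ``n_features`` is set,
    each component first ranks all candidate features by the ensemble's
    impurity importance and keeps its own top-k list (the lists may
    differ between components), then refits on the subset.

    Attributes
    ----------
    models_ : dict component -> fitted estimator
    feature_lists_ : dict component -> ordered list of feature columns
    """

    def __init__(
        self,
        family: str = "extra_trees",
        n_features: int | None = None,
        params: Mapping | None = None,
        random_state: int = 0,
    ):
        self.family = family
        self.n_features = n_features
        self.params = params
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.family, self.params, self.random_state)

    def fit(self, X: pd.DataFrame, y=None):
        cols = _feature_cols(X)
        if not cols:
            raise ValueError("no feature columns (<channel>_<band-or-index>) in X")
        self.models_ = {}
        self.feature_lists_ = {}
        for comp in COMPONENTS:
            target = X[f"{comp}_class"].to_numpy()
            feats = list(cols)
            if self.n_features is not None:
                if self.n_features > len(cols):
                    raise ValueError(
                        f"n_features={self.n_features} exceeds {len(cols)} columns"
                    )
                ranker = _fit(make_model(self._spec()), X[cols].to_numpy(), target)
                order = np.argsort(ranker.feature_importances_)[::-1]
                feats = [cols[i] for i in order[: self.n_features]]
            model = _fit(make_model(self._spec()), X[feats].to_numpy(), target)
            self.models_[comp] = model
            self.feature_lists_[comp] = feats
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predicted classes, one column per component, values in {-1,0,1}."""
        out = {}
        for comp in COMPONENTS:
            out[f"{comp}_class"] = _predict(
                self.models_[comp], X[self.feature_lists_[comp]].to_numpy()
            )
        return pd.DataFrame(out, index=getattr(X, "index", None))

    def predict_triples(self, X: pd.DataFrame) -> np.ndarray:
        """(n, 3) array of (arousal, valence, dominance) classes."""
        pred = self.predict(X)
        return pred[["arousal_class", "valence_class", "dominance_class"]].to_numpy()


def train_final(
    table: pd.DataFrame,
    k: int = 34,
    model: ModelSpec = ModelSpec("extra_trees"),
) -> VADClassifier:
    """Fit the final per-component trio with top-k feature lists."""
    clf = VADClassifier(
        family=model.family, n_features=k, params=model.params,
        random_state=model.seed,
    )
    return clf.fit(table)


def evaluate_final_trio(
    table: pd.DataFrame,
    k: int = 34,
    model: ModelSpec = ModelSpec("extra_trees"),
    split: SplitSpec = SplitSpec(),
    *,
    decimate: bool = True,
) -> pd.DataFrame:
    """Cross-validate the final top-k trio over the shifted folds.

    For each fold a fresh trio is fitted on the (optionally decimated)
    training block — feature ranking included, so selection cannot peek at
    the test block — and scored on the test block.  Returns a tidy frame
    (component, fold, accuracy, macro_f1).
    """
    n = len(table)
    rows = []
    for fold in range(split.folds):
        tr, _va, te = shift_split(n, split, fold)
        if decimate:
            tr = tr[:: split.stride]
        trio = train_final(table.iloc[tr], k=k, model=model)
        pred = trio.predict(table.iloc[te])
        for comp in COMPONENTS:
            m = compute_metrics(
                table.iloc[te][f"{comp}_class"].to_numpy(),
                pred[f"{comp}_class"].to_numpy(),
            )
            rows.append(
                {
                    "component": comp,
                    "fold": fold,
                    "accuracy": m.accuracy,
                    "macro_f1": m.macro_f1,
                }
            )
    return pd.DataFrame(rows)


def save_bundle(clf: VADClassifier, path, metadata: Mapping | None = None) -> None:
    """Persist a fitted trio with a JSON metadata file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(clf, path / "models.joblib")
    meta = {
        "family": clf.family,
        "n_features": clf.n_features,
        "random_state": clf.random_state,
        "feature_lists": clf.feature_lists_,
        **(dict(metadata) if metadata else {}),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_bundle(path) -> tuple[VADClassifier, dict]:
    path = Path(path)
    clf = joblib.load(path / "models.joblib")
    meta = json.loads((path / "metadata.json").read_text())
    return clf, meta
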