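"""Tabular data loading, leak-free scaling and stratified splitting.

Everything a classification experiment touches before modelling lives here:
CSV ingestion with categorical encoding, the two scalers (z-score for
raw-feature baselines, min-max for the neutrosophic stage, which needs
values in [0, 1]), and stratified hold-out / k-fold plans.  All scaler and
split state is fitted on training rows only so that downstream stages can
be run inside cross-validation folds without leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from ._errors import ConfigurationError, ShapeMismatchError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TabularDataset",
    "ScalerState",
    "SplitPlan",
    "read_table",
    "fit_scaler",
    "apply_scaler",
    "stratified_split",
    "kfold_plan",
]


@dataclass
class TabularDataset:
    """A numeric design matrix with named columns and a label vector.

    ``X`` holds one row per sample and one column per (already encoded)
    predictor; ``y`` holds the class labels.  ``n_dropped`` records how
    many raw rows were discarded for missing values during loading.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ShapeMismatchError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ShapeMismatchError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise ShapeMismatchError(
                f"{len(self.feature_names)} names for {self.X.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("X contains non-finite values after loading")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: np.ndarray) -> "TabularDataset":
        """Row-subset view used by split/fold consumers."""
        idx = np.asarray(indices, dtype=int)
        return TabularDataset(list(self.feature_names), self.X[idx], self.y[idx])


@dataclass
class ScalerState:
    """Train-fitted per-feature statistics for z-score or min-max scaling."""

    kind: str  # "zscore" | "minmax"
    feature_names: list[str]
    center: np.ndarray  # mean (zscore) or min (minmax)
    scale: np.ndarray  # std (zscore) or max - min (minmax)
    fitted_on: int = 0

    @property
    def d(self) -> int:
        return len(self.feature_names)


@dataclass
class SplitPlan:
    """Deterministic train/test (and optionally k-fold) index assignment."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    ratio: float | None = None
    fold_assignments: np.ndarray | None = field(default=None)

    @property
    def k(self) -> int | None:
        if self.fold_assignments is None:
            return None
        return int(self.fold_assignments.max()) + 1


def _encode_categoricals(frame: pd.DataFrame) -> pd.DataFrame:
    """Label-encode binary object columns, one-hot expand multiclass ones."""
    out = {}
    for col in frame.columns:
        series = frame[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.astype(float)
            continue
        levels = sorted(series.astype(str).unique())
        if len(levels) <= 2:
            mapping = {lvl: i for i, lvl in enumerate(levels)}
            out[col] = series.astype(str).map(mapping).astype(float)
        else:
            for lvl in levels:
                out[f"{col}={lvl}"] = (series.astype(str) == lvl).astype(float)
    return pd.DataFrame(out, index=frame.index)


def read_table(
    path,
    target_column: str,
    missing: str = "drop",
) -> TabularDataset:
    """Load a delimited text table into a :class:`TabularDataset`.

    Binary categorical predictors are label-encoded, multiclass ones are
    one-hot expanded.  Rows with missing values are dropped under the
    default policy and the drop count is logged and recorded.

    Raises
    ------
    ConfigurationError
        If ``target_column`` is absent from the header.
    ValidationError
        If fewer than two classes survive loading.
    """
    if missing != "drop":
        raise ConfigurationError(f"unsupported missing-value policy: {missing!r}")
    frame = pd.read_csv(path)
    if target_column not in frame.columns:
        raise ConfigurationError(
            f"target column {target_column!r} not found; available: {list(frame.columns)}"
        )
    n_raw = len(frame)
    frame = frame.dropna(axis=0)
    n_dropped = n_raw - len(frame)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values", n_dropped)
    y = frame[target_column].to_numpy()
    predictors = _encode_categoricals(frame.drop(columns=[target_column]))
    if len(np.unique(y)) < 2:
        raise ValidationError("target has fewer than 2 classes after loading")
    return TabularDataset(
        feature_names=list(predictors.columns),
        X=predictors.to_numpy(dtype=float),
        y=y,
        n_dropped=n_dropped,
    )


def fit_scaler(train: TabularDataset, kind: str = "minmax") -> ScalerState:
    """Fit per-feature scaling statistics on training rows only.

    The z-score convention is the population standard deviation
    (divide by n); a constant feature under z-score is an error because
    its deviation is zero.
    """
    if kind not in ("zscore", "minmax"):
        raise ConfigurationError(f"unknown scaler kind: {kind!r}")
    if train.n < 2:
        raise ValidationError("need at least 2 samples to fit a scaler")
    if kind == "zscore":
        center = train.X.mean(axis=0)
        scale = train.X.std(axis=0, ddof=0)
        bad = np.flatnonzero(scale == 0)
        if bad.size:
            names = [train.feature_names[i] for i in bad]
            raise ValidationError(f"constant feature(s) under zscore: {names}")
    else:
        lo = train.X.min(axis=0)
        hi = train.X.max(axis=0)
        center = lo
        scale = hi - lo
    return ScalerState(
        kind=kind,
        feature_names=list(train.feature_names),
        center=center,
        scale=scale,
        fitted_on=train.n,
    )


def apply_scaler(data: TabularDataset, state: ScalerState) -> TabularDataset:
    """Apply train-fitted scaling; min-max output is clipped to [0, 1].

    Clipping keeps neutrosophic memberships well defined when test values
    fall outside the training range.  A feature that was constant during
    min-max fitting maps to 0.5 (maximal indeterminacy: the value carries
    no ordering information).
    """
    if data.d != state.d:
        raise ShapeMismatchError(
            f"data has {data.d} features but scaler was fitted on {state.d}"
        )
    if state.kind == "zscore":
        Xs = (data.X - state.center) / state.scale
    else:
        scale = state.scale.copy()
        degenerate = scale == 0
        scale[degenerate] = 1.0
        Xs = (data.X - state.center) / scale
        Xs[:, degenerate] = 0.5
        Xs = np.clip(Xs, 0.0, 1.0)
    return TabularDataset(list(data.feature_names), Xs, data.y, data.n_dropped)


def _check_class_sizes(y: np.ndarray, minimum: int, what: str) -> None:
    labels, counts = np.unique(y, return_counts=True)
    small = labels[counts < minimum]
    if small.size:
        raise ValidationError(
            f"class(es) {small.tolist()} have fewer than {minimum} samples; "
            f"cannot build a stratified {what}"
        )


def stratified_split(data: TabularDataset, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Stratified train/test split preserving class proportions within one sample."""
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError("ratio must lie strictly between 0 and 1")
    _check_class_sizes(data.y, 2, "split")
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=ratio, random_state=seed)
    train_idx, test_idx = next(splitter.split(data.X, data.y))
    return SplitPlan(
        train_indices=np.sort(train_idx),
        test_indices=np.sort(test_idx),
        seed=seed,
        ratio=ratio,
    )


def kfold_plan(data: TabularDataset, k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified k-fold assignment: each sample lands in exactly one fold."""
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    _check_class_sizes(data.y, k, f"{k}-fold plan")
    folds = np.full(data.n, -1, dtype=int)
    kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_id, (_, held_out) in enumerate(kf.split(data.X, data.y)):
        folds[held_out] = fold_id
    return SplitPlan(
        train_indices=np.arange(data.n),
        test_indices=np.array([], dtype=int),
        seed=seed,
        fold_assignments=folds,
    )
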