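"""Classification metrics, cross-validation, paired tests and model ranking.

Covers four jobs: confusion-count metrics (accuracy, precision, recall,
F1, optional AUC), leak-free k-fold cross-validation of a full pipeline,
McNemar's paired test for comparing two classifiers on the same test set,
and MEREC-weighted TOPSIS ranking of candidate models over several
metrics at once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "McNemarResult",
    "DecisionMatrixMCDM",
    "confusion_counts",
    "classification_metrics",
    "auc_score",
    "cross_validate",
    "mcnemar_test",
    "merec_weights",
    "topsis_rank",
]


@dataclass
class ConfusionCounts:
    """Binary TP/FP/FN/TN counts, or a full class x class matrix."""

    matrix: np.ndarray  # (c, c), rows = truth, cols = prediction
    classes: np.ndarray

    @property
    def binary(self) -> bool:
        return self.matrix.shape[0] == 2

    # binary convenience accessors; the positive class is classes[1]
    @property
    def tp(self) -> int:
        return int(self.matrix[1, 1])

    @property
    def fp(self) -> int:
        return int(self.matrix[0, 1])

    @property
    def fn(self) -> int:
        return int(self.matrix[1, 0])

    @property
    def tn(self) -> int:
        return int(self.matrix[0, 0])

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricsReport:
    """Accuracy, precision, recall, F1 (and optionally AUC) in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    averaging: str = "binary"


@dataclass
class McNemarResult:
    """Discordant counts and the paired-test statistic for two classifiers."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    chi2: float
    p_value: float
    corrected: bool
    exact: bool = False
    undefined: bool = False


@dataclass
class DecisionMatrixMCDM:
    """Alternatives x criteria performance matrix (all benefit-type here)."""

    alternatives: list[str]
    criteria: list[str]
    values: np.ndarray
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.alternatives), len(self.criteria)):
            raise ValidationError("matrix shape must be alternatives x criteria")


def confusion_counts(y_true, y_pred, classes=None) -> ConfusionCounts:
    """Exact confusion matrix; binary accessors use the larger label as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes.tolist())}
    mat = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true.tolist(), y_pred.tolist()):
        mat[index[t], index[p]] += 1
    return ConfusionCounts(matrix=mat, classes=classes)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; reporting 0", what)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts, averaging: str | None = None) -> MetricsReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Binary uses the plain one-class formulas; multiclass uses a
    support-weighted one-vs-rest average.  Degenerate denominators
    resolve to 0 with a warning.
    """
    mat = counts.matrix
    n = counts.total
    acc = _safe_div(float(np.trace(mat)), n, "accuracy")
    if averaging is None:
        averaging = "binary" if counts.binary else "weighted"
    if averaging == "binary":
        if not counts.binary:
            raise ValidationError("binary averaging requires exactly 2 classes")
        prn = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
        rcl = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    else:
        support = mat.sum(axis=1)
        prns, rcls = [], []
        for i in range(mat.shape[0]):
            prns.append(_safe_div(mat[i, i], mat[:, i].sum(), f"precision[{i}]"))
            rcls.append(_safe_div(mat[i, i], mat[i, :].sum(), f"recall[{i}]"))
        w = support / support.sum()
        prn = float(np.dot(w, prns))
        rcl = float(np.dot(w, rcls))
    f1 = _safe_div(2.0 * prn * rcl, prn + rcl, "F1")
    return MetricsReport(accuracy=acc, precision=prn, recall=rcl, f1=f1, averaging=averaging)


def auc_score(y_true, scores) -> float:
    """Binary ROC AUC for scores of the positive (larger) class."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y_true, scores))


def cross_validate(pipeline_factory, data, k: int = 5, seed: int = 0):
    """Stratified k-fold evaluation with every component fitted per fold.

    ``pipeline_factory`` must return a FRESH unfitted estimator with
    ``fit(dataset)``/``predict(dataset)``; receiving an already-fitted
    object is treated as a leakage hazard and rejected.  Returns the
    per-fold reports and a summary of means and standard deviations.
    """
    from .datasets import kfold_plan

    plan = kfold_plan(data, k=k, seed=seed)
    reports: list[MetricsReport] = []
    for fold in range(k):
        test_idx = np.flatnonzero(plan.fold_assignments == fold)
        train_idx = np.flatnonzero(plan.fold_assignments != fold)
        pipe = pipeline_factory()
        if getattr(pipe, "is_fitted", False):
            raise ValidationError(
                "pipeline_factory returned a fitted pipeline; components must "
                "be fitted inside each fold"
            )
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        pipe.fit(train)
        pred = pipe.predict(test)
        reports.append(classification_metrics(confusion_counts(test.y, pred)))
    summary = {
        metric: (
            float(np.mean([getattr(r, metric) for r in reports])),
            float(np.std([getattr(r, metric) for r in reports])),
        )
        for metric in ("accuracy", "precision", "recall", "f1")
    }
    return reports, summary


def mcnemar_test(y_true, pred_a, pred_b, correction: bool = True) -> McNemarResult:
    """McNemar's paired test on the discordant predictions of two classifiers.

    chi2 = (|b - c| - 1)^2 / (b + c) with continuity correction, or
    (b - c)^2 / (b + c) without; the p-value switches to the exact
    binomial branch when b + c < 25.  b + c = 0 leaves the statistic
    undefined (chi2 = 0, p = 1, flagged).
    """
    y_true = np.asarray(y_true)
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    if not (y_true.shape == pred_a.shape == pred_b.shape):
        raise ValidationError("all three vectors must have equal length")
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    m = b + c
    if m == 0:
        return McNemarResult(b=b, c=c, chi2=0.0, p_value=1.0,
                             corrected=correction, undefined=True)
    if correction:
        chi2 = (abs(b - c) - 1) ** 2 / m
    else:
        chi2 = (b - c) ** 2 / m
    if m < 25:
        p = float(stats.binomtest(min(b, c), m, 0.5).pvalue)
        exact = True
    else:
        p = float(stats.chi2.sf(chi2, df=1))
        exact = False
    return McNemarResult(b=b, c=c, chi2=float(chi2), p_value=p,
                         corrected=correction, exact=exact)


def merec_weights(matrix: DecisionMatrixMCDM) -> np.ndarray:
    """Criteria weights from the effect of removing each criterion.

    Benefit-type normalisation h_ij = min_i(x_ij) / x_ij; overall score
    S_i = ln(1 + mean_j |ln h_ij|); removal score S_i^(j) excludes
    criterion j; the weight of j is proportional to E_j = sum_i
    |S_i^(j) - S_i|.  Identical alternatives (all E_j = 0) fall back to
    uniform weights.
    """
    X = matrix.values
    if np.any(X <= 0):
        raise ValidationError("MEREC requires a strictly positive matrix")
    m, k = X.shape
    h = X.min(axis=0, keepdims=True) / X
    abs_ln = np.abs(np.log(h))
    # removal scores keep the original criterion count in the denominator,
    # so a criterion with |ln h| = 0 everywhere has exactly zero effect
    S = np.log1p(abs_ln.sum(axis=1) / k)
    E = np.empty(k)
    for j in range(k):
        rest = np.delete(abs_ln, j, axis=1)
        S_j = np.log1p(rest.sum(axis=1) / k)
        E[j] = np.abs(S_j - S).sum()
    if E.sum() == 0:
        return np.full(k, 1.0 / k)
    return E / E.sum()


def topsis_rank(matrix: DecisionMatrixMCDM) -> tuple[np.ndarray, np.ndarray]:
    """Closeness-to-ideal scores and the resulting ranking.

    Columns are vector-normalised and weighted; the ideal (anti-ideal)
    profile takes the per-criterion max (min); closeness is
    C = D- / (D+ + D-).  Returns (closeness, order) where ``order`` lists
    alternative indices from best to worst; ties keep input order with a
    warning.
    """
    X = matrix.values
    w = matrix.weights
    if w is None:
        w = np.full(X.shape[1], 1.0 / X.shape[1])
    w = np.asarray(w, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValidationError("weights must sum to 1")
    norms = np.sqrt((X ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    V = X / norms * w
    ideal = V.max(axis=0)
    anti = V.min(axis=0)
    d_pos = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((V - anti) ** 2).sum(axis=1))
    denom = d_pos + d_neg
    closeness = np.where(denom == 0, 0.5, d_neg / np.where(denom == 0, 1.0, denom))
    if np.any(denom == 0):
        warnings.warn("alternative(s) equal to both ideal and anti-ideal; closeness 0.5")
    order = np.argsort(-closeness, kind="stable")
    rounded = np.round(closeness, 12)
    if np.unique(rounded).size < rounded.size:
        warnings.warn("tied closeness scores; ties broken by alternative order")
    return closeness, order
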