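"""Rough-set machinery and discernibility-guided attribute reduction.

A decision table is a matrix of discrete symbols plus a class label per
object.  Attribute subsets induce indiscernibility partitions; the lower
and upper approximations of a target set, the positive region and the
dependency degree γ are the classical constructions.  Attribute reduction
is done greedily on the discernibility matrix: at each step pick the
attribute hitting the most still-uncovered object pairs with different
labels, until every resolvable distinction is covered or a feature cap is
reached.  An exhaustive brute-force reduct enumerator is included as an
independent oracle for testing at small attribute counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError, ValidationError
from .datasets import TabularDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DecisionTable",
    "Partition",
    "DiscernibilityMatrix",
    "Reduct",
    "Discretizer",
    "discretize",
    "indiscernibility_partition",
    "lower_approximation",
    "upper_approximation",
    "dependency_degree",
    "build_discernibility_matrix",
    "qrdm_select",
    "exhaustive_reduct_oracle",
]


@dataclass
class DecisionTable:
    """Objects × discrete attribute values plus a decision label per object."""

    attributes: list[str]
    values: np.ndarray  # (n, d) integer symbol codes
    decision: np.ndarray  # (n,) labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.decision = np.asarray(self.decision)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix of symbols")
        if self.values.shape[0] != self.decision.shape[0]:
            raise ValidationError("decision must have one label per object")
        if self.values.shape[1] != len(self.attributes):
            raise ValidationError("one attribute name per column required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def attr_indices(self, attrs) -> list[int]:
        index = {a: i for i, a in enumerate(self.attributes)}
        try:
            return [index[a] for a in attrs]
        except KeyError as exc:
            raise ConfigurationError(f"unknown attribute {exc.args[0]!r}") from exc


@dataclass
class Partition:
    """Disjoint blocks of object indices covering 0..n-1."""

    blocks: list[np.ndarray]
    block_of: np.ndarray  # (n,) block id per object

    @property
    def n(self) -> int:
        return self.block_of.shape[0]

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class DiscernibilityMatrix:
    """Sparse map from object pairs with different decisions to differing attributes.

    Pairs whose decisions differ but whose attribute rows are identical are
    inconsistent: no attribute set can separate them.  They are kept in
    ``inconsistent_pairs`` and excluded from coverage accounting.
    """

    entries: dict[tuple[int, int], frozenset[int]]
    inconsistent_pairs: list[tuple[int, int]]
    attributes: list[str]
    effective: set[tuple[int, int]] | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    def effective_entries(self) -> dict[tuple[int, int], frozenset[int]]:
        """Entries whose coverage can change the dependency degree.

        A pair with both objects outside the positive region of the full
        attribute set lies wholly in the boundary: separating it cannot
        move any object into a pure block, so such pairs are excluded
        from the greedy cover's targets (like the identical-row pairs,
        they are unresolvable in effect).
        """
        if self.effective is None:
            return dict(self.entries)
        return {p: a for p, a in self.entries.items() if p in self.effective}


@dataclass
class Reduct:
    """Ordered attribute selection with coverage diagnostics."""

    selected: list[str]
    selected_idx: list[int]
    coverage_trace: list[int]  # uncovered nonempty entries remaining after each pick
    gamma: float
    truncated: bool
    n_inconsistent: int = 0


class Discretizer:
    """Quantile or equal-width binning with train-derived cut points.

    Columns whose number of distinct training values does not exceed the
    bin count are treated as already discrete and passed through as codes.
    A continuous column with fewer distinct values than requested bins
    degrades gracefully to distinct-value bins with a logged warning.
    """

    def __init__(self, bins: int = 3, strategy: str = "quantile") -> None:
        if strategy not in ("quantile", "equal_width", "none"):
            raise ConfigurationError(f"unknown strategy {strategy!r}")
        if strategy != "none" and bins < 2:
            raise ConfigurationError("bins must be at least 2")
        self.bins = bins
        self.strategy = strategy
        self.cut_points_: list[np.ndarray | None] | None = None
        self.pass_levels_: list[np.ndarray | None] | None = None
        self.feature_names_: list[str] | None = None

    def fit(self, data: TabularDataset) -> "Discretizer":
        self.feature_names_ = list(data.feature_names)
        self.cut_points_ = []
        self.pass_levels_ = []
        for j, name in enumerate(data.feature_names):
            col = data.X[:, j]
            levels = np.unique(col)
            if self.strategy == "none" or levels.size <= self.bins:
                if self.strategy != "none" and levels.size < self.bins and levels.size > 1:
                    logger.warning(
                        "column %r has %d distinct values < %d bins; "
                        "using distinct-value bins",
                        name,
                        levels.size,
                        self.bins,
                    )
                if levels.size == 1:
                    logger.warning("column %r is constant; single symbol", name)
                self.cut_points_.append(None)
                self.pass_levels_.append(levels)
                continue
            if self.strategy == "quantile":
                qs = np.linspace(0, 1, self.bins + 1)[1:-1]
                cuts = np.unique(np.quantile(col, qs))
            else:
                cuts = np.linspace(col.min(), col.max(), self.bins + 1)[1:-1]
            self.cut_points_.append(cuts)
            self.pass_levels_.append(None)
        return self

    def transform(self, data: TabularDataset) -> DecisionTable:
        if self.cut_points_ is None:
            raise ValidationError("discretizer is not fitted")
        if list(data.feature_names) != self.feature_names_:
            raise ConfigurationError("feature names differ from the fitted data")
        cols = []
        for j in range(data.d):
            col = data.X[:, j]
            cuts = self.cut_points_[j]
            if cuts is None:
                levels = self.pass_levels_[j]
                # unseen level maps to nearest trained level
                codes = np.abs(col[:, None] - levels[None, :]).argmin(axis=1)
                cols.append(codes)
            else:
                cols.append(np.digitize(col, cuts))
        return DecisionTable(
            attributes=list(data.feature_names),
            values=np.column_stack(cols).astype(int),
            decision=data.y.copy(),
        )

    def fit_transform(self, data: TabularDataset) -> DecisionTable:
        return self.fit(data).transform(data)


def discretize(data: TabularDataset, bins: int = 3, strategy: str = "quantile") -> DecisionTable:
    """One-shot discretization (fit and apply on the same rows)."""
    return Discretizer(bins=bins, strategy=strategy).fit_transform(data)


def indiscernibility_partition(table: DecisionTable, attrs) -> Partition:
    """Group objects agreeing on every attribute in ``attrs``.

    The empty attribute set yields the coarsest partition (one block).
    """
    idx = table.attr_indices(attrs)
    if not idx:
        block_of = np.zeros(table.n, dtype=int)
        return Partition(blocks=[np.arange(table.n)], block_of=block_of)
    sub = table.values[:, idx]
    _, block_of = np.unique(sub, axis=0, return_inverse=True)
    blocks = [np.flatnonzero(block_of == b) for b in range(block_of.max() + 1)]
    return Partition(blocks=blocks, block_of=block_of)


def lower_approximation(partition: Partition, target) -> set[int]:
    """Union of blocks fully contained in the target set."""
    tset = set(int(t) for t in target)
    out: set[int] = set()
    for block in partition.blocks:
        if all(int(o) in tset for o in block):
            out.update(int(o) for o in block)
    return out


def upper_approximation(partition: Partition, target) -> set[int]:
    """Union of blocks intersecting the target set."""
    tset = set(int(t) for t in target)
    out: set[int] = set()
    for block in partition.blocks:
        if any(int(o) in tset for o in block):
            out.update(int(o) for o in block)
    return out


def dependency_degree(table: DecisionTable, attrs) -> float:
    """γ = |positive region| / n under the attrs-induced partition.

    A block contributes to the positive region iff its decision labels are
    pure, so γ is computed blockwise without materialising class extents.
    """
    part = indiscernibility_partition(table, attrs)
    pos = 0
    for block in part.blocks:
        labels = table.decision[block]
        if (labels == labels[0]).all():
            pos += block.size
    return pos / table.n


def build_discernibility_matrix(table: DecisionTable) -> DiscernibilityMatrix:
    """For each object pair with different decisions, the attributes separating them."""
    if table.n == 0:
        raise ValidationError("empty decision table")
    entries: dict[tuple[int, int], frozenset[int]] = {}
    inconsistent: list[tuple[int, int]] = []
    vals = table.values
    dec = table.decision
    # positive region of the full attribute set: objects in pure blocks
    part = indiscernibility_partition(table, table.attributes)
    in_pos = np.zeros(table.n, dtype=bool)
    for block in part.blocks:
        labels = dec[block]
        if (labels == labels[0]).all():
            in_pos[block] = True
    effective: set[tuple[int, int]] = set()
    for i in range(table.n - 1):
        diff_dec = np.flatnonzero(dec[i + 1 :] != dec[i]) + (i + 1)
        if diff_dec.size == 0:
            continue
        diffs = vals[diff_dec] != vals[i]  # (m, d) bool
        for row, j in enumerate(diff_dec):
            attrs = frozenset(np.flatnonzero(diffs[row]).tolist())
            if attrs:
                entries[(i, int(j))] = attrs
                if in_pos[i] or in_pos[j]:
                    effective.add((i, int(j)))
            else:
                inconsistent.append((i, int(j)))
    if inconsistent:
        logger.warning(
            "%d object pair(s) share attribute values but differ in decision; "
            "they are excluded from coverage",
            len(inconsistent),
        )
    return DiscernibilityMatrix(
        entries=entries,
        inconsistent_pairs=inconsistent,
        attributes=list(table.attributes),
        effective=effective,
    )


def qrdm_select(
    table: DecisionTable,
    max_features: int | None = None,
    prune: bool = False,
    weighted: bool = False,
) -> Reduct:
    """Greedy discernibility-matrix cover, the QuickReduct variant used here.

    At each step the attribute present in the largest number of uncovered
    entries is taken (ties broken by lowest column index); every entry it
    hits is removed.  The loop stops when all resolvable distinctions are
    covered or ``max_features`` attributes have been taken (``truncated``).
    ``weighted=True`` scores each entry by 1/|entry| instead of 1, favouring
    attributes that resolve otherwise hard-to-separate pairs.  ``prune=True``
    runs a backward pass dropping selected attributes whose removal keeps
    the dependency degree intact, yielding an inclusion-minimal selection.
    """
    if max_features is None:
        max_features = table.d
    if max_features < 1:
        raise ValidationError("max_features must be at least 1")
    matrix = build_discernibility_matrix(table)
    entry_sets = list(matrix.effective_entries().values())
    if not entry_sets:
        if matrix.inconsistent_pairs:
            logger.warning("table is fully inconsistent; returning empty reduct")
        return Reduct(
            selected=[],
            selected_idx=[],
            coverage_trace=[],
            gamma=dependency_degree(table, []),
            truncated=False,
            n_inconsistent=len(matrix.inconsistent_pairs),
        )

    uncovered = entry_sets
    selected_idx: list[int] = []
    trace: list[int] = []
    while uncovered and len(selected_idx) < max_features:
        scores = np.zeros(table.d)
        for entry in uncovered:
            w = 1.0 / len(entry) if weighted else 1.0
            for a in entry:
                scores[a] += w
        scores[selected_idx] = -np.inf
        best = int(np.argmax(scores))  # argmax keeps the lowest index on ties
        selected_idx.append(best)
        uncovered = [e for e in uncovered if best not in e]
        trace.append(len(uncovered))
    truncated = bool(uncovered)

    if prune and not truncated and len(selected_idx) > 1:
        target_gamma = dependency_degree(table, table.attributes)
        keep = list(selected_idx)
        for a in reversed(selected_idx):  # drop late, likely-redundant picks first
            trial = [b for b in keep if b != a]
            names = [table.attributes[b] for b in trial]
            if trial and dependency_degree(table, names) >= target_gamma:
                keep = trial
        selected_idx = [a for a in selected_idx if a in keep]

    selected = [table.attributes[i] for i in selected_idx]
    gamma = dependency_degree(table, selected)
    return Reduct(
        selected=selected,
        selected_idx=selected_idx,
        coverage_trace=trace,
        gamma=gamma,
        truncated=truncated,
        n_inconsistent=len(matrix.inconsistent_pairs),
    )


def exhaustive_reduct_oracle(table: DecisionTable, max_attrs: int = 12) -> set[frozenset[str]]:
    """All inclusion-minimal attribute subsets preserving full dependency.

    Brute force over the power set; refuses above ``max_attrs`` attributes.
    The constant-decision table has γ = 1 for every subset, so its unique
    minimal reduct is the empty set.
    """
    if table.d > max_attrs:
        raise ValidationError(
            f"{table.d} attributes exceed the exhaustive-search guard ({max_attrs})"
        )
    full_gamma = dependency_degree(table, table.attributes)
    minimal: set[frozenset[str]] = set()
    for size in range(0, table.d + 1):
        for combo in itertools.combinations(table.attributes, size):
            cand = frozenset(combo)
            if any(m <= cand for m in minimal):
                continue
            if dependency_degree(table, combo) >= full_gamma:
                minimal.add(cand)
    return minimal
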