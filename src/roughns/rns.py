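"""Rough-neutrosophic six-component feature encoding.

Each min-max-scaled feature value x in [0, 1] is first mapped to a
neutrosophic triple (T, I, F): truth-membership T = x, falsity F = 1 - x,
and indeterminacy I = 1 - |2x - 1|, which peaks at the mid-range where the
value is least committal.  The three components are independent — no
T + I + F = 1 constraint is imposed.

The triples are then summarised over indiscernibility granules: the lower
approximation is the pessimistic summary (min T, max I, max F over the
object's block) and the upper approximation the optimistic one (max T,
min I, min F).  Every selected feature therefore expands into six columns
— lower and upper T/I/F — so a k-feature selection yields a 6k-wide
matrix.  The granulation defaults to the indiscernibility partition of
the discretized selected attributes, matching the rough-set stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._errors import ValidationError
from .datasets import TabularDataset
from .rough import Discretizer, Partition, Reduct, indiscernibility_partition

__all__ = [
    "neutrosophic_encode",
    "rns_lower",
    "rns_upper",
    "RNSDataset",
    "rns_transform_table",
    "RNSTransformer",
]

COMPONENTS = ("T_low", "I_low", "F_low", "T_up", "I_up", "F_up")

# pluggable membership mapping: x in [0,1] -> (T, I, F)
MembershipMapping = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]


def default_mapping(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """T = x, I = 1 - |2x - 1| (peak at 0.5), F = 1 - x."""
    return x, 1.0 - np.abs(2.0 * x - 1.0), 1.0 - x


def neutrosophic_encode(
    x: np.ndarray, mapping: MembershipMapping = default_mapping
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map scaled values in [0, 1] to (T, I, F) component arrays."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValidationError(
            "values outside [0, 1]; min-max scale (with clipping) upstream"
        )
    T, I, F = mapping(x)
    return T, I, F


def rns_lower(
    triples: tuple[np.ndarray, np.ndarray, np.ndarray], partition: Partition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pessimistic granule summary: min T, max I, max F within each block."""
    T, I, F = triples
    Tl, Il, Fl = np.empty_like(T), np.empty_like(I), np.empty_like(F)
    for block in partition.blocks:
        Tl[block] = T[block].min()
        Il[block] = I[block].max()
        Fl[block] = F[block].max()
    return Tl, Il, Fl


def rns_upper(
    triples: tuple[np.ndarray, np.ndarray, np.ndarray], partition: Partition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimistic granule summary: max T, min I, min F within each block."""
    T, I, F = triples
    Tu, Iu, Fu = np.empty_like(T), np.empty_like(I), np.empty_like(F)
    for block in partition.blocks:
        Tu[block] = T[block].max()
        Iu[block] = I[block].min()
        Fu[block] = F[block].min()
    return Tu, Iu, Fu


@dataclass
class RNSDataset:
    """Assembled 6k-wide rough-neutrosophic matrix with named columns."""

    feature_names: list[str]  # the k selected source features
    column_names: list[str]  # 6k expanded names, feature-major
    matrix: np.ndarray  # (n, 6k)
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != 6 * len(self.feature_names):
            raise ValidationError("matrix width must be 6 x number of features")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return len(self.feature_names)

    def as_feature_map(self) -> np.ndarray:
        """Reshape to (n, channels=k, length=6) for the attention network."""
        return self.matrix.reshape(self.n, self.k, 6)


def _column_names(features: list[str]) -> list[str]:
    names = []
    for f in features:
        names += [f"{f}_T_low", f"{f}_I_low", f"{f}_F_low",
                  f"{f}_T_up", f"{f}_I_up", f"{f}_F_up"]
    return names


def rns_transform_table(
    data: TabularDataset,
    selected: Reduct | list[str],
    partition: Partition | None = None,
    partition_source: str = "reduct_partition",
    bins: int = 3,
    mapping: MembershipMapping = default_mapping,
) -> RNSDataset:
    """Expand each selected feature of a [0, 1]-scaled table into six components.

    ``partition_source`` chooses the granulation when no partition is given:
    ``reduct_partition`` uses the indiscernibility classes of the discretized
    selected attributes jointly; ``per_feature_bins`` granulates each feature
    by its own quantile bins.
    """
    features = selected.selected if isinstance(selected, Reduct) else list(selected)
    if not features:
        raise ValidationError(
            "empty feature selection; inspect the reduct search output"
        )
    idx = [data.feature_names.index(f) for f in features]
    sub = TabularDataset(features, data.X[:, idx], data.y)

    if partition is not None:
        parts = [partition] * len(features)
    elif partition_source == "reduct_partition":
        table = Discretizer(bins=bins).fit_transform(sub)
        parts = [indiscernibility_partition(table, features)] * len(features)
    elif partition_source == "per_feature_bins":
        parts = []
        for f in features:
            one = TabularDataset([f], sub.X[:, [features.index(f)]], sub.y)
            table = Discretizer(bins=bins).fit_transform(one)
            parts.append(indiscernibility_partition(table, [f]))
    else:
        raise ValidationError(f"unknown partition_source {partition_source!r}")

    n = sub.n
    out = np.empty((n, 6 * len(features)))
    for j, part in enumerate(parts):
        triples = neutrosophic_encode(sub.X[:, j], mapping)
        Tl, Il, Fl = rns_lower(triples, part)
        Tu, Iu, Fu = rns_upper(triples, part)
        out[:, 6 * j : 6 * (j + 1)] = np.column_stack([Tl, Il, Fl, Tu, Iu, Fu])
    return RNSDataset(
        feature_names=features,
        column_names=_column_names(features),
        matrix=out,
        y=sub.y.copy(),
    )


class RNSTransformer:
    """Train/apply split of the rough-neutrosophic expansion.

    ``fit`` discretizes the selected columns of the training rows, forms
    their indiscernibility granules and stores each granule's pessimistic
    and optimistic T/I/F summaries.  ``transform`` maps new rows to the
    granule matching their discretized signature and combines the stored
    summary with the row's own triple; a signature never seen in training
    falls back to the row's point triple (a singleton granule).
    """

    def __init__(
        self,
        features: list[str],
        bins: int = 3,
        strategy: str = "quantile",
        mapping: MembershipMapping = default_mapping,
    ) -> None:
        self.features = list(features)
        self.bins = bins
        self.strategy = strategy
        self.mapping = mapping
        self._disc: Discretizer | None = None
        self._granules: dict[tuple, np.ndarray] | None = None  # signature -> (k, 6)

    def _subset(self, data: TabularDataset) -> TabularDataset:
        idx = [data.feature_names.index(f) for f in self.features]
        return TabularDataset(self.features, data.X[:, idx], data.y)

    def fit(self, train: TabularDataset) -> "RNSTransformer":
        if not self.features:
            raise ValidationError("empty feature selection")
        sub = self._subset(train)
        self._disc = Discretizer(bins=self.bins, strategy=self.strategy).fit(sub)
        table = self._disc.transform(sub)
        part = indiscernibility_partition(table, self.features)
        k = len(self.features)
        granules: dict[tuple, np.ndarray] = {}
        for block in part.blocks:
            sig = tuple(table.values[block[0]].tolist())
            summary = np.empty((k, 6))
            for j in range(k):
                T, I, F = neutrosophic_encode(sub.X[block, j], self.mapping)
                summary[j] = [T.min(), I.max(), F.max(), T.max(), I.min(), F.min()]
            granules[sig] = summary
        self._granules = granules
        return self

    def transform(self, data: TabularDataset) -> RNSDataset:
        if self._granules is None or self._disc is None:
            raise ValidationError("transformer is not fitted")
        sub = self._subset(data)
        table = self._disc.transform(sub)
        k = len(self.features)
        out = np.empty((sub.n, 6 * k))
        for i in range(sub.n):
            sig = tuple(table.values[i].tolist())
            T, I, F = neutrosophic_encode(sub.X[i], self.mapping)
            point = np.column_stack([T, I, F, T, I, F])  # (k, 6)
            stored = self._granules.get(sig)
            if stored is None:
                combined = point
            else:
                combined = stored.copy()
                # lower: min T, max I, max F; upper: max T, min I, min F
                combined[:, 0] = np.minimum(stored[:, 0], point[:, 0])
                combined[:, 1] = np.maximum(stored[:, 1], point[:, 1])
                combined[:, 2] = np.maximum(stored[:, 2], point[:, 2])
                combined[:, 3] = np.maximum(stored[:, 3], point[:, 3])
                combined[:, 4] = np.minimum(stored[:, 4], point[:, 4])
                combined[:, 5] = np.minimum(stored[:, 5], point[:, 5])
            out[i] = combined.reshape(-1)
        return RNSDataset(
            feature_names=self.features,
            column_names=_column_names(self.features),
            matrix=out,
            y=sub.y.copy(),
        )
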