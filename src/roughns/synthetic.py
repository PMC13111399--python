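"""Synthetic tabular benchmarks with a planted minimal reduct.

The generator plants a known informative feature subset whose discretized
values determine the label through a stated rule (parity of the bin codes
by default, so that no strict subset of the informative features carries
any signal — the informative set is the unique minimal reduct).  Around
it sit exact monotone copies (redundant features, removable without
information loss) and label-independent noise features, plus optional
label flipping.  Continuous mode jitters each value inside its bin while
keeping a margin away from the bin edges, so equal-width discretization
at the matching bin count recovers the planted symbols exactly — even
when the cut points are refitted on a subset of the rows.  (Quantile cuts
are rank-based: any occupancy imbalance in a subset shifts them inside a
bin, and a single mis-binned object contaminates its whole
indiscernibility block, so quantile recovery is exact only when cuts are
fitted and applied on the same balanced rows.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable

import numpy as np

from ._errors import ValidationError
from .datasets import TabularDataset

__all__ = ["SyntheticSpec", "generate", "planted_reduct_recovery"]


def parity_rule(bins: tuple[int, ...]) -> int:
    """Label = parity of the summed bin codes; every informative feature
    is needed, none is sufficient alone."""
    return int(sum(bins) % 2)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults give the desk-scale benchmark used throughout: 500 samples,
    2 informative binary-bin features under a parity rule, 1 exact
    redundant copy, 5 noise features, no label noise, continuous values.
    """

    n: int = 500
    n_informative: int = 2
    n_redundant: int = 1
    n_noise: int = 5
    n_bins: int = 2
    rule: Callable[[tuple[int, ...]], int] = field(default=parity_rule)
    label_noise: float = 0.0
    continuous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValidationError("need at least one informative feature")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValidationError("label_noise must lie in [0, 0.5)")
        if self.n_bins < 2:
            raise ValidationError("informative features need at least 2 bins")

    @property
    def total_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def generate(spec: SyntheticSpec) -> tuple[TabularDataset, list[str]]:
    """Draw one dataset; returns it with the planted informative names.

    Redundant feature j is an exact monotone transform (affine, slope
    (j mod 2 ? -1 : 2)) of informative feature ``j mod n_informative``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    # validate rule coverage before any sampling
    for combo in product(range(spec.n_bins), repeat=spec.n_informative):
        label = spec.rule(combo)
        if label is None:
            raise ValidationError(f"rule does not cover bin combination {combo}")

    # balanced bin occupancy per feature: the empirical quantiles then fall
    # exactly between bins, so quantile binning recovers the planted symbols
    base = np.tile(np.arange(spec.n_bins), spec.n // spec.n_bins + 1)[: spec.n]
    codes = np.column_stack(
        [rng.permutation(base) for _ in range(spec.n_informative)]
    )
    if spec.continuous:
        # jitter stays away from bin edges so discretization cuts fall in a
        # genuine density gap even when refitted on a subset of the rows
        margin = 0.08
        jitter = rng.uniform(margin, 1.0 - margin, size=codes.shape)
        informative = (codes + jitter) / spec.n_bins
    else:
        informative = codes.astype(float)

    columns = [informative[:, j] for j in range(spec.n_informative)]
    names = [f"inf{j}" for j in range(spec.n_informative)]
    for j in range(spec.n_redundant):
        src = j % spec.n_informative
        slope, intercept = ((-1.0, 1.0) if j % 2 else (2.0, 1.0))
        columns.append(slope * informative[:, src] + intercept)
        names.append(f"red{j}")
    for j in range(spec.n_noise):
        columns.append(rng.uniform(0.0, 1.0, size=spec.n))
        names.append(f"noise{j}")

    y = np.array([spec.rule(tuple(row)) for row in codes], dtype=int)
    if spec.label_noise > 0:
        flips = rng.uniform(size=spec.n) < spec.label_noise
        labels = np.unique(y)
        if labels.size == 2:
            y[flips] = labels[0] + labels[1] - y[flips]
        else:
            y[flips] = rng.choice(labels, size=int(flips.sum()))

    data = TabularDataset(feature_names=names, X=np.column_stack(columns), y=y)
    return data, [f"inf{j}" for j in range(spec.n_informative)]


def planted_reduct_recovery(
    spec: SyntheticSpec,
    bins: int | None = None,
    max_features: int | None = None,
    prune: bool = True,
    strategy: str = "equal_width",
) -> dict:
    """Run discretize -> reduct search and report recovery of the plant.

    A selected redundant copy counts as recovering its source (functional
    equivalence, not name identity).  ``covers_rule`` requires the final
    dependency degree to reach 1.
    """
    from .datasets import apply_scaler, fit_scaler
    from .rough import Discretizer, qrdm_select

    data, informative = generate(spec)
    scaled = apply_scaler(data, fit_scaler(data, "minmax"))
    table = Discretizer(bins=bins or spec.n_bins, strategy=strategy).fit_transform(scaled)
    reduct = qrdm_select(table, max_features=max_features, prune=prune)

    def canonical(name: str) -> str:
        if name.startswith("red"):
            j = int(name[3:])
            return f"inf{j % spec.n_informative}"
        return name

    mapped = {canonical(f) for f in reduct.selected}
    legitimate = {canonical(f) for f in data.feature_names if not f.startswith("noise")}
    return {
        "selected": reduct.selected,
        "mapped_selected": sorted(mapped),
        "gamma": reduct.gamma,
        "truncated": reduct.truncated,
        "subset_ok": mapped <= legitimate,
        "recovers_plant": mapped == set(informative),
        "covers_rule": reduct.gamma == 1.0,
    }
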