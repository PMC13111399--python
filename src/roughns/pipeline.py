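"""End-to-end pipeline: scale -> reduct -> RNS -> dual attention -> forest.

Glues the stages into one estimator with a fit/predict surface so it can
be dropped into cross-validation.  Every component — min-max scaler,
discretizer cut points, reduct search, rough-neutrosophic granules,
network parameters and the forest — is fitted exclusively on the rows
passed to ``fit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._errors import ValidationError
from .datasets import TabularDataset, apply_scaler, fit_scaler
from .danet import NetworkConfig, TrainedExtractor, train_extractor
from .rns import RNSTransformer
from .rough import Discretizer, Reduct, qrdm_select

__all__ = ["RNSDANetPipeline"]


@dataclass
class RNSDANetPipeline:
    """Rough-neutrosophic dual-attention classifier.

    Parameters
    ----------
    bins : bin count for discretization (reduct search and granulation);
        with ``strategy`` the main reproducibility lever for selection.
    strategy : "quantile" (robust to skew; default) or "equal_width"
        (locks onto geometric density gaps).
    max_features : cap on the reduct size.
    network : extractor hyperparameters (attention variant, epochs, ...).
    rf_params : keyword arguments of the random-forest head.
    prune : enable backward pruning of the greedy reduct.
    """

    bins: int = 3
    strategy: str = "quantile"
    max_features: int = 10
    network: NetworkConfig = field(default_factory=NetworkConfig)
    rf_params: dict = field(default_factory=dict)
    prune: bool = True
    val_fraction: float = 0.2

    # fitted state
    is_fitted: bool = field(default=False, init=False, repr=False)

    def fit(self, train: TabularDataset) -> "RNSDANetPipeline":
        self.scaler_ = fit_scaler(train, "minmax")
        scaled = apply_scaler(train, self.scaler_)
        table = Discretizer(bins=self.bins, strategy=self.strategy).fit_transform(scaled)
        self.reduct_: Reduct = qrdm_select(
            table, max_features=self.max_features, prune=self.prune
        )
        if not self.reduct_.selected:
            raise ValidationError(
                "reduct search selected no attributes; the decision may be "
                "constant or the table fully inconsistent"
            )
        self.rns_ = RNSTransformer(
            self.reduct_.selected, bins=self.bins, strategy=self.strategy
        ).fit(scaled)
        rns_train = self.rns_.transform(scaled)
        fmap = rns_train.as_feature_map()
        self.extractor_: TrainedExtractor = train_extractor(
            fmap, train.y, self.network, val_fraction=self.val_fraction
        )
        emb = self.extractor_.embed(fmap)
        self.classifier_ = RandomForestClassifier(
            random_state=self.network.seed, **self.rf_params
        )
        self.classifier_.fit(emb, train.y)
        self.is_fitted = True
        return self

    def _embed(self, data: TabularDataset) -> np.ndarray:
        if not self.is_fitted:
            raise ValidationError("pipeline is not fitted")
        scaled = apply_scaler(data, self.scaler_)
        rns = self.rns_.transform(scaled)
        return self.extractor_.embed(rns.as_feature_map())

    def predict(self, data: TabularDataset) -> np.ndarray:
        emb = self._embed(data)
        return self.classifier_.predict(emb)

    def predict_proba(self, data: TabularDataset) -> np.ndarray:
        emb = self._embed(data)
        return self.classifier_.predict_proba(emb)
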