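"""Dual-attention feature extractor for rough-neutrosophic tabular input.

The network consumes a feature map of shape (batch, C, L) where the C
channels are the selected features and the L = 6 positions are the
rough-neutrosophic components of each feature.  Two attention blocks can
be enabled independently:

* **Channel attention (CAM).**  Adaptive average pooling over the L axis
  gives per-channel summaries; a two-layer bottleneck gate (1x1
  convolutions, ReLU then sigmoid) produces weights g in (0, 1)^C, and the
  block output is ``x * g + x`` — recalibration with a residual, so with
  all gate parameters at zero the block is exactly ``x -> 1.5 x``.
* **Soft attention (SAM).**  Single-head scaled dot-product attention over
  the L positions: Q, K, V are shared linear maps of each position's
  C-vector, scores are ``Q K^T / sqrt(C)``, softmax rows sum to one, and
  the output is the attention-weighted sum of V.

The attended map is flattened and passed through a dense layer of width
``hidden_expansion x (C*L)``, a linear embedding layer, and a softmax
classification head.  Training minimises cross-entropy with Adam and L2
weight decay; after training, the penultimate embeddings feed an external
ensemble classifier.  Everything is implemented directly in NumPy with
hand-derived gradients, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import ShapeMismatchError, ValidationError

__all__ = [
    "NetworkConfig",
    "TrainedExtractor",
    "TrialRecord",
    "cam_forward",
    "sam_forward",
    "init_params",
    "extractor_forward",
    "train_extractor",
    "extract_embeddings",
    "tune",
    "TUNING_BOUNDS",
]

ATTENTION_VARIANTS = ("none", "cam", "sam", "cam_sam")

# search ranges enforced during tuning
TUNING_BOUNDS = {
    "learning_rate": (1e-5, 1e-1),  # log scale
    "batch_size": (16, 128),
    "weight_decay": (1e-6, 1e-2),  # log scale
    "hidden_expansion": (2, 4),
    "n_estimators": (50, 300),
    "max_depth": (5, 30),
    "min_samples_split": (2, 10),
}


@dataclass
class NetworkConfig:
    """Hyperparameters of the extractor; defaults follow the training protocol
    (Adam, learning rate 1e-3, batch size 32, 50 epochs)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    weight_decay: float = 0.0
    hidden_expansion: int = 2
    cam_reduction: int = 2
    epochs: int = 50
    embedding_dim: int = 16
    seed: int = 0
    attention_variant: str = "cam_sam"

    def __post_init__(self) -> None:
        if self.attention_variant not in ATTENTION_VARIANTS:
            raise ValidationError(
                f"attention_variant must be one of {ATTENTION_VARIANTS}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate, batch_size and epochs must be positive")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be nonnegative")


@dataclass
class TrialRecord:
    """One hyperparameter-search trial: sampled config and its objective."""

    trial_id: int
    config: NetworkConfig
    rf_params: dict
    objective: float
    status: str = "complete"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# attention blocks (functional forward passes; backward passes below)
# ---------------------------------------------------------------------------

def cam_forward(x: np.ndarray, params: dict, cache: dict | None = None) -> np.ndarray:
    """Channel-attention gate with residual: y = x * g + x.

    ``params`` holds W1 (r, C), b1 (r), W2 (C, r), b2 (C) with bottleneck
    width r = max(1, C // reduction).
    """
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in CAM input")
    W1, b1, W2, b2 = params["cam_W1"], params["cam_b1"], params["cam_W2"], params["cam_b2"]
    s = x.mean(axis=2)  # (B, C)
    h_pre = s @ W1.T + b1
    h = np.maximum(h_pre, 0.0)
    g = _sigmoid(h @ W2.T + b2)  # (B, C)
    y = x * (1.0 + g)[:, :, None]
    if cache is not None:
        cache.update(cam_x=x, cam_s=s, cam_hpre=h_pre, cam_h=h, cam_g=g)
    return y


def _cam_backward(dy: np.ndarray, params: dict, cache: dict, grads: dict) -> np.ndarray:
    W1, W2 = params["cam_W1"], params["cam_W2"]
    x, h_pre, h, g = cache["cam_x"], cache["cam_hpre"], cache["cam_h"], cache["cam_g"]
    L = x.shape[2]
    dx = dy * (1.0 + g)[:, :, None]
    dg = (dy * x).sum(axis=2)  # (B, C)
    dz2 = dg * g * (1.0 - g)
    grads["cam_W2"] = dz2.T @ h
    grads["cam_b2"] = dz2.sum(axis=0)
    dh = dz2 @ W2
    dh_pre = dh * (h_pre > 0)
    grads["cam_W1"] = dh_pre.T @ cache["cam_s"]
    grads["cam_b1"] = dh_pre.sum(axis=0)
    ds = dh_pre @ W1  # (B, C)
    dx += ds[:, :, None] / L
    return dx


def sam_forward(x: np.ndarray, params: dict, cache: dict | None = None) -> np.ndarray:
    """Scaled dot-product attention over the L positions.

    Each position's channel vector is projected by Wq, Wk, Wv (C, C);
    attention weights are softmax(Q K^T / sqrt(C)) row-wise.
    """
    if x.shape[2] == 0:
        raise ValidationError("SAM requires at least one sequence position")
    Wq, Wk, Wv = params["sam_Wq"], params["sam_Wk"], params["sam_Wv"]
    X = np.transpose(x, (0, 2, 1))  # (B, L, C)
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    d = X.shape[2]
    S = Q @ np.transpose(K, (0, 2, 1)) / np.sqrt(d)  # (B, L, L)
    A = _softmax(S, axis=-1)
    O = A @ V  # (B, L, C)
    if cache is not None:
        cache.update(sam_X=X, sam_Q=Q, sam_K=K, sam_V=V, sam_A=A)
    return np.transpose(O, (0, 2, 1))


def _sam_backward(dy: np.ndarray, params: dict, cache: dict, grads: dict) -> np.ndarray:
    Wq, Wk, Wv = params["sam_Wq"], params["sam_Wk"], params["sam_Wv"]
    X, Q, K, V, A = (cache["sam_X"], cache["sam_Q"], cache["sam_K"],
                     cache["sam_V"], cache["sam_A"])
    d = X.shape[2]
    dO = np.transpose(dy, (0, 2, 1))  # (B, L, C)
    dA = dO @ np.transpose(V, (0, 2, 1))
    dV = np.transpose(A, (0, 2, 1)) @ dO
    # softmax jacobian applied row-wise
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dS /= np.sqrt(d)
    dQ = dS @ K
    dK = np.transpose(dS, (0, 2, 1)) @ Q
    B = X.shape[0]
    X2 = X.reshape(-1, d)
    grads["sam_Wq"] = X2.T @ dQ.reshape(-1, d)
    grads["sam_Wk"] = X2.T @ dK.reshape(-1, d)
    grads["sam_Wv"] = X2.T @ dV.reshape(-1, d)
    dX = dQ @ Wq.T + dK @ Wk.T + dV @ Wv.T
    return np.transpose(dX, (0, 2, 1))


# ---------------------------------------------------------------------------
# full extractor
# ---------------------------------------------------------------------------

def init_params(C: int, L: int, n_classes: int, config: NetworkConfig) -> dict:
    """Seeded Glorot-uniform initialisation of every trainable tensor."""
    rng = np.random.default_rng(config.seed)

    def glorot(shape):
        fan_in, fan_out = shape[-1], shape[0]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    r = max(1, C // config.cam_reduction)
    flat = C * L
    hidden = config.hidden_expansion * flat
    params = {
        "cam_W1": glorot((r, C)),
        "cam_b1": np.zeros(r),
        "cam_W2": glorot((C, r)),
        "cam_b2": np.zeros(C),
        "sam_Wq": glorot((C, C)),
        "sam_Wk": glorot((C, C)),
        "sam_Wv": glorot((C, C)),
        "dense_W": glorot((hidden, flat)),
        "dense_b": np.zeros(hidden),
        "emb_W": glorot((config.embedding_dim, hidden)),
        "emb_b": np.zeros(config.embedding_dim),
        "head_W": glorot((n_classes, config.embedding_dim)),
        "head_b": np.zeros(n_classes),
    }
    return params


def extractor_forward(
    x: np.ndarray,
    params: dict,
    config: NetworkConfig,
    cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the configured pipeline; returns (embeddings, logits).

    The ``attention_variant`` switch supports the ablations: ``none``
    bypasses both blocks, ``cam``/``sam`` enable one, ``cam_sam`` both
    (CAM first — it stabilises channel scales before SAM mixes positions).
    """
    if x.ndim != 3:
        raise ShapeMismatchError("expected a (batch, C, L) feature map")
    h = x
    if config.attention_variant in ("cam", "cam_sam"):
        h = cam_forward(h, params, cache)
    if config.attention_variant in ("sam", "cam_sam"):
        h = sam_forward(h, params, cache)
    B = h.shape[0]
    flat = h.reshape(B, -1)
    if flat.shape[1] != params["dense_W"].shape[1]:
        raise ShapeMismatchError(
            f"flattened width {flat.shape[1]} does not match the "
            f"configured input width {params['dense_W'].shape[1]}"
        )
    z1 = flat @ params["dense_W"].T + params["dense_b"]
    a1 = np.maximum(z1, 0.0)
    emb = a1 @ params["emb_W"].T + params["emb_b"]
    logits = emb @ params["head_W"].T + params["head_b"]
    if cache is not None:
        cache.update(flat=flat, z1=z1, a1=a1, emb=emb, attended_shape=h.shape)
    return emb, logits


def _backward(
    dlogits: np.ndarray, params: dict, config: NetworkConfig, cache: dict
) -> dict:
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["head_W"] = dlogits.T @ cache["emb"]
    grads["head_b"] = dlogits.sum(axis=0)
    demb = dlogits @ params["head_W"]
    grads["emb_W"] = demb.T @ cache["a1"]
    grads["emb_b"] = demb.sum(axis=0)
    da1 = demb @ params["emb_W"]
    dz1 = da1 * (cache["z1"] > 0)
    grads["dense_W"] = dz1.T @ cache["flat"]
    grads["dense_b"] = dz1.sum(axis=0)
    dflat = dz1 @ params["dense_W"]
    dh = dflat.reshape(cache["attended_shape"])
    if config.attention_variant in ("sam", "cam_sam"):
        dh = _sam_backward(dh, params, cache, grads)
    if config.attention_variant in ("cam", "cam_sam"):
        dh = _cam_backward(dh, params, cache, grads)
    return grads


def loss_and_grads(
    x: np.ndarray,
    y: np.ndarray,
    params: dict,
    config: NetworkConfig,
) -> tuple[float, dict]:
    """Mean cross-entropy (plus L2 decay) and gradients for one batch."""
    cache: dict = {}
    _, logits = extractor_forward(x, params, config, cache)
    B = x.shape[0]
    probs = _softmax(logits, axis=1)
    eps = 1e-12
    ce = -np.log(probs[np.arange(B), y] + eps).mean()
    wd = config.weight_decay
    l2 = 0.0
    if wd:
        l2 = 0.5 * wd * sum(
            float((v ** 2).sum()) for k, v in params.items() if "_W" in k
        )
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = _backward(dlogits, params, config, cache)
    if wd:
        for k in grads:
            if "_W" in k:
                grads[k] = grads[k] + wd * params[k]
    return float(ce + l2), grads


@dataclass
class TrainedExtractor:
    """Fitted network parameters plus config, class order and history."""

    params: dict
    config: NetworkConfig
    classes: np.ndarray
    input_shape: tuple[int, int]  # (C, L)
    history: dict = field(default_factory=dict)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate embeddings, classification head bypassed."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            raise ShapeMismatchError("pass a (n, C, L) feature map (see RNSDataset.as_feature_map)")
        if x.shape[1:] != self.input_shape:
            raise ShapeMismatchError(
                f"input shape {x.shape[1:]} does not match training shape {self.input_shape}"
            )
        emb, _ = extractor_forward(x, self.params, self.config)
        return emb

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        _, logits = extractor_forward(np.asarray(x, dtype=float), self.params, self.config)
        return _softmax(logits, axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[self.predict_proba(x).argmax(axis=1)]


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class shuffled tail split used for the validation curves."""
    val_idx = []
    for label in np.unique(y):
        members = np.flatnonzero(y == label)
        members = rng.permutation(members)
        n_val = max(1, int(round(fraction * members.size)))
        val_idx.append(members[:n_val])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


def train_extractor(
    x: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    val_fraction: float = 0.2,
) -> TrainedExtractor:
    """Fit the extractor with Adam, recording per-epoch learning curves.

    ``x`` is a (n, C, L) feature map; labels may be arbitrary hashables
    and are encoded internally.  Deterministic for a fixed config seed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ShapeMismatchError("expected a (n, C, L) feature map")
    if not 0.0 < val_fraction <= 0.5:
        raise ValidationError("val_fraction must lie in (0, 0.5]")
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes to train")
    n, C, L = x.shape
    rng = np.random.default_rng(config.seed)
    tr_idx, va_idx = _stratified_holdout(y_enc, val_fraction, rng)
    x_tr, y_tr = x[tr_idx], y_enc[tr_idx]
    x_va, y_va = x[va_idx], y_enc[va_idx]

    params = init_params(C, L, classes.size, config)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}

    def evaluate(xs, ys):
        _, logits = extractor_forward(xs, params, config)
        probs = _softmax(logits, axis=1)
        loss = float(-np.log(probs[np.arange(ys.size), ys] + 1e-12).mean())
        acc = float((probs.argmax(axis=1) == ys).mean())
        return loss, acc

    for _epoch in range(config.epochs):
        order = rng.permutation(x_tr.shape[0])
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = loss_and_grads(x_tr[batch], y_tr[batch], params, config)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss at step {t}); "
                    "lower the learning rate"
                )
            t += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                params[k] = params[k] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        tl, ta = evaluate(x_tr, y_tr)
        vl, va = evaluate(x_va, y_va)
        history["train_loss"].append(tl)
        history["train_acc"].append(ta)
        history["val_loss"].append(vl)
        history["val_acc"].append(va)

    return TrainedExtractor(
        params=params,
        config=config,
        classes=classes,
        input_shape=(C, L),
        history=history,
    )


def extract_embeddings(model: TrainedExtractor, x: np.ndarray) -> np.ndarray:
    """Per-sample embeddings of a fitted extractor (head bypassed)."""
    return model.embed(x)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def sample_config(rng: np.random.Generator, base: NetworkConfig) -> tuple[NetworkConfig, dict]:
    """Draw one (network, forest) configuration from the tuning ranges."""
    lo, hi = TUNING_BOUNDS["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = TUNING_BOUNDS["weight_decay"]
    wd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    cfg = replace(
        base,
        learning_rate=lr,
        weight_decay=wd,
        batch_size=int(rng.integers(*TUNING_BOUNDS["batch_size"], endpoint=True)),
        hidden_expansion=int(rng.choice([2, 4])),
    )
    rf_params = {
        "n_estimators": int(rng.integers(*TUNING_BOUNDS["n_estimators"], endpoint=True)),
        "max_depth": int(rng.integers(*TUNING_BOUNDS["max_depth"], endpoint=True)),
        "min_samples_split": int(rng.integers(*TUNING_BOUNDS["min_samples_split"], endpoint=True)),
    }
    return cfg, rf_params


def tune(
    x: np.ndarray,
    y: np.ndarray,
    n_trials: int = 50,
    seed: int = 0,
    base_config: NetworkConfig | None = None,
    val_fraction: float = 0.2,
) -> tuple[tuple[NetworkConfig, dict], list[TrialRecord]]:
    """Joint random search over network and forest hyperparameters.

    The objective is inner-validation accuracy of the full extractor ->
    ensemble pipeline, computed only on the supplied (training) data: each
    trial holds out a stratified fraction, trains the extractor on the
    rest, fits the forest on its embeddings and scores the held-out part.
    Deterministic per seed; returns the argmax configuration and all
    trial records.
    """
    from sklearn.ensemble import RandomForestClassifier

    if n_trials < 1:
        raise ValidationError("n_trials must be at least 1")
    x = np.asarray(x, dtype=float)
    base = base_config or NetworkConfig()
    rng = np.random.default_rng(seed)
    classes, y_enc = np.unique(y, return_inverse=True)
    tr_idx, va_idx = _stratified_holdout(y_enc, val_fraction, np.random.default_rng(seed))

    records: list[TrialRecord] = []
    for trial in range(n_trials):
        cfg, rf_params = sample_config(rng, base)
        cfg = replace(cfg, seed=int(seed + trial + 1))
        try:
            model = train_extractor(x[tr_idx], y_enc[tr_idx], cfg, val_fraction)
            emb_tr = model.embed(x[tr_idx])
            emb_va = model.embed(x[va_idx])
            clf = RandomForestClassifier(random_state=cfg.seed, **rf_params)
            clf.fit(emb_tr, y_enc[tr_idx])
            objective = float(clf.score(emb_va, y_enc[va_idx]))
            records.append(TrialRecord(trial, cfg, rf_params, objective))
        except RuntimeError:
            records.append(TrialRecord(trial, cfg, rf_params, 0.0, status="diverged"))
    best = max(records, key=lambda r: (r.objective, -r.trial_id))
    return (best.config, best.rf_params), records
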