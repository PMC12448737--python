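"""Attention-based 1-D convolutional classifier for gene-expression vectors.

The baseline network treats a sample's p expression values as a length-p
sequence with one channel:

    conv1d(1 -> 32, k=3, same, ReLU)
    conv1d(32 -> 64, k=3, same, ReLU)
    global average pool over positions        g_c = (1/p) sum_i h_ic
    dense(64 -> p) + softmax                  alpha = attention over positions
    position-wise reweighting                 h'_ic = alpha_i * h_ic
    flatten (p * 64)
    dense(-> 128, ReLU)
    dropout(0.5)
    dense(-> 1, sigmoid)

Summing the reweighted map over positions yields the attention context
vector c = sum_i alpha_i h_i; keeping positions before flattening is what
gives the dense-128 layer its large fan-in (8 263 593 total trainable
parameters at p = 1000). Ablation variants: WFAL / WSAL / RBAL remove
the first / second / both attention blocks of a two-attention parent
spec, and RFCL removes the 128-unit dense layer. A "plain CNN"
comparator feeds the pooled 64-vector straight into the dense layer.

No deep-learning framework is used: forward pass, backpropagation and
the Adam optimizer are implemented directly on numpy arrays. Training
follows binary cross-entropy with early stopping on validation loss
(patience 5, best weights restored). Determinism contract: fixed seed,
single-threaded, same BLAS backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AttCnnSpec",
    "TrainConfig",
    "TrainedAttCnn",
    "AttCnnNetwork",
    "ABLATION_VARIANTS",
    "attention_weights",
    "build_attcnn",
    "context_reweight",
    "global_average_pool",
    "make_ablation",
    "make_plain_cnn",
    "make_two_attention_parent",
    "predict_proba",
    "train",
]

ABLATION_VARIANTS = ("baseline", "WFAL", "WSAL", "RBAL", "RFCL")


@dataclass(frozen=True)
class AttCnnSpec:
    """Declarative architecture; the parameter count is computable from it.

    ``attention_blocks`` is a subset of {"after_conv1", "after_conv2"};
    the canonical baseline uses a single block after the second
    convolution. ``dense_units=None`` removes the fully connected layer
    (the RFCL ablation). ``gap_to_dense=True`` skips attention and
    flattening entirely, feeding the pooled channel vector into the
    dense layer (the plain-CNN comparator).
    """

    input_length: int
    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    attention_blocks: frozenset[str] = frozenset({"after_conv2"})
    dense_units: int | None = 128
    dropout_rate: float = 0.5
    gap_to_dense: bool = False

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        if not self.conv_filters:
            raise ValueError("conv_filters must be non-empty")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_length < self.kernel_size:
            raise ValueError(
                f"input_length {self.input_length} < kernel_size {self.kernel_size}"
            )
        bad = set(self.attention_blocks) - {"after_conv1", "after_conv2"}
        if bad:
            raise ValueError(f"unknown attention blocks: {sorted(bad)}")
        if self.gap_to_dense and self.attention_blocks:
            raise ValueError("gap_to_dense excludes attention blocks")


@dataclass
class TrainConfig:
    """Optimization settings for Adam / binary cross-entropy training."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    grid: dict | None = None  # e.g. {"learning_rate": [...], "dropout_rate": [...]}

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedAttCnn:
    """Fitted network handle with its training history."""

    spec: AttCnnSpec
    network: "AttCnnNetwork"
    history: dict[str, list[float]]
    best_epoch: int


# ---------------------------------------------------------------------------
# standalone attention algebra


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax attention weights with max-subtraction for stability."""
    u = np.asarray(scores, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("attention scores must be finite")
    e = np.exp(u - u.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def context_reweight(features: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Scale a positions x channels map by per-position weights.

    Summing the result over positions reproduces the attention context
    vector c = sum_i alpha_i h_i exactly.
    """
    features = np.asarray(features, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if features.ndim != 2 or alpha.shape != (features.shape[0],):
        raise ValueError(
            f"shape mismatch: features {features.shape}, alpha {alpha.shape}"
        )
    return alpha[:, None] * features


def global_average_pool(features: np.ndarray) -> np.ndarray:
    """Channel-wise mean over positions."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 1:
        raise ValueError("features must be a non-empty positions x channels map")
    return features.mean(axis=0)


# ---------------------------------------------------------------------------
# architecture table and variants


def build_attcnn(spec: AttCnnSpec) -> list[tuple[str, tuple, int]]:
    """Layer table (name, output shape, trainable parameters) for a spec.

    Shapes use None for the batch axis. The total of the params column
    equals the parameter count of the instantiated network exactly.
    """
    p = spec.input_length
    k = spec.kernel_size
    f1, f2 = spec.conv_filters
    rows: list[tuple[str, tuple, int]] = []
    rows.append(("conv1", (None, p, f1), k * 1 * f1 + f1))
    if "after_conv1" in spec.attention_blocks:
        rows.append(("gap1", (None, f1), 0))
        rows.append(("attention1_dense", (None, p), f1 * p + p))
        rows.append(("attention1_reweight", (None, p, f1), 0))
    rows.append(("conv2", (None, p, f2), k * f1 * f2 + f2))
    if "after_conv2" in spec.attention_blocks:
        rows.append(("gap2", (None, f2), 0))
        rows.append(("attention2_dense", (None, p), f2 * p + p))
        rows.append(("attention2_reweight", (None, p, f2), 0))
    if spec.gap_to_dense:
        rows.append(("gap", (None, f2), 0))
        feat_dim = f2
    else:
        rows.append(("flatten", (None, p * f2), 0))
        feat_dim = p * f2
    if spec.dense_units is not None:
        rows.append(("dense", (None, spec.dense_units), feat_dim * spec.dense_units + spec.dense_units))
        feat_dim = spec.dense_units
    rows.append(("dropout", (None, feat_dim), 0))
    rows.append(("output", (None, 1), feat_dim * 1 + 1))
    return rows


def count_params(spec: AttCnnSpec) -> int:
    """Total trainable parameters from the layer table."""
    return sum(n for _, _, n in build_attcnn(spec))


def make_two_attention_parent(base: AttCnnSpec) -> AttCnnSpec:
    """Extended spec with symmetric attention blocks after both convolutions.

    This is the parent the WFAL/WSAL/RBAL ablations are defined against.
    Its parameter count exceeds the single-attention baseline by the
    first attention dense layer (f1*p + p).
    """
    return replace(base, attention_blocks=frozenset({"after_conv1", "after_conv2"}))


def make_plain_cnn(base: AttCnnSpec) -> AttCnnSpec:
    """Comparator CNN: attention removed, GAP feeding the dense layer."""
    return replace(base, attention_blocks=frozenset(), gap_to_dense=True)


def make_ablation(variant: str, base: AttCnnSpec) -> AttCnnSpec:
    """Spec transformation for a named ablation variant.

    WFAL/WSAL/RBAL expect ``base`` to be the two-attention parent and
    drop the first / second / both attention blocks; RFCL removes the
    128-unit dense layer (flatten -> dropout -> output); "baseline"
    returns the spec unchanged.
    """
    if variant == "baseline":
        return base
    if variant == "WFAL":
        return replace(base, attention_blocks=base.attention_blocks - {"after_conv1"})
    if variant == "WSAL":
        return replace(base, attention_blocks=base.attention_blocks - {"after_conv2"})
    if variant == "RBAL":
        return replace(base, attention_blocks=frozenset())
    if variant == "RFCL":
        return replace(base, dense_units=None)
    raise ValueError(f"unknown ablation variant {variant!r}; expected one of {ABLATION_VARIANTS}")


# ---------------------------------------------------------------------------
# the network itself


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, p, c) -> (n, p, k*c) sliding windows with 'same' zero padding."""
    n, p, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    windows = np.stack([xp[:, i : i + p, :] for i in range(k)], axis=2)
    return windows.reshape(n, p, k * c)


def _col2im(dcols: np.ndarray, k: int, p: int, c: int) -> np.ndarray:
    """Adjoint of _im2col: (n, p, k*c) -> (n, p, c)."""
    n = dcols.shape[0]
    pad = k // 2
    d = dcols.reshape(n, p, k, c)
    out = np.zeros((n, p + 2 * pad, c))
    for i in range(k):
        out[:, i : i + p, :] += d[:, :, i, :]
    return out[:, pad : pad + p, :]


class AttCnnNetwork:
    """Numpy implementation of an :class:`AttCnnSpec` with Adam training."""

    def __init__(self, spec: AttCnnSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        p = spec.input_length
        k = spec.kernel_size
        f1, f2 = spec.conv_filters
        P: dict[str, np.ndarray] = {}
        P["W1"] = _glorot(rng, k * 1, f1, (k * 1, f1))
        P["b1"] = np.zeros(f1)
        if "after_conv1" in spec.attention_blocks:
            P["Wa1"] = _glorot(rng, f1, p, (f1, p))
            P["ba1"] = np.zeros(p)
        P["W2"] = _glorot(rng, k * f1, f2, (k * f1, f2))
        P["b2"] = np.zeros(f2)
        if "after_conv2" in spec.attention_blocks:
            P["Wa2"] = _glorot(rng, f2, p, (f2, p))
            P["ba2"] = np.zeros(p)
        feat_dim = f2 if spec.gap_to_dense else p * f2
        if spec.dense_units is not None:
            P["Wd"] = _glorot(rng, feat_dim, spec.dense_units, (feat_dim, spec.dense_units))
            P["bd"] = np.zeros(spec.dense_units)
            feat_dim = spec.dense_units
        P["Wo"] = _glorot(rng, feat_dim, 1, (feat_dim, 1))
        P["bo"] = np.zeros(1)
        self.params = P

    # -- bookkeeping --------------------------------------------------------

    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in weights.items()}

    # -- forward ------------------------------------------------------------

    def _attention_block(self, h, Wa, ba, cache_key, cache):
        """GAP -> dense -> softmax over positions -> reweight the map."""
        g = h.mean(axis=1)                        # (n, c)
        scores = g @ Wa + ba                      # (n, p)
        alpha = attention_weights(scores)         # (n, p)
        hw = alpha[:, :, None] * h                # (n, p, c)
        cache[cache_key] = (h, g, alpha)
        return hw, alpha

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Predicted probabilities plus a cache for backprop.

        X is (n, input_length); dropout is active only when ``train`` is
        True and a generator is supplied.
        """
        spec = self.spec
        P = self.params
        if X.ndim != 2 or X.shape[1] != spec.input_length:
            raise ValueError(
                f"X must be (n, {spec.input_length}), got {X.shape}"
            )
        k = spec.kernel_size
        cache: dict = {}
        x = X[:, :, None]                                   # (n, p, 1)

        cols1 = _im2col(x, k)                               # (n, p, k)
        z1 = cols1 @ P["W1"] + P["b1"]
        h1 = np.maximum(z1, 0.0)
        cache["conv1"] = (cols1, z1)

        if "after_conv1" in spec.attention_blocks:
            h1, _ = self._attention_block(h1, P["Wa1"], P["ba1"], "att1", cache)

        cols2 = _im2col(h1, k)                              # (n, p, k*f1)
        z2 = cols2 @ P["W2"] + P["b2"]
        h2 = np.maximum(z2, 0.0)
        cache["conv2"] = (cols2, z2)

        if "after_conv2" in spec.attention_blocks:
            h2w, alpha = self._attention_block(h2, P["Wa2"], P["ba2"], "att2", cache)
            cache["alpha"] = alpha
        else:
            h2w = h2

        n = X.shape[0]
        if spec.gap_to_dense:
            feat = h2w.mean(axis=1)                         # (n, f2)
        else:
            feat = h2w.reshape(n, -1)                       # (n, p*f2)
        cache["feat_pre_dense"] = feat

        if spec.dense_units is not None:
            zd = feat @ P["Wd"] + P["bd"]
            feat = np.maximum(zd, 0.0)
            cache["dense"] = zd

        if train and spec.dropout_rate > 0 and dropout_rng is not None:
            keep = 1.0 - spec.dropout_rate
            mask = (dropout_rng.random(feat.shape) < keep) / keep
            feat = feat * mask
            cache["dropout_mask"] = mask
        cache["feat_final"] = feat

        logits = feat @ P["Wo"] + P["bo"]                   # (n, 1)
        prob = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        cache["prob"] = prob
        return prob, cache

    # -- backward -----------------------------------------------------------

    def _attention_backward(self, dhw, cache_entry, Wa):
        """Gradient through reweight + softmax + dense + GAP.

        Returns (dh, dWa, dba): dh collects both the direct alpha*dhw
        path and the path through alpha (which depends on h via GAP).
        """
        h, g, alpha = cache_entry
        n, p, c = h.shape
        dh = alpha[:, :, None] * dhw                        # direct path
        dalpha = np.einsum("npc,npc->np", dhw, h)           # (n, p)
        # softmax jacobian: ds = alpha * (dalpha - sum(dalpha * alpha))
        dscores = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        dWa = g.T @ dscores
        dba = dscores.sum(axis=0)
        dg = dscores @ Wa.T                                 # (n, c)
        dh += dg[:, None, :] / p                            # GAP backward
        return dh, dWa, dba

    def backward(self, X: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Mean-BCE gradients for every parameter."""
        spec = self.spec
        P = self.params
        n = X.shape[0]
        k = spec.kernel_size
        f1, f2 = spec.conv_filters
        p = spec.input_length
        grads: dict[str, np.ndarray] = {}

        prob = cache["prob"]
        dlogits = ((prob - y) / n)[:, None]                 # BCE + sigmoid
        feat = cache["feat_final"]
        grads["Wo"] = feat.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dfeat = dlogits @ P["Wo"].T

        if "dropout_mask" in cache:
            dfeat = dfeat * cache["dropout_mask"]

        if spec.dense_units is not None:
            zd = cache["dense"]
            dzd = dfeat * (zd > 0)
            pre = cache["feat_pre_dense"]
            grads["Wd"] = pre.T @ dzd
            grads["bd"] = dzd.sum(axis=0)
            dfeat = dzd @ P["Wd"].T

        if spec.gap_to_dense:
            dh2w = np.repeat(dfeat[:, None, :], p, axis=1) / p
        else:
            dh2w = dfeat.reshape(n, p, f2)

        if "after_conv2" in spec.attention_blocks:
            dh2, dWa2, dba2 = self._attention_backward(dh2w, cache["att2"], P["Wa2"])
            grads["Wa2"] = dWa2
            grads["ba2"] = dba2
        else:
            dh2 = dh2w

        cols2, z2 = cache["conv2"]
        dz2 = dh2 * (z2 > 0)
        grads["W2"] = np.einsum("npk,npf->kf", cols2, dz2)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ P["W2"].T
        dh1 = _col2im(dcols2, k, p, f1)

        if "after_conv1" in spec.attention_blocks:
            dh1, dWa1, dba1 = self._attention_backward(dh1, cache["att1"], P["Wa1"])
            grads["Wa1"] = dWa1
            grads["ba1"] = dba1

        cols1, z1 = cache["conv1"]
        dz1 = dh1 * (z1 > 0)
        grads["W1"] = np.einsum("npk,npf->kf", cols1, dz1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads


def _bce(y: np.ndarray, prob: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(prob, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train(
    spec: AttCnnSpec,
    cfg: TrainConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> TrainedAttCnn:
    """Adam / binary cross-entropy training with early stopping.

    Stops when validation loss fails to improve for ``cfg.patience``
    epochs or at ``cfg.max_epochs``; the best-validation weights are
    restored. All randomness (initialization, shuffling, dropout)
    derives from ``cfg.seed``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    if X_train.shape[1] != spec.input_length:
        raise ValueError(
            f"X_train has {X_train.shape[1]} columns, spec expects {spec.input_length}"
        )

    net = AttCnnNetwork(spec, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)

    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history: dict[str, list[float]] = {"loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    wait = 0
    n = len(y_train)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            prob, cache = net.forward(Xb, train=True, dropout_rng=rng)
            loss = _bce(yb, prob)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "inputs may need scaling or a smaller learning rate"
                )
            epoch_loss += loss * len(idx)
            grads = net.backward(Xb, yb, cache)
            step += 1
            for key, gr in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * gr
                v[key] = beta2 * v[key] + (1 - beta2) * gr**2
                mhat = m[key] / (1 - beta1**step)
                vhat = v[key] / (1 - beta2**step)
                net.params[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        val_prob, _ = net.forward(X_val)
        val_loss = _bce(y_val, val_prob)
        history["loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    net.set_weights(best_weights)
    return TrainedAttCnn(spec=spec, network=net, history=history, best_epoch=best_epoch)


def predict_proba(model: TrainedAttCnn, X: np.ndarray) -> np.ndarray:
    """Predicted case probabilities; dropout disabled, deterministic."""
    X = np.asarray(X, dtype=float)
    prob, _ = model.network.forward(X, train=False)
    return prob
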