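"""Tabular transformer regressor for per-feature missing-value prediction.

Each numeric feature of a row becomes one token: the scalar is mapped by a
feature-specific linear layer into a d_model-dimensional embedding, layer
normalisation is applied, and a fixed sinusoidal positional encoding over
the column order is added.  A stack of standard encoder layers (multi-head
scaled dot-product self-attention, position-wise ReLU feed-forward network,
each sub-layer wrapped in residual + LayerNorm) lets the model capture
inter-channel dependencies; the token matrix is pooled (mean, max or
attention pooling) and a linear head emits one scalar — the predicted
value of the currently missing feature.

Training minimises mean squared error with Adam on standardised inputs and
target, holding out a validation fraction for early stopping.  All
randomness (initialisation, shuffling, dropout) flows from the config
seed, so a fit is bit-reproducible single-threaded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import (Adam, Tensor, layer_norm, ones_parameter, parameter,
                       softmax, zeros_parameter)

_LN_EPS = 1e-5
POOLING_CHOICES = ("mean", "max", "attention")


@dataclass(frozen=True)
class TransformerConfig:
    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 64
    pooling: str = "mean"
    dropout: float = 0.1
    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 64
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.pooling not in POOLING_CHOICES:
            raise ValueError(f"pooling must be one of {POOLING_CHOICES}")


def positional_encoding(n_tokens: int, d: int) -> np.ndarray:
    """Sinusoidal position matrix P with P[pos,2i]=sin, P[pos,2i+1]=cos.

    The angular frequency of dimension pair i is 1/10000^(2i/d); entries
    are bounded by 1 in magnitude.
    """
    if d % 2 != 0:
        raise ValueError("embedding dimension d must be even")
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    P = np.empty((n_tokens, d))
    P[:, 0::2] = np.sin(angle)
    P[:, 1::2] = np.cos(angle)
    return P


def self_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention SoftMax(QKᵀ/√d_k)V on plain arrays."""
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("Q, K, V shapes are not conformable")
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(K.shape[-1])
    logits -= logits.max(axis=-1, keepdims=True)
    weights = np.exp(logits)
    weights /= weights.sum(axis=-1, keepdims=True)
    return weights @ V


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    return layer_norm(x, eps=_LN_EPS) * gain + bias


@dataclass
class RegressorModel:
    """Trained per-feature transformer regressor.

    ``params`` is the flat name→Tensor weight bundle; ``scaler`` holds the
    training-set standardisation (feature means/scales and target
    mean/scale) applied at fit time and inverted at predict time.
    """

    cfg: TransformerConfig
    feature_names: list[str]
    params: dict[str, Tensor]
    scaler: dict[str, np.ndarray]
    train_log: list[dict] = field(default_factory=list)
    val_index: np.ndarray | None = None   # rows of the fit's X used for val

    # -- parameter handling --------------------------------------------------

    @classmethod
    def initialise(cls, feature_names: list[str], cfg: TransformerConfig,
                   rng: np.random.Generator) -> "RegressorModel":
        n, d, ff = len(feature_names), cfg.d_model, cfg.d_ff
        p: dict[str, Tensor] = {
            "embed_w": parameter(rng, n, d, scale=np.sqrt(1.0 / d)),
            "embed_b": zeros_parameter(n, d),
            "embed_ln_g": ones_parameter(d),
            "embed_ln_b": zeros_parameter(d),
            "head_w": parameter(rng, d, 1),
            "head_b": zeros_parameter(1),
        }
        if cfg.pooling == "attention":
            p["pool_q"] = parameter(rng, d, 1)
        for layer in range(cfg.n_layers):
            pre = f"L{layer}_"
            p[pre + "Wq"] = parameter(rng, d, d)
            p[pre + "Wk"] = parameter(rng, d, d)
            p[pre + "Wv"] = parameter(rng, d, d)
            p[pre + "Wo"] = parameter(rng, d, d)
            p[pre + "W1"] = parameter(rng, d, ff)
            p[pre + "b1"] = zeros_parameter(ff)
            p[pre + "W2"] = parameter(rng, ff, d)
            p[pre + "b2"] = zeros_parameter(d)
            p[pre + "ln1_g"] = ones_parameter(d)
            p[pre + "ln1_b"] = zeros_parameter(d)
            p[pre + "ln2_g"] = ones_parameter(d)
            p[pre + "ln2_b"] = zeros_parameter(d)
        scaler = {"x_mean": np.zeros(n), "x_scale": np.ones(n),
                  "y_mean": np.zeros(1), "y_scale": np.ones(1)}
        return cls(cfg=cfg, feature_names=list(feature_names), params=p,
                   scaler=scaler)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_snapshot(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()

    # -- forward pass --------------------------------------------------------

    def _embed(self, X: np.ndarray) -> Tensor:
        """Per-feature linear embedding + LayerNorm + positional encoding."""
        x = Tensor(np.asarray(X, dtype=np.float32)[:, :, None])  # (B, n, 1)
        E = x * self.params["embed_w"] + self.params["embed_b"]
        E = _layer_norm(E, self.params["embed_ln_g"], self.params["embed_ln_b"])
        P = positional_encoding(len(self.feature_names), self.cfg.d_model)
        return E + Tensor(P.astype(np.float32))

    def _multi_head(self, Z: Tensor, layer: int) -> Tensor:
        cfg = self.cfg
        B, T, D = Z.shape
        h, dk = cfg.n_heads, D // cfg.n_heads
        pre = f"L{layer}_"

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dk).swapaxes(1, 2)   # (B, h, T, dk)

        Q = split(Z @ self.params[pre + "Wq"])
        K = split(Z @ self.params[pre + "Wk"])
        V = split(Z @ self.params[pre + "Wv"])
        logits = (Q @ K.swapaxes(-1, -2)) * float(1.0 / np.sqrt(dk))
        attn = softmax(logits, axis=-1) @ V                # (B, h, T, dk)
        concat = attn.swapaxes(1, 2).reshape(B, T, D)
        return concat @ self.params[pre + "Wo"]

    def _encoder_layer(self, Z: Tensor, layer: int,
                       drop_rng: np.random.Generator | None) -> Tensor:
        pre = f"L{layer}_"
        attended = self._dropout(self._multi_head(Z, layer), drop_rng)
        Z1 = _layer_norm(Z + attended,
                         self.params[pre + "ln1_g"], self.params[pre + "ln1_b"])
        hidden = (Z1 @ self.params[pre + "W1"] + self.params[pre + "b1"]).relu()
        ffn = hidden @ self.params[pre + "W2"] + self.params[pre + "b2"]
        ffn = self._dropout(ffn, drop_rng)
        return _layer_norm(Z1 + ffn,
                           self.params[pre + "ln2_g"], self.params[pre + "ln2_b"])

    def _dropout(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.cfg.dropout == 0.0:
            return t
        keep = 1.0 - self.cfg.dropout
        mask = (rng.random(t.shape) < keep).astype(np.float32) / np.float32(keep)
        return t * mask

    def _pool(self, Z: Tensor) -> Tensor:
        if self.cfg.pooling == "mean":
            return Z.mean(axis=1)
        if self.cfg.pooling == "max":
            return Z.max(axis=1)
        scores = (Z @ self.params["pool_q"]).swapaxes(1, 2)   # (B, 1, T)
        return (softmax(scores, axis=-1) @ Z).reshape(
            Z.shape[0], Z.shape[2])

    def _forward(self, X: np.ndarray,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        Z = self._embed(X)
        for layer in range(self.cfg.n_layers):
            Z = self._encoder_layer(Z, layer, drop_rng)
        pooled = self._pool(Z)
        out = pooled @ self.params["head_w"] + self.params["head_b"]
        return out.reshape(X.shape[0])

    # -- public API ----------------------------------------------------------

    def encode_row(self, x: np.ndarray) -> np.ndarray:
        """Token matrix Z = LayerNorm(feature embeddings) + positions."""
        x = np.asarray(x, dtype=float).ravel()
        if x.size != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.size}")
        return self._embed(x[None, :]).data[0]

    def encoder_forward(self, Z: np.ndarray, layer: int) -> np.ndarray:
        """One encoder layer applied to a token matrix (no dropout)."""
        Z = np.asarray(Z, dtype=float)
        single = Z.ndim == 2
        if single:
            Z = Z[None]
        out = self._encoder_layer(Tensor(Z), layer, None).data
        return out[0] if single else out

    def multi_head_attention(self, Z: np.ndarray, layer: int) -> np.ndarray:
        """The multi-head sub-layer alone (exposed for verification)."""
        Z = np.asarray(Z, dtype=float)
        single = Z.ndim == 2
        if single:
            Z = Z[None]
        out = self._multi_head(Tensor(Z), layer).data
        return out[0] if single else out

    def predict(self, X, feature_names: list[str] | None = None) -> np.ndarray:
        """Predict targets for complete rows, in original target units."""
        X = np.asarray(X, dtype=float)
        if feature_names is not None and list(feature_names) != self.feature_names:
            raise ValueError("feature set does not match the fitted model")
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X must be (n_rows, {len(self.feature_names)})")
        if np.isnan(X).any():
            raise ValueError("predict requires complete rows")
        Xs = (X - self.scaler["x_mean"]) / self.scaler["x_scale"]
        ys = self._forward(Xs).data
        return ys * self.scaler["y_scale"][0] + self.scaler["y_mean"][0]

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        weights = {k: v.data for k, v in self.params.items()}
        weights.update({f"scaler_{k}": v for k, v in self.scaler.items()})
        np.savez(path.with_suffix(".npz"), **weights)
        meta = {"config": asdict(self.cfg),
                "feature_names": self.feature_names,
                "train_log": self.train_log}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "RegressorModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = TransformerConfig(**meta["config"])
        model = cls.initialise(meta["feature_names"], cfg,
                               np.random.default_rng(cfg.seed))
        with np.load(path.with_suffix(".npz")) as archive:
            for k in model.params:
                model.params[k].data = archive[k]
            for k in model.scaler:
                model.scaler[k] = archive[f"scaler_{k}"]
        model.train_log = meta["train_log"]
        return model


def fit_regressor(X, y, feature_names: list[str],
                  cfg: TransformerConfig) -> RegressorModel:
    """Train the transformer on complete rows with MSE + Adam.

    ``val_fraction`` rows (seeded shuffle) monitor generalisation; the
    weights with the best validation loss are restored, and training stops
    after ``patience`` epochs without improvement.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one target per row")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("training data must be complete (no NaN)")
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 training rows")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match X")

    rng = np.random.default_rng(cfg.seed)
    model = RegressorModel.initialise(feature_names, cfg, rng)

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0
    y_mean, y_scale = y.mean(), y.std()
    if y_scale == 0.0:
        y_scale = 1.0
    model.scaler = {"x_mean": x_mean, "x_scale": x_scale,
                    "y_mean": np.array([y_mean]),
                    "y_scale": np.array([y_scale])}
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    model.val_index = val_idx.copy()
    if train_idx.size < 2:
        raise ValueError(
            "too few rows after the validation split; reduce batch size "
            "or supply more data")

    optimiser = Adam(list(model.params.values()), lr=cfg.lr)
    best_val = np.inf
    best_weights = model.snapshot()
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            pred = model._forward(Xs[batch], drop_rng=rng)
            loss = ((pred - Tensor(ys[batch].astype(np.float32))) ** 2).mean()
            optimiser.zero_grad()
            loss.backward()
            optimiser.step()
            epoch_loss += float(loss.data) * batch.size
        epoch_loss /= order.size
        val_pred = model._forward(Xs[val_idx]).data
        val_loss = float(np.mean((val_pred - ys[val_idx]) ** 2))
        model.train_log.append({"epoch": epoch, "train_mse": epoch_loss,
                                "val_mse": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.snapshot()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_snapshot(best_weights)
    return model
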