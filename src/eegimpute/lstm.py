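"""LSTM encoder–decoder used to verify imputed tables downstream.

Imputation quality is judged indirectly: a sequence model is trained to
predict the cognitive-state index from the channel amplitudes using only
the rows that were observed complete, and is then evaluated on the rows
whose gaps each imputation method filled.  Because the forecaster and the
test-row set are identical across methods, any difference in test metrics
is attributable to the imputed cell values alone; the method whose filled
cells look most like real data scores best.

The "sequence" fed to the encoder is the ordered list of channel values
within one row (one scalar per channel, in column order) — the encoder
walks across the scalp montage rather than across time, so train/test
membership can be defined row-wise.  The encoder's final hidden and cell
states are passed, via a repeat-vector, to a single-step LSTM decoder
whose output feeds a fully connected head emitting the scalar target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, parameter, zeros_parameter
from .metrics import MetricsReport, compute_metrics
from .tabular import TabularDataset

TARGET_DEFAULT = "Cognitive_State_Index"


@dataclass(frozen=True)
class LstmConfig:
    hidden_size: int = 32
    n_layers: int = 1
    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 64
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")


def _lstm_cell_params(rng, d_in: int, hidden: int, prefix: str) -> dict:
    h4 = 4 * hidden
    p = {
        prefix + "Wx": parameter(rng, d_in, h4),
        prefix + "Wh": parameter(rng, hidden, h4),
        prefix + "b": zeros_parameter(h4),
    }
    # forget-gate bias starts at 1 so early training retains state
    p[prefix + "b"].data[hidden:2 * hidden] = 1.0
    return p


def _lstm_step(x: Tensor, h: Tensor, c: Tensor, params: dict, prefix: str,
               hidden: int) -> tuple[Tensor, Tensor]:
    gates = x @ params[prefix + "Wx"] + h @ params[prefix + "Wh"] \
        + params[prefix + "b"]
    i = gates.narrow(0, hidden).sigmoid()
    f = gates.narrow(hidden, 2 * hidden).sigmoid()
    g = gates.narrow(2 * hidden, 3 * hidden).tanh()
    o = gates.narrow(3 * hidden, 4 * hidden).sigmoid()
    c_new = f * c + i * g
    return o * c_new.tanh(), c_new


@dataclass
class ForecasterModel:
    """Trained encoder–decoder forecaster (scalar one-step horizon)."""

    cfg: LstmConfig
    feature_names: list[str]
    target_name: str
    params: dict[str, Tensor]
    scaler: dict[str, np.ndarray]
    train_log: list[dict] = field(default_factory=list)

    @classmethod
    def initialise(cls, feature_names, target_name, cfg: LstmConfig,
                   rng: np.random.Generator) -> "ForecasterModel":
        H = cfg.hidden_size
        p: dict[str, Tensor] = {}
        for layer in range(cfg.n_layers):
            d_in = 1 if layer == 0 else H
            p.update(_lstm_cell_params(rng, d_in, H, f"enc{layer}_"))
        p.update(_lstm_cell_params(rng, H, H, "dec_"))
        p["out_w"] = parameter(rng, H, 1)
        p["out_b"] = zeros_parameter(1)
        n = len(feature_names)
        scaler = {"x_mean": np.zeros(n), "x_scale": np.ones(n),
                  "y_mean": np.zeros(1), "y_scale": np.ones(1)}
        return cls(cfg=cfg, feature_names=list(feature_names),
                   target_name=target_name, params=p, scaler=scaler)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_snapshot(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()

    def _forward(self, X: np.ndarray) -> Tensor:
        """Encode the per-row channel sequence; decode one step; dense head."""
        cfg = self.cfg
        B, T = X.shape
        H = cfg.hidden_size
        Xf = np.asarray(X, dtype=np.float32)
        zeros = np.zeros((B, H), dtype=np.float32)
        layer_inputs: list = [Tensor(Xf[:, t][:, None]) for t in range(T)]
        h = c = None
        for layer in range(cfg.n_layers):
            h, c = Tensor(zeros), Tensor(zeros)
            outputs = []
            for t in range(T):
                h, c = _lstm_step(layer_inputs[t], h, c, self.params,
                                  f"enc{layer}_", H)
                outputs.append(h)
            layer_inputs = outputs
        # repeat-vector: the context h_n is the decoder's one-step input
        h_dec, _ = _lstm_step(h, h, c, self.params, "dec_", H)
        out = h_dec @ self.params["out_w"] + self.params["out_b"]
        return out.reshape(B)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X must be (n_rows, {len(self.feature_names)})")
        if np.isnan(X).any():
            raise ValueError("predict requires complete rows")
        Xs = (X - self.scaler["x_mean"]) / self.scaler["x_scale"]
        ys = self._forward(Xs).data
        return ys * self.scaler["y_scale"][0] + self.scaler["y_mean"][0]


def fit_forecaster(ds: TabularDataset, target_col: str = TARGET_DEFAULT,
                   cfg: LstmConfig = LstmConfig(),
                   feature_cols: list[str] | None = None,
                   exclude_cols: tuple[str, ...] = ("Timestamp",),
                   ) -> ForecasterModel:
    """Train the encoder–decoder on fully observed rows.

    ``feature_cols`` default to every column except the target and
    ``exclude_cols``, in table order (the sequence order of the encoder).
    """
    if target_col not in ds.col_names:
        raise ValueError(f"target column {target_col!r} absent")
    if feature_cols is None:
        feature_cols = [c for c in ds.col_names
                        if c != target_col and c not in exclude_cols]
    cols = [ds.col_index(c) for c in feature_cols]
    X = ds.values[:, cols]
    y = ds.column(target_col)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("training rows must be fully observed")
    n = X.shape[0]
    if n < 50:
        raise ValueError("need at least 50 complete rows")

    rng = np.random.default_rng(cfg.seed)
    model = ForecasterModel.initialise(feature_cols, target_col, cfg, rng)
    x_mean, x_scale = X.mean(axis=0), X.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0
    y_mean, y_scale = y.mean(), y.std() or 1.0
    model.scaler = {"x_mean": x_mean, "x_scale": x_scale,
                    "y_mean": np.array([y_mean]),
                    "y_scale": np.array([y_scale])}
    Xs = ((X - x_mean) / x_scale).astype(np.float32)
    ys = ((y - y_mean) / y_scale).astype(np.float32)

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    optimiser = Adam(list(model.params.values()), lr=cfg.lr)
    best_val, stale = np.inf, 0
    best_weights = model.snapshot()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            pred = model._forward(Xs[batch])
            loss = ((pred - Tensor(ys[batch])) ** 2).mean()
            optimiser.zero_grad()
            loss.backward()
            optimiser.step()
            epoch_loss += float(loss.data) * batch.size
        val_loss = float(np.mean((model._forward(Xs[val_idx]).data
                                  - ys[val_idx]) ** 2))
        model.train_log.append({"epoch": epoch,
                                "train_mse": epoch_loss / order.size,
                                "val_mse": val_loss})
        if val_loss < best_val - 1e-12:
            best_val, stale = val_loss, 0
            best_weights = model.snapshot()
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_snapshot(best_weights)
    return model


@dataclass
class VerificationReport:
    per_method: dict[str, MetricsReport]
    ranking: list[str]                     # by R², best first
    n_train_rows: int
    n_test_rows: int

    def as_dict(self) -> dict:
        return {"per_method": {k: v.as_dict()
                               for k, v in self.per_method.items()},
                "ranking": list(self.ranking),
                "n_train_rows": self.n_train_rows,
                "n_test_rows": self.n_test_rows}


def compare_imputations(methods: dict[str, TabularDataset],
                        original: TabularDataset,
                        target_col: str = TARGET_DEFAULT,
                        cfg: LstmConfig = LstmConfig(),
                        exclude_cols: tuple[str, ...] = ("Timestamp",),
                        ) -> VerificationReport:
    """Rank imputation methods by the downstream forecaster's test metrics.

    One forecaster is trained on the original complete rows; every
    method's imputed table is then evaluated on the identical set of
    originally incomplete rows.
    """
    feature_cols = [c for c in original.col_names
                    if c != target_col and c not in exclude_cols]
    feat_idx = [original.col_index(c) for c in feature_cols]
    complete = ~original.mask[:, feat_idx].any(axis=1)
    test_rows = np.flatnonzero(~complete)
    if test_rows.size == 0:
        raise ValueError("original table has no incomplete rows to test on")

    train_ds = TabularDataset(
        original.values[complete], list(original.col_names),
        original.row_ids[complete],
        original.mask[complete])
    forecaster = fit_forecaster(train_ds, target_col, cfg,
                                feature_cols=feature_cols)

    y_true = original.values[test_rows, original.col_index(target_col)]
    if np.isnan(y_true).any():
        raise ValueError("target column must be observed on test rows")

    per_method: dict[str, MetricsReport] = {}
    for name, imputed in methods.items():
        if imputed.mask.any():
            raise ValueError(f"method {name!r} left missing cells")
        if not np.array_equal(imputed.row_ids, original.row_ids):
            raise ValueError(f"method {name!r} is not row-aligned")
        cols = [imputed.col_index(c) for c in feature_cols]
        X_test = imputed.values[np.ix_(test_rows, cols)]
        per_method[name] = compute_metrics(y_true,
                                           forecaster.predict(X_test))
    ranking = sorted(per_method, key=lambda m: per_method[m].r2, reverse=True)
    return VerificationReport(per_method=per_method, ranking=ranking,
                              n_train_rows=int(complete.sum()),
                              n_test_rows=int(test_rows.size))
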