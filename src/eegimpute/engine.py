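"""Iterative per-feature imputation loop.

The pipeline mirrors the chained-imputation recipe: mark missing cells and
assign row IDs, move complete columns left and complete rows up, then for
each incomplete feature column — in ascending order of missing-cell count —
train a fresh transformer regressor that maps the currently complete
predictor columns to the target column on the rows where it is observed,
predict the rows where it is missing, and write the predictions into the
table.  Every column completed this way joins the predictor set of the
columns after it.  When all columns are filled the rows are sorted back to
their original order by ID.

An :class:`ImputationTrace` records, per column, how many rows trained the
model, how many cells were imputed, the validation metrics of the fit and
how many epochs ran, so a benchmark run can be audited after the fact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .metrics import MetricsReport, compute_metrics
from .tabular import ColumnPartition, TabularDataset, partition_and_reorder, \
    restore_order
from .transformer import RegressorModel, TransformerConfig, fit_regressor

log = logging.getLogger(__name__)

# columns with fewer observed values than this train nothing useful and
# fall back to mean imputation (always logged)
MIN_OBSERVED_FOR_MODEL = 20


@dataclass
class ColumnTrace:
    column: str
    method: str                       # "transformer" | "mean" | "constant"
    n_train: int
    n_imputed: int
    epochs_run: int = 0
    val_metrics: MetricsReport | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        if self.val_metrics is not None:
            d["val_metrics"] = self.val_metrics.as_dict()
        return d


@dataclass
class ImputationTrace:
    order: list[str] = field(default_factory=list)
    per_column: list[ColumnTrace] = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)
    seed: int = 0

    def as_dict(self) -> dict:
        return {"order": list(self.order),
                "per_column": [c.as_dict() for c in self.per_column],
                "config_snapshot": dict(self.config_snapshot),
                "seed": self.seed}


def plan_order(ds: TabularDataset, partition: ColumnPartition) -> list[str]:
    """Incomplete columns by ascending missing count; ties keep column order.

    Imputing the least-damaged columns first maximises the training rows
    available to the early models, and each completed column strengthens
    the predictor set of the later, harder ones.
    """
    counts = ds.missing_counts()
    cols = list(partition.incomplete_cols)
    return sorted(cols, key=lambda c: (counts[c], cols.index(c)))


def impute_feature(ds: TabularDataset, col: str, predictors: list[str],
                   cfg: TransformerConfig
                   ) -> tuple[TabularDataset, ColumnTrace, RegressorModel | None]:
    """Train on rows where ``col`` is observed, predict where it is missing.

    Returns the updated dataset (observed cells untouched, ``col`` fully
    observed afterwards), the per-column trace entry, and the fitted model
    (None when a fallback path was taken).
    """
    j = ds.col_index(col)
    pred_idx = [ds.col_index(p) for p in predictors]
    if ds.mask[:, pred_idx].any():
        raise ValueError("predictor columns must be complete")

    observed = ~ds.mask[:, j]
    to_fill = np.flatnonzero(~observed)
    values = ds.values.copy()
    mask = ds.mask.copy()
    n_train = int(observed.sum())
    n_imputed = int(to_fill.size)
    if n_imputed == 0:
        return ds.copy(), ColumnTrace(col, "transformer", n_train, 0), None

    y_obs = values[observed, j]
    if n_train < MIN_OBSERVED_FOR_MODEL:
        log.warning("column %s has only %d observed values; "
                    "falling back to mean imputation", col, n_train)
        values[to_fill, j] = y_obs.mean()
        mask[to_fill, j] = False
        out = TabularDataset(values, list(ds.col_names), ds.row_ids.copy(), mask)
        return out, ColumnTrace(col, "mean", n_train, n_imputed), None
    if np.ptp(y_obs) == 0.0:
        # constant column: the regression is degenerate, impute the constant
        values[to_fill, j] = y_obs[0]
        mask[to_fill, j] = False
        out = TabularDataset(values, list(ds.col_names), ds.row_ids.copy(), mask)
        return out, ColumnTrace(col, "constant", n_train, n_imputed), None

    X_train = values[np.ix_(np.flatnonzero(observed), pred_idx)]
    model = fit_regressor(X_train, y_obs, list(predictors), cfg)

    val_metrics = None
    if model.val_index is not None and model.val_index.size >= 2:
        val_rows = np.flatnonzero(observed)[model.val_index]
        try:
            val_metrics = compute_metrics(
                values[val_rows, j],
                model.predict(values[np.ix_(val_rows, pred_idx)]))
        except ValueError:
            val_metrics = None

    values[to_fill, j] = model.predict(values[np.ix_(to_fill, pred_idx)])
    mask[to_fill, j] = False
    out = TabularDataset(values, list(ds.col_names), ds.row_ids.copy(), mask)
    trace = ColumnTrace(col, "transformer", n_train, n_imputed,
                        epochs_run=len(model.train_log),
                        val_metrics=val_metrics)
    return out, trace, model


def run_pipeline(ds: TabularDataset, cfg: TransformerConfig,
                 feature_cols: list[str] | None = None,
                 id_cols: list[str] = (),
                 ) -> tuple[TabularDataset, ImputationTrace]:
    """Impute every incomplete feature column; restore the original layout.

    The returned table has the input's row order (by ID) and column order,
    so it is a drop-in complete replacement for ``ds``.
    ``feature_cols`` defaults to every column not named in ``id_cols``.
    Identifier-like columns (timestamps, the downstream target) are never
    imputation targets nor predictors.
    """
    if feature_cols is None:
        feature_cols = [c for c in ds.col_names if c not in id_cols]
    if any(ds.mask[:, ds.col_index(c)].any() for c in id_cols):
        raise ValueError("id-like columns must not contain missing cells")

    def _original_layout(table: TabularDataset) -> TabularDataset:
        perm = [table.col_index(c) for c in ds.col_names]
        return TabularDataset(table.values[:, perm], list(ds.col_names),
                              table.row_ids, table.mask[:, perm])

    work, part = partition_and_reorder(ds, feature_cols, id_cols)
    trace = ImputationTrace(config_snapshot=asdict(cfg), seed=cfg.seed)
    if not part.incomplete_cols:
        return _original_layout(restore_order(work)), trace
    if not part.complete_cols:
        raise ValueError(
            "no complete feature column to start from; use a baseline "
            "imputer (zero/mean/knn) for this table")
    if not part.complete_row_ids:
        raise ValueError("no fully complete row: the iterative scheme has "
                         "no uncontaminated training data")

    order = plan_order(work, part)
    trace.order = list(order)
    predictors = list(part.complete_cols)
    for idx, col in enumerate(order):
        col_cfg = replace(cfg, seed=(cfg.seed + 7919 * (idx + 1)) % (2**31))
        work, col_trace, _ = impute_feature(work, col, predictors, col_cfg)
        trace.per_column.append(col_trace)
        predictors.append(col)
        log.info("imputed %s: %d cells from %d training rows (%s)",
                 col, col_trace.n_imputed, col_trace.n_train, col_trace.method)
    return _original_layout(restore_order(work)), trace
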