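"""Regression-error metrics used to score imputations and forecasts.

Five measures are reported for every comparison: MAE, MSE, RMSE, MAPE and
the coefficient of determination R².  MAPE divides by the true value, which
is hazardous for EEG amplitudes that cross zero; pairs with |y_true| at or
below ``mape_eps`` are excluded from the MAPE average and the exclusion
count is reported so the omission is visible.

R² is 1 - SSE/SST and is deliberately not clipped: a predictor worse than
the mean yields a negative score.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .tabular import TabularDataset


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    mse: float
    rmse: float
    mape: float          # percent; NaN if every pair was excluded
    r2: float
    n: int
    n_mape_excluded: int

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(y_true, y_pred, mape_eps: float = 1e-8) -> MetricsReport:
    """Score predictions against truth with MAE/MSE/RMSE/MAPE/R².

    Raises ``ValueError`` on length mismatch, empty input, or a constant
    ``y_true`` (for which R² is undefined).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted")
    if y_true.size == 0:
        raise ValueError("empty input")
    if np.isnan(y_true).any() or np.isnan(y_pred).any():
        raise ValueError("inputs contain NaN")

    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    rmse = float(np.sqrt(mse))

    keep = np.abs(y_true) > mape_eps
    n_excluded = int((~keep).sum())
    if keep.any():
        mape = float(100.0 * np.mean(np.abs(err[keep] / y_true[keep])))
    else:
        mape = float("nan")

    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("y_true is constant: R^2 is undefined")
    r2 = 1.0 - float(np.sum(err ** 2)) / sst

    return MetricsReport(mae=mae, mse=mse, rmse=rmse, mape=mape, r2=r2,
                         n=int(y_true.size), n_mape_excluded=n_excluded)


def masked_evaluation(truth, imputed: TabularDataset,
                      mape_eps: float = 1e-8
                      ) -> tuple[dict[str, MetricsReport], MetricsReport]:
    """Score an imputed table on exactly the cells the injector masked.

    ``truth`` is a SyntheticTruth (held_out lists every masked cell with its
    pre-masking value).  Returns (per-column reports, pooled report);
    columns whose held-out truths are constant are skipped in the
    per-column map (their pairs still enter the pooled report).
    """
    if not truth.held_out:
        raise ValueError("no held-out cells to evaluate")
    if imputed.mask.any():
        raise ValueError("imputed table still contains missing cells")
    id_to_pos = {int(r): i for i, r in enumerate(imputed.row_ids)}

    by_col: dict[str, list[tuple[float, float]]] = {}
    pooled_true, pooled_pred = [], []
    for row_id, col, true_val in truth.held_out:
        try:
            i = id_to_pos[int(row_id)]
        except KeyError:
            raise ValueError(f"imputed table lacks row id {row_id}") from None
        pred = float(imputed.values[i, imputed.col_index(col)])
        by_col.setdefault(col, []).append((float(true_val), pred))
        pooled_true.append(float(true_val))
        pooled_pred.append(pred)

    per_column = {}
    for col, pairs in by_col.items():
        t, p = zip(*pairs)
        if len(set(t)) > 1:
            per_column[col] = compute_metrics(t, p, mape_eps)
    pooled = compute_metrics(pooled_true, pooled_pred, mape_eps)
    return per_column, pooled
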