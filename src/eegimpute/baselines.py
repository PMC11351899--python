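"""Reference imputers the transformer pipeline is compared against.

Zero imputation writes 0.0 into every missing cell; mean imputation writes
the column mean of the observed cells; KNN imputation averages the values
of the k nearest donor rows under a missingness-aware Euclidean distance.

The KNN distance between rows ``a`` and ``b`` is computed over the set S
of features observed in both rows and rescaled for the features it could
not see::

    d(a, b) = sqrt( (d_total / |S|) * sum_{s in S} (a_s - b_s)^2 )

which is the nan-aware Euclidean distance of scikit-learn.  Features are
z-scored (observed-cell statistics) before distances are taken so that
columns on different scales contribute comparably; neighbour ties are
broken by smaller row id so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances

from .tabular import TabularDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _filled(ds: TabularDataset, values: np.ndarray) -> TabularDataset:
    return TabularDataset(values, list(ds.col_names), ds.row_ids.copy(),
                          np.zeros_like(ds.mask))


def zero_impute(ds: TabularDataset) -> TabularDataset:
    """Replace every missing cell with 0.0."""
    values = ds.values.copy()
    values[ds.mask] = 0.0
    return _filled(ds, values)


def mean_impute(ds: TabularDataset) -> TabularDataset:
    """Replace missing cells with the observed mean of their column."""
    values = ds.values.copy()
    for j, name in enumerate(ds.col_names):
        col_mask = ds.mask[:, j]
        if not col_mask.any():
            continue
        observed = values[~col_mask, j]
        if observed.size == 0:
            raise ValueError(f"column {name!r} has no observed values")
        values[col_mask, j] = observed.mean()
    return _filled(ds, values)


def knn_impute(ds: TabularDataset, cfg: KnnConfig = KnnConfig()
               ) -> TabularDataset:
    """Impute each missing cell from its k nearest donor rows.

    Donors for cell (i, j) are the rows where column j is observed; the k
    donors closest to row i (nan-aware Euclidean on z-scored features,
    ties by smaller row id) contribute their column-j values unweighted.
    A row sharing no observed feature with any donor falls back to the
    column mean, with a warning.
    """
    X = ds.values.copy()
    if cfg.standardize:
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd[(sd == 0) | np.isnan(sd)] = 1.0
        mu = np.where(np.isnan(mu), 0.0, mu)
        Xz = (X - mu) / sd
    else:
        Xz = X

    # distances on the original (pre-imputation) missingness pattern
    dist = nan_euclidean_distances(Xz, Xz)
    out = X.copy()
    for j in np.flatnonzero(ds.mask.any(axis=0)):
        donors = np.flatnonzero(~ds.mask[:, j])
        if donors.size == 0:
            raise ValueError(
                f"column {ds.col_names[j]!r} has no observed values")
        col_mean = X[donors, j].mean()
        for i in np.flatnonzero(ds.mask[:, j]):
            d = dist[i, donors]
            usable = ~np.isnan(d)
            if not usable.any():
                log.warning(
                    "row id %d shares no observed feature with any donor "
                    "for column %s; falling back to the column mean",
                    ds.row_ids[i], ds.col_names[j])
                out[i, j] = col_mean
                continue
            cand = donors[usable]
            order = np.lexsort((ds.row_ids[cand], d[usable]))
            chosen = cand[order[:min(cfg.k, cand.size)]]
            out[i, j] = X[chosen, j].mean()
    return _filled(ds, out)
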