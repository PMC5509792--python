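"""Feature normalization, per-subgroup PCA and R^2 ranking.

These stages are sklearn transformers so the whole chain composes into an
``sklearn.pipeline.Pipeline`` that is re-fit inside every cross-validation
fold: PCA loadings are estimated on training rows and applied to test rows,
and the R^2 ranking sees training labels only.

PCA is fit separately within each feature subgroup cell (subgroup further
split by frequency band and chromophore, e.g. the 19 channels of alpha-band
power form one cell and become 19 principal-component scores).  PLV columns
pass through untouched.  All principal components are retained; dimension
reduction happens afterwards through the R^2 ranking, since low-eigenvalue
components may still discriminate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

#: metadata fields that define a PCA cell
CELL_KEY = ("subgroup", "nv_type", "chromophore", "band")


class SubjectScaler(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring; constant columns map to exactly zero.

    Fit on one subject's whole feature table (the convention used here:
    normalization precedes cross-validation, so marginal feature statistics
    are shared between folds — a deliberate, documented convention; put the
    scaler inside the fold pipeline for the strictly train-only variant).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


class SubgroupPCA(BaseEstimator, TransformerMixin):
    """PCA fit per (subgroup, band, chromophore) cell; PLV passes through.

    Parameters
    ----------
    meta : DataFrame
        Per-column feature metadata (one row per input column) carrying the
        ``subgroup``, ``nv_type``, ``chromophore``, ``band`` and ``channel``
        fields.  Output column order follows input cell order.
    passthrough : tuple of subgroup names exempt from PCA.
    """

    def __init__(self, meta: pd.DataFrame, passthrough: tuple = ("PLV",)):
        self.meta = meta
        self.passthrough = passthrough

    def _cells(self):
        meta = self.meta.reset_index(drop=True)
        keys = meta[list(CELL_KEY)].apply(tuple, axis=1)
        seen: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            seen.setdefault(k, []).append(i)
        return seen

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.meta):
            raise ValueError("X width does not match feature metadata")
        self.cells_ = []
        out_meta_rows = []
        for key, cols in self._cells().items():
            subgroup = key[0]
            if subgroup in self.passthrough:
                self.cells_.append((key, cols, None))
                out_meta_rows.extend(self.meta.iloc[cols].to_dict("records"))
                continue
            n_comp = min(len(cols), max(X.shape[0] - 1, 1))
            if n_comp < len(cols):
                warnings.warn(
                    f"cell {key}: only {X.shape[0]} training rows; "
                    f"keeping {n_comp} of {len(cols)} components"
                )
            pca = PCA(n_components=n_comp, svd_solver="full")
            pca.fit(X[:, cols])
            self.cells_.append((key, cols, pca))
            base = self.meta.iloc[cols[0]].to_dict()
            for pc in range(n_comp):
                row = dict(base)
                row["channel"] = f"PC{pc + 1}"
                row["eigen_rank"] = pc + 1
                out_meta_rows.append(row)
        self.output_meta_ = pd.DataFrame(out_meta_rows).reset_index(drop=True)
        if "eigen_rank" not in self.output_meta_:
            self.output_meta_["eigen_rank"] = np.nan
        return self

    def transform(self, X):
        check_is_fitted(self, "cells_")
        X = np.asarray(X, dtype=float)
        parts = []
        for _, cols, pca in self.cells_:
            parts.append(X[:, cols] if pca is None else pca.transform(X[:, cols]))
        return np.hstack(parts)


def rank_r2(X: np.ndarray, y: np.ndarray,
            meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rank columns by squared Pearson correlation with the label series.

    The label series codes rest/0-back/..../3-back as 0..4.  Constant
    columns get R^2 = 0.  Ties break deterministically by (subgroup, band,
    channel) lexical order when metadata is supplied, else by column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    denom_y = np.sqrt((yc ** 2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * denom_y)
    r2 = np.where((sx > 0) & (denom_y > 0), r ** 2, 0.0)
    r2 = np.nan_to_num(r2, nan=0.0)

    tbl = pd.DataFrame({"column": np.arange(X.shape[1]), "r2": r2})
    if meta is not None:
        tbl["subgroup"] = meta["subgroup"].to_numpy()
        tbl["band"] = meta["band"].to_numpy()
        tbl["channel"] = meta["channel"].astype(str).to_numpy()
        tbl = tbl.sort_values(
            by=["r2", "subgroup", "band", "channel"],
            ascending=[False, True, True, True], kind="mergesort")
    else:
        tbl = tbl.sort_values(by=["r2", "column"],
                              ascending=[False, True], kind="mergesort")
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return tbl.reset_index(drop=True)


class R2Selector(BaseEstimator, TransformerMixin):
    """Keep the ``n_features`` columns most correlated with the labels.

    ``n_features=None`` keeps everything (still reordered by rank so a
    downstream truncation is a plain slice).  Requires ``y`` at fit time;
    ranking never sees test rows.
    """

    def __init__(self, n_features: int | None = None,
                 meta: pd.DataFrame | None = None):
        self.n_features = n_features
        self.meta = meta

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.n_features is not None and not 1 <= self.n_features <= X.shape[1]:
            raise ValueError(
                f"n_features must be in [1, {X.shape[1]}], got {self.n_features}")
        tbl = rank_r2(X, np.asarray(y), self.meta)
        self.ranking_ = tbl["column"].to_numpy()
        self.r2_ = np.empty(X.shape[1])
        self.r2_[tbl["column"].to_numpy()] = tbl["r2"].to_numpy()
        self.table_ = tbl
        return self

    def _n(self) -> int:
        return len(self.ranking_) if self.n_features is None else self.n_features

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        return np.asarray(X, dtype=float)[:, self.ranking_[:self._n()]]
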