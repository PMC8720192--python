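"""Confound residualization, nearest-neighbour imputation, modality PCA.

The confound design follows the "simple" population-imaging set: scanning
site, age, age squared, sex, age x sex, head size, head motion in resting
and task fMRI, acquisition date and date squared, plus an intercept.
Continuous confounds are centred before squaring/interacting; site is
one-hot encoded with the reference level dropped.

IDPs are reduced separately per modality block (resting, structural, task)
by PCA on standardized variables, retaining the minimal number of components
whose cumulative explained variance reaches the target (default 50%).
Held-out subjects are projected with the stored loadings, never refit.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from . import fields as F

__all__ = [
    "build_confound_design", "residualize", "knn_impute",
    "ConfoundRegressor", "PcaModel", "fit_pca_group", "project", "GroupPCA",
]


def build_confound_design(table: pd.DataFrame) -> pd.DataFrame:
    """Confound design matrix from the confound columns of a table.

    Returns a full-column-rank frame (raises on collinearity) indexed like
    ``table``.
    """
    cols = {}
    site = table["site"].to_numpy()
    levels = np.unique(site)
    for s in levels[1:]:                      # drop reference level
        cols[f"site_{int(s)}"] = (site == s).astype(float)
    age = table["age"].to_numpy(dtype=float)
    age_c = age - age.mean()
    sex = table["sex"].to_numpy(dtype=float)
    date = table["scan_date"].to_numpy(dtype=float)
    date_c = date - date.min()                # days since earliest scan
    date_c = date_c - date_c.mean()
    cols["age"] = age_c
    cols["age_sq"] = age_c ** 2
    cols["sex"] = sex
    cols["age_x_sex"] = age_c * sex
    cols["head_size"] = table["head_size"].to_numpy(dtype=float)
    cols["head_motion_rest"] = table["head_motion_rest"].to_numpy(dtype=float)
    cols["head_motion_task"] = table["head_motion_task"].to_numpy(dtype=float)
    cols["date"] = date_c
    cols["date_sq"] = date_c ** 2
    cols["intercept"] = np.ones(len(table))
    design = pd.DataFrame(cols, index=table.index)
    _check_rank(design.to_numpy(), list(design.columns))
    return design


def _check_rank(D, names):
    if not np.isfinite(D).all():
        raise ValueError("confound design contains missing values")
    sv = np.linalg.svd(D - 0.0, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        # name the most collinear columns via the null-space vector
        _, _, Vt = np.linalg.svd(D)
        null = np.abs(Vt[-1])
        worst = [names[i] for i in np.argsort(null)[::-1][:3]]
        raise ValueError(f"rank-deficient confound design; collinear "
                         f"columns likely among {worst}")


def residualize(data, design) -> np.ndarray:
    """Per-variable least-squares residuals against the confound design.

    ``data`` may contain missing cells; for each variable the fit skips rows
    with a missing value and the residual there stays missing. Residuals of
    observed cells are orthogonal to every design column (over the rows used
    for that variable's fit).
    """
    X = np.asarray(data, dtype=float)
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        D = design.to_numpy(dtype=float)
    else:
        D = np.asarray(design, dtype=float)
        names = [f"c{j}" for j in range(D.shape[1])]
    _check_rank(D, names)
    single = X.ndim == 1
    X = np.atleast_2d(X.T).T
    out = np.full_like(X, np.nan)
    complete = np.isfinite(X).all(axis=1)
    full_cols = np.nonzero(np.isfinite(X).all(axis=0))[0]
    if full_cols.size:                       # fast path: complete variables
        beta, *_ = np.linalg.lstsq(D, X[:, full_cols], rcond=None)
        out[:, full_cols] = X[:, full_cols] - D @ beta
    for j in np.nonzero(~np.isfinite(X).all(axis=0))[0]:
        obs = np.isfinite(X[:, j])
        beta, *_ = np.linalg.lstsq(D[obs], X[obs, j], rcond=None)
        out[obs, j] = X[obs, j] - D[obs] @ beta
    return out[:, 0] if single else out


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer removing confound variance from variables.

    ``fit(X, confounds=D)`` estimates per-variable betas on ``D`` (skipping
    missing rows per variable); ``transform`` subtracts the fitted confound
    contribution. Fitting and transforming the same sample reproduces
    :func:`residualize` exactly. The confound model is meant to be refit
    within each analysis sample rather than transferred.
    """

    def fit(self, X, y=None, *, confounds):
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        D = np.asarray(confounds, dtype=float)
        _check_rank(D, [f"c{j}" for j in range(D.shape[1])])
        self.n_features_in_ = X.shape[1]
        self.coef_ = np.full((D.shape[1], X.shape[1]), np.nan)
        full = np.isfinite(X).all(axis=0)
        if full.any():
            self.coef_[:, full], *_ = np.linalg.lstsq(D, X[:, full],
                                                      rcond=None)
        for j in np.nonzero(~full)[0]:
            obs = np.isfinite(X[:, j])
            self.coef_[:, j], *_ = np.linalg.lstsq(D[obs], X[obs, j],
                                                   rcond=None)
        return self

    def transform(self, X, *, confounds):
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        D = np.asarray(confounds, dtype=float)
        return X - D @ self.coef_


def knn_impute(data, k: int = 1, groups=None) -> np.ndarray:
    """Nearest-neighbour imputation of missing cells.

    A missing cell ``(i, j)`` is filled with the mean of variable ``j`` over
    the ``k`` nearest subjects that observe it; distance is the Euclidean
    distance over the variables observed in both rows, computed within the
    same modality group as ``j`` when ``groups`` (a per-column group label
    array) is given.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(data, dtype=float).copy()
    n, p = X.shape
    if groups is None:
        groups = np.zeros(p, dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        cols = np.nonzero(groups == g)[0]
        Xg = X[:, cols]
        obs = np.isfinite(Xg)
        if not obs.any(axis=1).all():
            raise ValueError("a row is fully missing within a modality group")
        if obs.all():
            continue
        if not obs.any(axis=0).all():
            raise ValueError("a variable has no observed values")
        for i in np.nonzero(~obs.all(axis=1))[0]:
            shared = obs & obs[i]                        # (n, |g|)
            diff = np.where(shared, Xg - Xg[i], 0.0)
            d2 = (diff ** 2).sum(axis=1)
            d2[~shared.any(axis=1)] = np.inf
            d2[i] = np.inf
            for j in np.nonzero(~obs[i])[0]:
                donors = np.nonzero(obs[:, j] & np.isfinite(d2)
                                    & (d2 < np.inf))[0]
                if donors.size == 0:
                    raise ValueError("no donor rows for a missing cell")
                nearest = donors[np.argsort(d2[donors], kind="stable")[:k]]
                X[i, cols[j]] = Xg[nearest, j].mean()
    return X


class PcaModel:
    """Per-modality-group PCA: means, scalings, orthonormal loadings.

    Standardizes variables, eigendecomposes the correlation structure and
    retains the minimal component count whose cumulative explained-variance
    fraction reaches the target. Sign convention: the largest-|loading|
    entry of each component is positive.
    """

    def __init__(self, mean, scale, loadings, explained_variance_ratio,
                 columns=None):
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.loadings = np.asarray(loadings, dtype=float)  # (n_comp, p)
        self.explained_variance_ratio = np.asarray(explained_variance_ratio,
                                                   dtype=float)
        self.columns = list(columns) if columns is not None else None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def cumulative_explained_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist(),
                "loadings": self.loadings.tolist(),
                "explained_variance_ratio":
                    self.explained_variance_ratio.tolist(),
                "columns": self.columns}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PcaModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_pca_group(data, variance_target: float = 0.5,
                  columns=None) -> PcaModel:
    """Fit a :class:`PcaModel` on complete standardized data."""
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must be in (0, 1]")
    X = np.asarray(data, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("PCA input must be complete (impute first)")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0.0] = 1.0
    Z = (X - mean) / scale
    pca = PCA(svd_solver="full").fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    if cum[-1] < variance_target - 1e-9:
        raise ValueError("variance target unreachable: would need more "
                         "components than subjects/variables provide")
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    load = pca.components_[:n_comp]
    flip = np.sign(load[np.arange(n_comp),
                        np.argmax(np.abs(load), axis=1)])
    load = load * flip[:, None]
    return PcaModel(mean, scale, load,
                    pca.explained_variance_ratio_[:n_comp], columns)


def project(data, model: PcaModel) -> np.ndarray:
    """Project (possibly held-out) data with a fitted model — never refit."""
    X = np.asarray(data, dtype=float)
    if X.shape[1] != model.loadings.shape[1]:
        raise ValueError(
            f"variable mismatch: model has {model.loadings.shape[1]} "
            f"columns, data has {X.shape[1]}")
    return ((X - model.mean) / model.scale) @ model.loadings.T


class GroupPCA(BaseEstimator, TransformerMixin):
    """Modality-block PCA transformer over an IDP DataFrame.

    Fits one :class:`PcaModel` per modality group present in the columns and
    concatenates the per-group component scores (resting, structural, task
    order) on transform.
    """

    def __init__(self, variance_target: float = 0.5):
        self.variance_target = variance_target

    def _group_columns(self, columns):
        out = {}
        for g, mods in F.MODALITY_GROUPS.items():
            cols = [c for c in columns if c.startswith("idp_")
                    and F.modality_of(c) in mods]
            if cols:
                out[g] = cols
        return out

    def fit(self, X: pd.DataFrame, y=None):
        self.groups_ = self._group_columns(X.columns)
        self.models_ = {
            g: fit_pca_group(X[cols].to_numpy(), self.variance_target,
                             columns=cols)
            for g, cols in self.groups_.items()}
        self.n_components_ = {g: m.n_components
                              for g, m in self.models_.items()}
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for cols in self.groups_.values()
                   for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing[:5]}")
        return np.hstack([project(X[cols].to_numpy(), self.models_[g])
                          for g, cols in self.groups_.items()])
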