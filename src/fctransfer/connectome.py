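"""Functional-connectivity features and multi-site confound correction.

A subject's functional connectome is the symmetric matrix of Pearson
correlations between region-of-interest (ROI) time series.  With n ROIs the
strict upper triangle gives n(n-1)/2 connectivity features per subject
(4,005 for the standard 90-region parcellation).

Multi-site cohorts carry systematic feature shifts from acquisition site and
demographics.  :func:`site_bias_correct` removes them per feature by ordinary
least squares on site (dummy-coded), age, sex and handedness, keeping
``intercept + residual``, followed by a per-site mean adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ShapeError

__all__ = [
    "ROITimeSeries",
    "ConnectomeDataset",
    "compute_fc_matrix",
    "vectorize_fc",
    "devectorize_fc",
    "edge_index_pairs",
    "site_bias_correct",
]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("site", "age", "sex", "handedness")


@dataclass
class ROITimeSeries:
    """One subject's ROI time series: T timepoints x n ROIs."""

    subject_id: str
    data: np.ndarray
    roi_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 3:
            raise InvalidInputError("time series needs at least 3 timepoints")
        if self.roi_names is not None and len(self.roi_names) != self.data.shape[1]:
            raise ShapeError("roi_names length does not match ROI count")


@dataclass
class ConnectomeDataset:
    """Subjects x FC-feature matrix with labels and covariates.

    ``features[s, e]`` is the connectivity weight of edge e (upper-triangle
    order, see :func:`vectorize_fc`) for subject s.  ``labels`` uses 1 for the
    disease (positive) group and 0 for healthy; it may be None for unlabeled
    corpora (e.g. the offline healthy corpus).  ``covariates`` is indexed like
    ``subject_ids`` with columns site, age, sex, handedness (NaN/empty =
    missing).
    """

    features: np.ndarray
    subject_ids: list[str]
    n_rois: int
    labels: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n_edges = self.n_rois * (self.n_rois - 1) // 2
        if self.features.shape[1] != n_edges:
            raise ShapeError(
                f"expected {n_edges} edge features for {self.n_rois} ROIs, "
                f"got {self.features.shape[1]}"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise InvalidInputError("subject_ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        if not self.roi_names:
            self.roi_names = [f"ROI{i + 1}" for i in range(self.n_rois)]

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]


def compute_fc_matrix(ts: ROITimeSeries) -> np.ndarray:
    """Pearson correlation matrix of the ROI time series.

    Symmetric with unit diagonal, entries in [-1, 1].  A zero-variance ROI
    produces zero correlations with a warning (its pairings are undefined).
    """
    X = ts.data
    sd = X.std(axis=0)
    # relative tolerance: a float-constant series has std ~1e-15, not exactly 0
    zero_var = sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if np.any(zero_var):
        warnings.warn(
            f"subject {ts.subject_id}: {int(zero_var.sum())} zero-variance ROI(s); "
            "their correlations are set to 0",
            RuntimeWarning,
        )
        X = X.copy()
        # give the flat ROI unit variance noise-free placeholder; correlations
        # with it are zeroed below
        X[:, zero_var] = 0.0
        X[0, zero_var] = 1.0
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    if np.any(zero_var):
        C[zero_var, :] = 0.0
        C[:, zero_var] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def edge_index_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle in row-major order."""
    return np.triu_indices(n, k=1)


def vectorize_fc(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major; length n(n-1)/2."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ShapeError("FC matrix must be square")
    if np.max(np.abs(M - M.T)) > tol:
        raise InvalidInputError("FC matrix is not symmetric within tolerance")
    iu, ju = edge_index_pairs(M.shape[0])
    return M[iu, ju]


def devectorize_fc(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_fc` with the unit diagonal restored."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != n * (n - 1) // 2:
        raise ShapeError(f"vector length {v.shape[0]} != n(n-1)/2 for n={n}")
    M = np.zeros((n, n))
    iu, ju = edge_index_pairs(n)
    M[iu, ju] = v
    M = M + M.T
    np.fill_diagonal(M, 1.0)
    return M


def _impute(cov: pd.DataFrame) -> pd.DataFrame:
    """Mode-impute categoricals and mean-impute numerics, with logged counts."""
    cov = cov.copy()
    cov = cov.replace("", np.nan)
    for col in cov.columns:
        n_missing = int(cov[col].isna().sum())
        if n_missing == 0:
            continue
        if col == "age":
            fill = cov[col].astype(float).mean()
        else:
            fill = cov[col].mode(dropna=True).iloc[0]
        logger.info("imputed %d missing values in covariate %r with %r", n_missing, col, fill)
        cov[col] = cov[col].fillna(fill)
    cov["age"] = cov["age"].astype(float)
    return cov


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + site/sex/handedness dummies (reference = first level
    alphabetically) + numeric age.  Collinear columns are dropped with a
    logged warning."""
    cols: list[np.ndarray] = [np.ones(len(cov))]
    names = ["intercept"]
    for col in ("site", "sex", "handedness"):
        levels = sorted(cov[col].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((cov[col].astype(str) == lev).to_numpy(float))
            names.append(f"{col}[{lev}]")
    age = cov["age"].to_numpy(float)
    cols.append(age - age.mean())
    names.append("age")
    D = np.column_stack(cols)

    # Drop collinear columns (e.g. a sex dummy constant within the cohort).
    keep = [0]
    for j in range(1, D.shape[1]):
        trial = D[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear confound column %r", names[j])
    return D[:, keep], [names[j] for j in keep]


def site_bias_correct(ds: ConnectomeDataset) -> ConnectomeDataset:
    """Remove site/age/sex/handedness effects from every FC feature.

    Per feature: fit ``y = b0 + X b + e`` by OLS and keep ``b0 + e``; then
    subtract, per site, the difference between that site's mean and the grand
    mean of the feature.  Covariates are retained in the output for audit.
    Idempotent on noiseless constructions; requires at least two sites.
    """
    if ds.covariates is None:
        raise InvalidInputError("site_bias_correct requires covariates")
    missing = [c for c in COVARIATE_COLUMNS if c not in ds.covariates.columns]
    if missing:
        raise InvalidInputError(f"covariates missing columns: {missing}")
    cov = _impute(ds.covariates[list(COVARIATE_COLUMNS)])
    sites = cov["site"].astype(str).to_numpy()
    if len(np.unique(sites)) < 2:
        raise InvalidInputError("site correction requires at least 2 sites")

    D, names = _design_matrix(cov)
    Y = ds.features
    B, *_ = np.linalg.lstsq(D, Y, rcond=None)
    fitted = D @ B
    # intercept + residual: subtract every modeled effect except the intercept
    adjusted = Y - fitted + B[0]

    grand = adjusted.mean(axis=0)
    for s in np.unique(sites):
        mask = sites == s
        adjusted[mask] -= adjusted[mask].mean(axis=0) - grand

    return replace(ds, features=adjusted, covariates=ds.covariates.copy())
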