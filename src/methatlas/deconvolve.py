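"""Weighted robust constrained deconvolution of bulk methylomes (wRPC).

Each bulk sample's marker-promoter beta vector is regressed on the K
columns of a DNAm reference with Huber's robust M-estimator (or plain
weighted least squares), using per-marker confidence weights as
observation weights. Estimated coefficients are projected onto the
simplex the paper-free way fractions demand: negative coefficients are
set to zero and the rest rescaled to sum to one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import DNAmReference

DEFAULT_HUBER_K = 1.345  # standard 95%-efficiency tuning constant


def _check_reference_rank(X: np.ndarray, cell_types) -> None:
    """Reject rank-deficient references, naming collinear cell types."""
    K = X.shape[1]
    if np.linalg.matrix_rank(X) < K:
        pairs = []
        for i in range(K):
            for j in range(i + 1, K):
                if np.allclose(X[:, i], X[:, j]):
                    pairs.append((str(cell_types[i]), str(cell_types[j])))
        detail = f"; identical columns: {pairs}" if pairs else ""
        raise ValueError(f"reference matrix is rank-deficient{detail}")


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _huber_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    k: float,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    """Huber M-estimation by iteratively reweighted least squares.

    Observation weights ``w`` multiply the robustness weights; the residual
    scale is re-estimated each iteration from the normalized median
    absolute deviation.
    """
    coef = _weighted_lstsq(X, y, w)
    for _ in range(max_iter):
        resid = y - X @ coef
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= np.finfo(float).eps * max(1.0, np.abs(y).max()):
            break  # (near-)perfect fit
        u = np.abs(resid) / (k * scale)
        hub = np.where(u <= 1.0, 1.0, 1.0 / np.maximum(u, 1e-300))
        new = _weighted_lstsq(X, y, w * hub)
        if np.max(np.abs(new - coef)) < tol:
            coef = new
            break
        coef = new
    return coef


def _project_simplex(coef: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero negative coefficients, rescale the rest to sum to one."""
    f = np.clip(coef, 0.0, None)
    total = f.sum()
    if total <= 0:
        return np.zeros_like(f), True
    return f / total, False


def estimate_fractions(
    bulk: pd.DataFrame,
    ref,
    weights: pd.Series | None = None,
    robust: bool = True,
    huber_k: float = DEFAULT_HUBER_K,
    max_iter: int = 50,
    tol: float = 1e-8,
    min_marker_frac: float = 0.3,
) -> pd.DataFrame:
    """Estimate cell-type fractions for every bulk sample.

    Parameters
    ----------
    bulk : DataFrame
        Marker-promoter x sample matrix (beta values for DNAm references;
        expression values when validating expression references). Missing
        values drop the marker for that sample only.
    ref : DNAmReference or DataFrame
        Marker x cell-type reference. A :class:`DNAmReference` supplies
        its own weights unless ``weights`` overrides them.
    weights : Series, optional
        Per-marker observation weights; defaults to the reference weights
        (or unit weights). Fractions are invariant to a common rescaling
        of the weights.
    robust : bool
        Huber loss (default) versus squared loss.
    huber_k : float
        Huber tuning constant in units of the robust residual scale.
    min_marker_frac : float
        Minimum fraction of reference markers that must be present in
        ``bulk``.

    Returns
    -------
    DataFrame
        Samples x cell types; rows are non-negative and sum to one, except
        the all-zero row returned (with a warning) when every raw
        coefficient is non-positive.
    """
    if isinstance(ref, DNAmReference):
        ref_values = ref.values
        if weights is None:
            weights = ref.weights
    else:
        ref_values = ref
    markers = ref_values.index.intersection(bulk.index)
    if len(markers) < min_marker_frac * len(ref_values.index):
        raise ValueError(
            f"only {len(markers)}/{len(ref_values.index)} reference markers "
            f"present in bulk data (need >= {min_marker_frac:.0%})"
        )
    if weights is None:
        weights = pd.Series(1.0, index=ref_values.index)
    w_all = pd.Series(weights).reindex(markers).to_numpy(dtype=float)
    if np.isnan(w_all).any() or (w_all < 0).any():
        raise ValueError("marker weights must be non-negative and complete")
    X_all = ref_values.loc[markers].to_numpy(dtype=float)
    _check_reference_rank(X_all, ref_values.columns)
    Y = bulk.loc[markers].to_numpy(dtype=float)

    K = ref_values.shape[1]
    out = np.zeros((bulk.shape[1], K))
    for s in range(bulk.shape[1]):
        y = Y[:, s]
        ok = ~np.isnan(y) & (w_all > 0)
        if ok.sum() < K:
            warnings.warn(
                f"sample {bulk.columns[s]!r}: fewer usable markers than cell "
                "types; returning the zero row",
                UserWarning,
                stacklevel=2,
            )
            continue
        X, w = X_all[ok], w_all[ok]
        if robust:
            coef = _huber_fit(X, y[ok], w, huber_k, max_iter, tol)
        else:
            coef = _weighted_lstsq(X, y[ok], w)
        frac, degenerate = _project_simplex(coef)
        if degenerate:
            warnings.warn(
                f"sample {bulk.columns[s]!r}: all coefficients non-positive; "
                "returning the zero row",
                UserWarning,
                stacklevel=2,
            )
        out[s] = frac
    return pd.DataFrame(out, index=bulk.columns, columns=ref_values.columns)


def pseudo_bulk(profiles: pd.DataFrame, labels) -> pd.DataFrame:
    """Average single-cell/nucleus profiles into one profile per cell type.

    Per type and gene, the mean over non-missing values; genes missing in
    all cells of a type stay missing so downstream steps can exclude them.
    """
    labels = pd.Series(labels).reindex(profiles.columns)
    if labels.isna().any():
        missing = profiles.columns[labels.isna()][:5].tolist()
        raise ValueError(f"unlabeled profiles: {missing}")
    return profiles.T.groupby(labels.astype(str)).mean().T


class WRPCDeconvolver(BaseEstimator):
    """Weighted robust partial-correlation deconvolution as an estimator.

    ``fit`` stores a reference (and weights), ``transform``/``predict``
    turn a marker x sample bulk matrix into a sample x cell-type fraction
    matrix. See :func:`estimate_fractions` for parameter semantics.
    """

    def __init__(
        self,
        robust: bool = True,
        huber_k: float = DEFAULT_HUBER_K,
        max_iter: int = 50,
        tol: float = 1e-8,
        min_marker_frac: float = 0.3,
    ):
        self.robust = robust
        self.huber_k = huber_k
        self.max_iter = max_iter
        self.tol = tol
        self.min_marker_frac = min_marker_frac

    def fit(self, X, y=None, weights: pd.Series | None = None) -> "WRPCDeconvolver":
        """Store reference ``X`` (DNAmReference or marker x type DataFrame)."""
        if isinstance(X, DNAmReference):
            self.reference_ = X.values
            self.weights_ = X.weights if weights is None else pd.Series(weights)
        else:
            self.reference_ = pd.DataFrame(X)
            self.weights_ = (
                pd.Series(1.0, index=self.reference_.index)
                if weights is None
                else pd.Series(weights)
            )
        _check_reference_rank(
            self.reference_.to_numpy(dtype=float), self.reference_.columns
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "reference_")
        return estimate_fractions(
            X,
            self.reference_,
            weights=self.weights_,
            robust=self.robust,
            huber_k=self.huber_k,
            max_iter=self.max_iter,
            tol=self.tol,
            min_marker_frac=self.min_marker_frac,
        )

    predict = transform
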