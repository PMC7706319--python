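"""Regularized two-view CCA with optional graph-Laplacian feature smoothing.

Given sample-aligned views X_i, X_j, CCA finds weight pairs (w_i, w_j)
maximizing corr(X_i w_i, X_j w_j).  The within-view covariances are
regularized as C~ = C + alpha*I (or C + alpha*(I+L) with a normalized
network Laplacian L, which additionally pulls the weights of interacting
features toward each other), with alpha set by reconditioning to a target
condition number c.  The solver whitens each view with the regularized
covariance square root and takes the SVD of the whitened cross-covariance —
algebraically the standard generalized-eigenproblem formulation, but
numerically stabler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .condition import recondition_alpha, recondition_alpha_laplacian
from .io import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = ["CCAProjection", "fit_cca", "choose_k", "project", "coproject_concat"]


@dataclass
class CCAProjection:
    """Fitted weights, canonical correlations and the regularization record."""

    w_left: np.ndarray  # d_i x k
    w_right: np.ndarray  # d_j x k
    correlations: np.ndarray  # k, descending in [0, 1]
    alpha_left: float
    alpha_right: float
    used_laplacian: tuple[bool, bool]
    mean_left: np.ndarray
    mean_right: np.ndarray
    spectrum: np.ndarray  # full canonical-correlation spectrum pre-truncation

    @property
    def k(self) -> int:
        return self.w_left.shape[1]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, OmicsMatrix) else np.asarray(x, dtype=float)


def choose_k(eigenvalues, percent: float) -> int:
    """Number of components by the cumulative-spectrum rule (PCA-style).

    The largest k whose cumulative share of the total is <= percent/100
    (boundary inclusive), but at least 1.  Entries below 1e-12 of the leading
    value are excluded from the total first; an all-zero spectrum yields 1
    with a warning.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty spectrum")
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    if np.any(ev < 0) or np.any(np.diff(ev) > 1e-12):
        raise ValueError("spectrum must be nonnegative and descending")
    if ev[0] == 0.0:
        logger.warning("all-zero spectrum; keeping 1 component")
        return 1
    ev = np.where(ev >= 1e-12 * ev[0], ev, 0.0)
    frac = np.cumsum(ev) / ev.sum()
    k = int(np.sum(frac <= percent / 100.0 + 1e-15))
    return max(k, 1)


def _inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    """Symmetric pseudo-inverse square root; directions below a relative
    eigenvalue floor are dropped (they carry no usable variance)."""
    eig, vec = np.linalg.eigh(C)
    floor = max(eig[-1], 0.0) * 1e-10
    keep = eig > floor
    if not keep.any():
        raise ValueError("covariance matrix is numerically zero")
    inv = vec[:, keep] / np.sqrt(eig[keep])
    return inv @ vec[:, keep].T


def fit_cca(
    Xi,
    Xj,
    Li: np.ndarray | None = None,
    Lj: np.ndarray | None = None,
    c: float = 4.0,
    percent: float = 85.0,
    alpha: float | tuple[float, float] | None = None,
    k: int | None = None,
) -> CCAProjection:
    """Fit regularized (optionally Laplacian-smoothed) CCA on two views.

    Parameters
    ----------
    Li, Lj:
        Optional normalized graph Laplacians on each view's features.  When
        given, that side is regularized as C + alpha*(I + L) and alpha comes
        from the Weyl-bound reconditioning rule (requires c > 3); otherwise
        C + alpha*I with the exact reconditioning rule.
    alpha:
        Overrides the reconditioning rule — a scalar applied to both sides
        or a (left, right) pair.  ``alpha=0`` gives classical CCA.
    k:
        Overrides the cumulative-spectrum component rule.
    """
    if isinstance(Xi, OmicsMatrix) and isinstance(Xj, OmicsMatrix):
        if Xi.sample_ids != Xj.sample_ids:
            raise ValueError("views are not sample-aligned; run align_samples first")
    Xi, Xj = _values(Xi), _values(Xj)
    n = Xi.shape[0]
    if Xj.shape[0] != n:
        raise ValueError("sample count mismatch")
    if n <= 2:
        raise ValueError("CCA needs more than 2 samples")
    if not (np.all(np.isfinite(Xi)) and np.all(np.isfinite(Xj))):
        raise ValueError("non-finite values in input views")
    for L, X, side in ((Li, Xi, "left"), (Lj, Xj, "right")):
        if L is not None and L.shape != (X.shape[1], X.shape[1]):
            raise ValueError(f"{side} Laplacian dimension does not match the view")

    mean_i, mean_j = Xi.mean(axis=0), Xj.mean(axis=0)
    Xic, Xjc = Xi - mean_i, Xj - mean_j
    Cii = Xic.T @ Xic / (n - 1)
    Cjj = Xjc.T @ Xjc / (n - 1)
    Cij = Xic.T @ Xjc / (n - 1)

    if alpha is None:
        a_i = recondition_alpha_laplacian(Cii, c) if Li is not None else recondition_alpha(Cii, c)
        a_j = recondition_alpha_laplacian(Cjj, c) if Lj is not None else recondition_alpha(Cjj, c)
    else:
        a_i, a_j = (alpha, alpha) if np.isscalar(alpha) else alpha
    if a_i < 0 or a_j < 0:
        raise ValueError("alpha must be nonnegative")

    Cii_t = Cii + a_i * (np.eye(Cii.shape[0]) + (Li if Li is not None else 0.0))
    Cjj_t = Cjj + a_j * (np.eye(Cjj.shape[0]) + (Lj if Lj is not None else 0.0))
    Mi = _inv_sqrt_psd(Cii_t)
    Mj = _inv_sqrt_psd(Cjj_t)
    U, s, Vt = np.linalg.svd(Mi @ Cij @ Mj)
    rho = np.clip(s, 0.0, 1.0)

    kk = k if k is not None else choose_k(rho, percent)
    kk = min(kk, len(rho))
    w_left = Mi @ U[:, :kk]
    w_right = Mj @ Vt[:kk].T

    # determinism: each left column's largest-|entry| positive; the right
    # column follows the same flip so cov(u_left, u_right) stays >= 0
    for m in range(kk):
        col = w_left[:, m]
        if col[int(np.argmax(np.abs(col)))] < 0:
            w_left[:, m] = -col
            w_right[:, m] = -w_right[:, m]

    return CCAProjection(
        w_left=w_left,
        w_right=w_right,
        correlations=rho[:kk],
        alpha_left=float(a_i),
        alpha_right=float(a_j),
        used_laplacian=(Li is not None, Lj is not None),
        mean_left=mean_i,
        mean_right=mean_j,
        spectrum=rho,
    )


def project(X, W: np.ndarray, mean: np.ndarray | None = None) -> np.ndarray:
    """Canonical variables U = (X - mean) W (column-centered projection)."""
    X = _values(X)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} features, W expects {W.shape[0]}"
        )
    if mean is None:
        mean = X.mean(axis=0)
    return (X - mean) @ W


def coproject_concat(
    Ui: np.ndarray,
    Uj: np.ndarray,
    sample_ids: list[str] | None = None,
    node: str = "node",
) -> OmicsMatrix:
    """Concatenate the two sides' canonical variables into one pseudo-view.

    Output column k+m is exactly Uj's column m; feature IDs are
    ``<node>:<side>:<component>``.
    """
    Ui, Uj = np.asarray(Ui, dtype=float), np.asarray(Uj, dtype=float)
    if Ui.shape[0] != Uj.shape[0]:
        raise ValueError("row count mismatch between the two sides")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(Ui.shape[0])]
    feature_ids = [f"{node}:L:{m}" for m in range(Ui.shape[1])] + [
        f"{node}:R:{m}" for m in range(Uj.shape[1])
    ]
    return OmicsMatrix(
        sample_ids=list(sample_ids),
        feature_ids=feature_ids,
        values=np.hstack([Ui, Uj]),
        name=node,
    )
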