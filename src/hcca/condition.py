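"""Condition-number analysis of (cross-)covariance matrices.

The condition number kappa = sigma_max / sigma_min measures how close a
matrix is to singular.  The hierarchy builder merges the dataset pair whose
cross-covariance has the *smallest* kappa (the pair least similar to
singular, i.e. the most robustly correlated), and the same machinery sets
the ridge strength alpha by "reconditioning": choosing alpha so the
regularized within-view covariance attains a prescribed condition number c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OmicsMatrix

# below this relative floor a singular value is treated as exactly zero
SINGULAR_RTOL = 1e-14

__all__ = [
    "PairScore",
    "condition_number",
    "cross_condition",
    "pair_table",
    "select_pair",
    "recondition_alpha",
    "recondition_alpha_laplacian",
]


@dataclass(frozen=True)
class PairScore:
    """kappa of the cross-covariance of views i and j (i < j)."""

    i: int
    j: int
    kappa: float

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError("PairScore requires i < j")
        if not (self.kappa >= 1 or np.isinf(self.kappa)):
            raise ValueError(f"kappa must be >= 1, got {self.kappa}")


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, OmicsMatrix) else np.asarray(x, dtype=float)


def condition_number(M) -> float:
    """sigma_max / sigma_min over the min(n, d) singular values of M.

    Returns +inf when sigma_min < sigma_max * 1e-14 (numerical singularity),
    including the all-zero matrix.
    """
    M = _values(M)
    if M.size == 0:
        raise ValueError("empty matrix")
    s = np.linalg.svd(np.atleast_2d(M), compute_uv=False)
    smax, smin = s[0], s[-1]
    if smin < smax * SINGULAR_RTOL or smax == 0.0:
        return float("inf")
    return float(smax / smin)


def _cross_cov(Xi: np.ndarray, Xj: np.ndarray) -> np.ndarray:
    n = Xi.shape[0]
    Xic = Xi - Xi.mean(axis=0)
    Xjc = Xj - Xj.mean(axis=0)
    return Xic.T @ Xjc / (n - 1)


def cross_condition(Xi, Xj) -> float:
    """Condition number of the centered cross-covariance of two views."""
    if isinstance(Xi, OmicsMatrix) and isinstance(Xj, OmicsMatrix):
        if Xi.sample_ids != Xj.sample_ids:
            raise ValueError("views are not sample-aligned; run align_samples first")
    Xi, Xj = _values(Xi), _values(Xj)
    if Xi.shape[0] != Xj.shape[0]:
        raise ValueError(f"sample count mismatch: {Xi.shape[0]} vs {Xj.shape[0]}")
    if Xi.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return condition_number(_cross_cov(Xi, Xj))


def pair_table(views: list) -> list[PairScore]:
    """kappa of every unordered view pair, in lexicographic (i, j) order."""
    if len(views) < 2:
        raise ValueError("need at least 2 views")
    scores = []
    for i in range(len(views)):
        for j in range(i + 1, len(views)):
            scores.append(PairScore(i, j, cross_condition(views[i], views[j])))
    return scores

def select_pair(views: list) -> tuple[int, int]:
    """The pair with the smallest cross-covariance condition number.

    Ties break toward the lexicographically smallest (i, j); a numerically
    singular pair (kappa = inf) is never chosen while a finite pair exists.
    """
    best = None
    for score in pair_table(views):
        if best is None or score.kappa < best.kappa:
            best = score
    return best.i, best.j


def _extreme_eigs(C: np.ndarray) -> tuple[float, float]:
    C = _values(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, float(np.abs(C).max()))):
        raise ValueError("expected a symmetric matrix")
    eig = np.linalg.eigvalsh(C)
    lmin = float(max(eig[0], 0.0))  # clip PSD round-off
    lmax = float(eig[-1])
    if lmax < 0:
        raise ValueError("matrix is not positive semidefinite")
    return lmax, lmin


def recondition_alpha(C, c: float) -> float:
    """Ridge strength making kappa(C + alpha*I) exactly c.

    alpha = (lambda_max - c * lambda_min) / (c - 1) when kappa(C) > c, else 0
    (a negative ridge would be unsound, so alpha is clamped at zero).
    """
    if not c > 1:
        raise ValueError("target condition number c must be > 1")
    lmax, lmin = _extreme_eigs(C)
    if lmax == 0.0:
        return 0.0
    kappa = float("inf") if lmin < lmax * SINGULAR_RTOL else lmax / lmin
    if kappa <= c:
        return 0.0
    return (lmax - c * lmin) / (c - 1)


def recondition_alpha_laplacian(C, c: float) -> float:
    """Ridge strength guaranteeing kappa(C + alpha*(I+L)) <= c for any
    normalized Laplacian L.

    The eigenvalues of I+L lie in [1, 3], so by Weyl's inequality
    lambda_max(C + alpha(I+L)) <= lambda_max(C) + 3 alpha and
    lambda_min >= lambda_min(C) + alpha; solving the bound for c gives
    alpha = (lambda_max - c * lambda_min) / (c - 3), which requires c > 3.
    """
    if not c > 3:
        raise ValueError(
            "target condition number c must be > 3: the Weyl bound's "
            "denominator is c - 3 because eigenvalues of I+L reach 3"
        )
    lmax, lmin = _extreme_eigs(C)
    if lmax == 0.0:
        return 0.0
    kappa = float("inf") if lmin < lmax * SINGULAR_RTOL else lmax / lmin
    if kappa <= c:
        return 0.0
    return max(0.0, (lmax - c * lmin) / (c - 3))
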