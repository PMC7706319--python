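"""Multiview baselines: pairwise CCA (SUMCOR), tensor CCA (CP-ALS), stacking.

PCCA maximizes the summed pairwise correlations among N views; it is solved
here through the standard SUMCOR relaxation — a generalized eigenproblem of
the off-diagonal block cross-covariance against the block-diagonal
regularized covariance — followed by per-view rescaling to the unit-variance
constraints.  TCCA maximizes the order-N correlation: the covariance tensor
of the whitened views is decomposed by rank-k CP alternating least squares.
Both reduce to ordinary two-view CCA at N=2, which is the module's primary
correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import scipy.linalg

from .cca import _inv_sqrt_psd, choose_k
from .condition import recondition_alpha
from .io import OmicsMatrix

__all__ = ["MultiviewProjection", "fit_pcca", "fit_tcca", "stack_views"]


@dataclass
class MultiviewProjection:
    """Per-view weights under w_v^T C~_vv w_v = 1 constraints."""

    weights: list[np.ndarray]  # d_v x k each
    method: str
    alphas: list[float]
    means: list[np.ndarray]
    eigenvalues: np.ndarray | None = None  # PCCA generalized spectrum
    objective_trace: list[float] = field(default_factory=list)  # TCCA ALS fit
    converged: bool = True

    @property
    def k(self) -> int:
        return self.weights[0].shape[1]

    def canonical_variables(self, views: list) -> list[np.ndarray]:
        out = []
        for X, W, mu in zip(views, self.weights, self.means):
            V = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, float)
            out.append((V - mu) @ W)
        return out

    def pairwise_correlation_sum(self, views: list, component: int = 0) -> float:
        """Achieved sum over pairs of corr(u_i, u_j) for one component."""
        us = [u[:, component] for u in self.canonical_variables(views)]
        total = 0.0
        for i in range(len(us)):
            for j in range(i + 1, len(us)):
                total += float(np.corrcoef(us[i], us[j])[0, 1])
        return total


def _prep(views, c, alpha):
    """Center, compute regularized covariances and whiteners per view."""
    if len(views) < 2:
        raise ValueError("need at least 2 views")
    vals = [v.values if isinstance(v, OmicsMatrix) else np.asarray(v, float) for v in views]
    n = vals[0].shape[0]
    ids0 = views[0].sample_ids if isinstance(views[0], OmicsMatrix) else None
    for v, V in zip(views, vals):
        if V.shape[0] != n:
            raise ValueError("sample count mismatch")
        if ids0 is not None and isinstance(v, OmicsMatrix) and v.sample_ids != ids0:
            raise ValueError("views are not sample-aligned; run align_samples first")
    means = [V.mean(axis=0) for V in vals]
    Xc = [V - mu for V, mu in zip(vals, means)]
    covs = [X.T @ X / (n - 1) for X in Xc]
    if alpha is None:
        alphas = [recondition_alpha(C, c) for C in covs]
    elif np.isscalar(alpha):
        alphas = [float(alpha)] * len(covs)
    else:
        alphas = [float(a) for a in alpha]
    covs_t = [C + a * np.eye(C.shape[0]) for C, a in zip(covs, alphas)]
    return n, Xc, means, covs_t, alphas


def fit_pcca(
    views: list,
    c: float = 4.0,
    percent: float = 85.0,
    alpha=None,
    k: int | None = None,
) -> MultiviewProjection:
    """Pairwise (multiset) CCA via the SUMCOR generalized eigenproblem."""
    n, Xc, means, covs_t, alphas = _prep(views, c, alpha)
    dims = [X.shape[1] for X in Xc]
    D = scipy.linalg.block_diag(*covs_t)
    B = np.zeros_like(D)
    offs = np.concatenate([[0], np.cumsum(dims)])
    for i in range(len(Xc)):
        for j in range(len(Xc)):
            if i == j:
                continue
            Cij = Xc[i].T @ Xc[j] / (n - 1)
            B[offs[i] : offs[i + 1], offs[j] : offs[j + 1]] = Cij
    eigval, eigvec = scipy.linalg.eigh(B, D)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if k is None:
        spectrum = np.clip(eigval[eigval > 0], 0, None)
        k = choose_k(np.sort(spectrum)[::-1], percent) if spectrum.size else 1
    k = min(k, eigvec.shape[1])

    weights = []
    for v in range(len(Xc)):
        Wv = eigvec[offs[v] : offs[v + 1], :k].copy()
        for m in range(k):
            norm2 = float(Wv[:, m] @ covs_t[v] @ Wv[:, m])
            if norm2 > 1e-300:
                Wv[:, m] /= np.sqrt(norm2)
        weights.append(Wv)
    # sign convention: view 0 largest-|entry| positive, other views follow
    # the sign of their correlation with view 0's canonical variable
    for m in range(k):
        col0 = weights[0][:, m]
        if col0[int(np.argmax(np.abs(col0)))] < 0:
            for Wv in weights:
                Wv[:, m] = -Wv[:, m]
    u0 = Xc[0] @ weights[0]
    for v in range(1, len(Xc)):
        uv = Xc[v] @ weights[v]
        for m in range(k):
            if float(u0[:, m] @ uv[:, m]) < 0:
                weights[v][:, m] = -weights[v][:, m]
    return MultiviewProjection(
        weights=weights,
        method="pcca",
        alphas=alphas,
        means=means,
        eigenvalues=eigval,
    )


# ---------------------------------------------------------------------------
# CP-ALS tensor CCA


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    """Columnwise Kronecker product; first matrix varies slowest (C order)."""

    def kr(A, B):
        r = A.shape[1]
        return np.einsum("ir,jr->ijr", A, B).reshape(-1, r)

    return reduce(kr, mats)


def cp_als(
    T: np.ndarray,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-8,
    rng: np.random.Generator | None = None,
):
    """Rank-k CP decomposition by alternating least squares.

    Factors are initialized from the leading left singular vectors of each
    mode's matricization (deterministic); pass ``rng`` to add random
    restarts columns when k exceeds a mode's rank.  Returns
    ``(factors, objective_trace, converged)`` where the objective is the fit
    1 - ||T - T_hat||_F / ||T||_F, non-decreasing across sweeps (each ALS
    subproblem is an exact least-squares solve).
    """
    N = T.ndim
    factors = []
    for v in range(N):
        Uv, sv, _ = np.linalg.svd(_unfold(T, v), full_matrices=False)
        r = min(k, Uv.shape[1])
        F = Uv[:, :r]
        if r < k:
            extra = (
                rng.standard_normal((T.shape[v], k - r))
                if rng is not None
                else np.ones((T.shape[v], k - r))
            )
            F = np.hstack([F, extra / np.linalg.norm(extra, axis=0)])
        factors.append(F)

    normT = float(np.sqrt((T**2).sum()))
    if normT == 0.0:
        return factors, [1.0], True
    trace: list[float] = []
    prev_err = np.inf
    converged = False
    for _ in range(max_iter):
        for v in range(N):
            others = [factors[m] for m in range(N) if m != v]
            Kr = _khatri_rao(others)
            G = reduce(np.multiply, [F.T @ F for F in others])
            factors[v] = _unfold(T, v) @ Kr @ np.linalg.pinv(G)
        # residual via the normal-equations identity
        full_kr = _khatri_rao(factors[1:])
        M0 = factors[0] @ full_kr.T
        err = float(np.sqrt(max(((_unfold(T, 0) - M0) ** 2).sum(), 0.0)))
        trace.append(1.0 - err / normT)
        if np.isfinite(prev_err) and prev_err - err <= tol * max(prev_err, 1e-300):
            converged = True
            break
        prev_err = err
    return factors, trace, converged


def fit_tcca(
    views: list,
    k: int,
    c: float = 4.0,
    max_iter: int = 200,
    tol: float = 1e-8,
    alpha=None,
    element_budget: float = 1e7,
    rng: np.random.Generator | None = None,
) -> MultiviewProjection:
    """Tensor CCA: CP-ALS on the covariance tensor of the whitened views."""
    n, Xc, means, covs_t, alphas = _prep(views, c, alpha)
    dims = [X.shape[1] for X in Xc]
    if np.prod([float(d) for d in dims]) > element_budget:
        raise ValueError(
            f"covariance tensor would hold {np.prod(dims):.3g} elements "
            f"(budget {element_budget:.3g}); reduce dimensionality first"
        )
    whiteners = [_inv_sqrt_psd(C) for C in covs_t]
    Y = [X @ M for X, M in zip(Xc, whiteners)]
    letters = "abcdefgh"[: len(Y)]
    subscripts = ",".join(f"n{ch}" for ch in letters) + "->" + letters
    T = np.einsum(subscripts, *Y) / (n - 1)

    factors, trace, converged = cp_als(T, k, max_iter=max_iter, tol=tol, rng=rng)
    if max_iter == 0:
        converged = False
    # order components by CP weight (product of factor column norms), descending
    norms = np.vstack([np.linalg.norm(F, axis=0) for F in factors])
    lam = norms.prod(axis=0)
    order = np.argsort(-lam, kind="stable")
    weights = []
    for M, F in zip(whiteners, factors):
        F = F[:, order]
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(np.linalg.norm(F, axis=0) > 0, F / np.linalg.norm(F, axis=0), F)
        weights.append(M @ F)
    for m in range(weights[0].shape[1]):
        col0 = weights[0][:, m]
        if col0[int(np.argmax(np.abs(col0)))] < 0:
            for Wv in weights:
                Wv[:, m] = -Wv[:, m]
    u0 = Xc[0] @ weights[0]
    for v in range(1, len(Xc)):
        uv = Xc[v] @ weights[v]
        for m in range(weights[0].shape[1]):
            if float(u0[:, m] @ uv[:, m]) < 0:
                weights[v][:, m] = -weights[v][:, m]
    return MultiviewProjection(
        weights=weights,
        method="tcca",
        alphas=alphas,
        means=means,
        objective_trace=trace,
        converged=converged,
    )


def stack_views(views: list[OmicsMatrix]) -> OmicsMatrix:
    """Horizontal concatenation with view-name-prefixed feature IDs."""
    if not views:
        raise ValueError("empty view list")
    if len(views) == 1:
        v = views[0]
        return OmicsMatrix(
            sample_ids=list(v.sample_ids),
            feature_ids=[f"{v.name or 'view0'}:{f}" for f in v.feature_ids],
            values=v.values.copy(),
            name="stacked",
        )
    ids0 = views[0].sample_ids
    for v in views[1:]:
        if v.sample_ids != ids0:
            raise ValueError("views are not sample-aligned; run align_samples first")
    feature_ids = []
    for i, v in enumerate(views):
        prefix = v.name or f"view{i}"
        feature_ids.extend(f"{prefix}:{f}" for f in v.feature_ids)
    return OmicsMatrix(
        sample_ids=list(ids0),
        feature_ids=feature_ids,
        values=np.hstack([v.values for v in views]),
        name="stacked",
    )
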