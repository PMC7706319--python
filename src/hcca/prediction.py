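"""Phenotype prediction on joint representations, and its evaluation.

Epsilon-insensitive support vector regression with a Gaussian kernel
K(x, x') = exp(-gamma ||x - x'||^2) predicts a continuous phenotype from the
integrated features; hyperparameters are picked by grid search with k-fold
cross-validation on the training split only.  Performance is summarized by
R^2 about the *training* target mean, mean squared error, and the fraction
of held-out predictions falling within a relative margin of the truth,
over many repeated random train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.svm import SVR

from .io import OmicsMatrix, RunConfig

__all__ = [
    "EvaluationReport",
    "default_grid",
    "fit_predict_svr",
    "r_squared",
    "margin_proportion",
    "repeated_evaluation",
    "repeated_evaluation_strict",
]

MARGINS = (0.05, 0.10, 0.15)


@dataclass
class EvaluationReport:
    """Per-repeat scores of the repeated random-split evaluation."""

    r2: np.ndarray
    mse: np.ndarray
    margin_proportions: dict[float, np.ndarray]
    seeds: list[int]
    chosen_params: list[dict]
    sd_defined: bool = True

    @property
    def n_repeats(self) -> int:
        return len(self.r2)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2, ddof=1)) if self.sd_defined else 0.0

    def summary(self) -> dict:
        out = {
            "n_repeats": self.n_repeats,
            "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2,
            "mean_mse": float(np.mean(self.mse)),
        }
        for m, vals in self.margin_proportions.items():
            out[f"margin_{int(round(m * 100))}pct"] = float(np.mean(vals))
        return out


def default_grid(U_train: np.ndarray, seed: int = 0) -> dict:
    """Default SVR grid: box constraint, epsilon, and kernel widths around
    the median-pairwise-distance heuristic gamma0 = 1 / (2 median^2)."""
    rng = np.random.default_rng(seed)
    n = U_train.shape[0]
    idx = rng.choice(n, size=min(n, 200), replace=False)
    d = euclidean_distances(U_train[idx])
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if not np.isfinite(med) or med <= 0:
        med = 1.0
    gamma0 = 1.0 / (2.0 * med * med)
    return {
        "C": [0.1, 1.0, 10.0, 100.0],
        "epsilon": [0.01, 0.1, 1.0],
        "gamma": [0.25 * gamma0, gamma0, 4.0 * gamma0],
    }


def reduced_grid(U_train: np.ndarray, seed: int = 0) -> dict:
    """Coarser grid for large repeated-evaluation runs (12 combinations)."""
    g = default_grid(U_train, seed)
    return {
        "C": [1.0, 10.0, 100.0],
        "epsilon": [0.01, 0.1],
        "gamma": [g["gamma"][0], g["gamma"][1]],
    }


def fit_predict_svr(
    U_train: np.ndarray,
    y_train: np.ndarray,
    U_test: np.ndarray,
    grid: dict | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    return_params: bool = False,
):
    """Grid-searched Gaussian-kernel SVR; test rows never touch fitting."""
    U_train = np.asarray(U_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    U_test = np.asarray(U_test, dtype=float)
    if len(U_train) < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} training samples")
    if not np.all(np.isfinite(y_train)):
        raise ValueError("non-finite target values")
    if grid is None:
        grid = default_grid(U_train, seed)
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ValueError("empty hyperparameter grid")
    search = GridSearchCV(
        SVR(kernel="rbf"),
        grid,
        scoring="neg_mean_squared_error",
        cv=KFold(n_splits=cv_folds, shuffle=True, random_state=seed % 2**31),
        n_jobs=1,
        refit=True,
    )
    search.fit(U_train, y_train)
    pred = search.predict(U_test)
    if return_params:
        return pred, dict(search.best_params_)
    return pred


def r_squared(y_true, y_pred, baseline_mean: float) -> float:
    """1 - SS_res / SS_tot with SS_tot about the training-set mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    denom = float(((y_true - baseline_mean) ** 2).sum())
    if denom == 0:
        raise ValueError(
            "all test targets equal the baseline mean; R^2 is undefined"
        )
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / denom


def margin_proportion(y_true, y_pred, margin_fraction: float, absolute: bool = False) -> float:
    """Fraction of predictions within ``margin_fraction * |y_i|`` of the
    truth (or within the absolute margin ``margin_fraction`` if requested)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if margin_fraction <= 0:
        raise ValueError("margin_fraction must be > 0")
    if absolute:
        band = margin_fraction
    else:
        if np.any(y_true == 0):
            raise ValueError(
                "relative margin undefined where y_true == 0; use absolute=True"
            )
        band = margin_fraction * np.abs(y_true)
    return float(np.mean(np.abs(y_pred - y_true) <= band))


def repeated_evaluation(
    U,
    y,
    config: RunConfig,
    n_repeats: int | None = None,
    grid: str | dict | None = None,
    cv_folds: int = 10,
) -> EvaluationReport:
    """Repeated random-split SVR evaluation of one representation.

    Each repeat draws a fresh train/test split at ``config.test_fraction``,
    grid-searches the SVR on the training folds, and scores the held-out
    samples; split seeds derive from ``config.seed`` plus the repeat index.
    ``grid`` may be an explicit parameter grid, ``"reduced"`` for the coarse
    grid, or None for the default grid.
    """
    Uv = U.values if isinstance(U, OmicsMatrix) else np.asarray(U, dtype=float)
    yv = np.asarray(y, dtype=float)
    if Uv.shape[0] != len(yv):
        raise ValueError("representation and phenotype sample counts differ")
    if Uv.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    n_repeats = n_repeats if n_repeats is not None else config.n_repeats
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    r2s, mses, params, seeds = [], [], [], []
    margins = {m: [] for m in MARGINS}
    for rep in range(n_repeats):
        seed = (config.seed + rep) % 2**31
        seeds.append(seed)
        idx_train, idx_test = train_test_split(
            np.arange(Uv.shape[0]),
            test_size=config.test_fraction,
            random_state=seed,
        )
        g = grid
        if grid == "reduced":
            g = reduced_grid(Uv[idx_train], seed)
        pred, best = fit_predict_svr(
            Uv[idx_train],
            yv[idx_train],
            Uv[idx_test],
            grid=g,
            cv_folds=cv_folds,
            seed=seed,
            return_params=True,
        )
        baseline = float(yv[idx_train].mean())
        r2s.append(r_squared(yv[idx_test], pred, baseline))
        mses.append(float(np.mean((yv[idx_test] - pred) ** 2)))
        params.append(best)
        absolute = bool(np.any(yv[idx_test] == 0))
        scale = float(np.abs(yv).mean()) if absolute else None
        for m in MARGINS:
            margins[m].append(
                margin_proportion(
                    yv[idx_test],
                    pred,
                    m * scale if absolute else m,
                    absolute=absolute,
                )
            )
    return EvaluationReport(
        r2=np.array(r2s),
        mse=np.array(mses),
        margin_proportions={m: np.array(v) for m, v in margins.items()},
        seeds=seeds,
        chosen_params=params,
        sd_defined=n_repeats > 1,
    )


def repeated_evaluation_strict(
    views,
    y,
    config: RunConfig,
    networks=None,
    n_repeats: int | None = None,
    grid: str | dict | None = None,
    cv_folds: int = 10,
) -> EvaluationReport:
    """Leakage-free variant of :func:`repeated_evaluation`.

    The default protocol learns the joint representation once on all samples
    and then splits; here the hierarchy is refit on each repeat's training
    rows only and held-out rows are mapped through the stored weights, so no
    test information can reach the representation.  Slower by a factor of
    ``n_repeats`` on the integration side.
    """
    from .hierarchy import fit_hcca, transform

    yv = np.asarray(y, dtype=float)
    n = views[0].n_samples
    if len(yv) != n:
        raise ValueError("phenotype length does not match the views")
    n_repeats = n_repeats if n_repeats is not None else config.n_repeats
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    r2s, mses, params, seeds = [], [], [], []
    margins = {m: [] for m in MARGINS}
    all_ids = views[0].sample_ids
    for rep in range(n_repeats):
        seed = (config.seed + rep) % 2**31
        seeds.append(seed)
        idx_train, idx_test = train_test_split(
            np.arange(n), test_size=config.test_fraction, random_state=seed
        )
        train_ids = [all_ids[i] for i in idx_train]
        test_ids = [all_ids[i] for i in idx_test]
        model = fit_hcca([v.take_samples(train_ids) for v in views],
                         networks=networks, config=config)
        U_train = model.root.U.values
        U_test = transform(model, [v.take_samples(test_ids) for v in views]).values
        g = grid
        if grid == "reduced":
            g = reduced_grid(U_train, seed)
        pred, best = fit_predict_svr(
            U_train, yv[idx_train], U_test, grid=g, cv_folds=cv_folds,
            seed=seed, return_params=True,
        )
        baseline = float(yv[idx_train].mean())
        r2s.append(r_squared(yv[idx_test], pred, baseline))
        mses.append(float(np.mean((yv[idx_test] - pred) ** 2)))
        params.append(best)
        absolute = bool(np.any(yv[idx_test] == 0))
        scale = float(np.abs(yv).mean()) if absolute else None
        for m in MARGINS:
            margins[m].append(
                margin_proportion(
                    yv[idx_test], pred, m * scale if absolute else m, absolute=absolute
                )
            )
    return EvaluationReport(
        r2=np.array(r2s),
        mse=np.array(mses),
        margin_proportions={m: np.array(v) for m, v in margins.items()},
        seeds=seeds,
        chosen_params=params,
        sd_defined=n_repeats > 1,
    )
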