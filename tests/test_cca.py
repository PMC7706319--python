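import numpy as np
import pytest
from scipy.optimize import minimize

from hcca.cca import choose_k, coproject_concat, fit_cca, project
from hcca.io import InteractionNetwork


def corr_objective_oracle(X, Y, n_starts=12, seed=0):
    """Directly maximize |corr(X w1, Y w2)| over weight pairs (numerical
    optimization, independent of the whitening/SVD solver)."""
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    di, dj = X.shape[1], Y.shape[1]

    def neg_corr(w):
        u = Xc @ w[:di]
        v = Yc @ w[di:]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            return 0.0
        return -abs(float(u @ v) / (nu * nv))

    best = 0.0
    for _ in range(n_starts):
        w0 = rng.standard_normal(di + dj)
        res = minimize(neg_corr, w0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        best = max(best, -res.fun)
    return best


class TestFitCCA:
    def test_identical_views_have_unit_first_correlation(self, rng):
        X = rng.standard_normal((30, 4))
        proj = fit_cca(X, X.copy(), alpha=0.0)
        assert proj.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_one_feature_views_give_pearson_correlation(self):
        x = np.array([[1.0], [2.0], [3.0]])
        y = np.array([[1.0], [3.0], [2.0]])
        proj = fit_cca(x, y, alpha=0.0)
        # centered vectors (-1,0,1) and (-1,1,0): corr = 1/2
        assert proj.correlations[0] == pytest.approx(0.5, abs=1e-10)

    def test_independent_views_below_permutation_null(self, rng):
        X = rng.standard_normal((500, 3))
        Y = rng.standard_normal((500, 3))
        rho = fit_cca(X, Y, alpha=0.0).correlations[0]
        null = []
        for _ in range(200):
            perm = rng.permutation(500)
            null.append(fit_cca(X[perm], Y, alpha=0.0).correlations[0])
        assert rho <= np.quantile(null, 0.99)

    def test_matches_direct_objective_maximization(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(12, 30))
            X = rng.standard_normal((n, int(rng.integers(1, 5))))
            Y = rng.standard_normal((n, int(rng.integers(1, 5))))
            proj = fit_cca(X, Y, alpha=0.0)
            oracle = corr_objective_oracle(X, Y)
            assert proj.correlations[0] == pytest.approx(oracle, abs=1e-4)

    def test_invariance_under_invertible_transforms(self, rng):
        X = rng.standard_normal((60, 4))
        Y = rng.standard_normal((60, 3))
        A = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        rho0 = fit_cca(X, Y, alpha=0.0).correlations
        rho1 = fit_cca(X @ A, Y, alpha=0.0).correlations
        np.testing.assert_allclose(rho0, rho1, atol=1e-6)

    def test_first_correlation_non_increasing_in_alpha(self, rng):
        X = rng.standard_normal((40, 6))
        Y = X @ rng.standard_normal((6, 5)) + 0.5 * rng.standard_normal((40, 5))
        rhos = [fit_cca(X, Y, alpha=a).correlations[0] for a in (0.0, 0.1, 1.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(rhos, rhos[1:]))

    def test_generalized_orthogonality_of_weights(self, rng):
        X = rng.standard_normal((50, 5))
        Y = rng.standard_normal((50, 4))
        proj = fit_cca(X, Y, c=4.0, k=3)
        n = X.shape[0]
        Xc = X - X.mean(0)
        C = Xc.T @ Xc / (n - 1) + proj.alpha_left * np.eye(5)
        np.testing.assert_allclose(proj.w_left.T @ C @ proj.w_left, np.eye(3), atol=1e-8)

    def test_sign_convention_largest_entry_positive(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 5))
        proj = fit_cca(X, Y, c=4.0)
        for m in range(proj.k):
            col = proj.w_left[:, m]
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_cca(rng.standard_normal((2, 2)), rng.standard_normal((2, 2)))

    def test_laplacian_smooths_weights_within_modules(self):
        # true signal constant over a connected network module: the fitted
        # weights should vary less inside the module with smoothing than
        # without (paired comparison over seeds)
        smoother = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, d = 60, 12
            z = rng.standard_normal(n)
            module = np.arange(6)
            X = 0.6 * rng.standard_normal((n, d))
            X[:, module] += z[:, None]  # constant loading on the module
            Y = z[:, None] + 0.3 * rng.standard_normal((n, 1))
            net = InteractionNetwork()
            for i in module:
                for j in module:
                    if i < j:
                        net.add_edge(f"f{i}", f"f{j}", 1.0)
            L = net.normalized_laplacian([f"f{i}" for i in range(d)])
            w_plain = fit_cca(X, Y, c=4.0, k=1).w_left[:, 0]
            w_smooth = fit_cca(X, Y, Li=L, c=4.0, k=1).w_left[:, 0]
            if np.var(w_smooth[module] / np.abs(w_smooth).max()) < np.var(
                w_plain[module] / np.abs(w_plain).max()
            ):
                smoother += 1
        assert smoother >= 15


class TestChooseK:
    @pytest.mark.parametrize(
        "spectrum, percent, expected",
        [
            ((1.0, 1.0, 1.0, 1.0), 85.0, 3),  # cumulative 25/50/75/100%
            ((0.9, 0.5, 0.3, 0.2, 0.1), 85.0, 3),  # 1.7/2.0 = 85% inclusive
            ((2.0,), 85.0, 1),
            ((1.0, 1.0), 100.0, 2),
            ((5.0, 1e-15), 85.0, 1),  # tiny tail excluded from the total
        ],
    )
    def test_cumulative_rule(self, spectrum, percent, expected):
        assert choose_k(np.array(spectrum), percent) == expected

    def test_all_zero_spectrum_returns_one(self, caplog):
        assert choose_k(np.zeros(4), 85.0) == 1

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError):
            choose_k(np.array([0.1, 0.5]), 85.0)  # ascending


class TestProject:
    def test_unit_basis_vector_selects_centered_column(self, rng):
        X = rng.standard_normal((10, 3))
        e1 = np.eye(3)[:, [1]]
        np.testing.assert_allclose(
            project(X, e1)[:, 0], X[:, 1] - X[:, 1].mean(), atol=1e-12
        )

    def test_zero_matrix_projects_to_zero(self):
        assert np.all(project(np.zeros((4, 3)), np.ones((3, 2))) == 0)

    def test_matches_explicit_matrix_product(self, rng):
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((3, 2))
        np.testing.assert_allclose(
            project(X, W), (X - X.mean(0)) @ W, atol=1e-12
        )

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            project(rng.standard_normal((4, 3)), rng.standard_normal((2, 2)))


class TestCoprojectConcat:
    def test_left_block_first_and_column_identity(self, rng):
        Ui = rng.standard_normal((5, 2))
        Uj = rng.standard_normal((5, 3))
        out = coproject_concat(Ui, Uj, node="n1")
        assert out.values.shape == (5, 5)
        np.testing.assert_array_equal(out.values[:, :2], Ui)
        for m in range(3):
            np.testing.assert_array_equal(out.values[:, 2 + m], Uj[:, m])
        assert out.feature_ids[0] == "n1:L:0" and out.feature_ids[2] == "n1:R:0"

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            coproject_concat(rng.standard_normal((4, 1)), rng.standard_normal((5, 1)))
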