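import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcca.condition import (
    condition_number,
    cross_condition,
    pair_table,
    recondition_alpha,
    recondition_alpha_laplacian,
    select_pair,
)


def random_spd(rng, d, spread=3.0):
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    eig = 10.0 ** rng.uniform(-spread / 2, spread / 2, size=d)
    return Q @ np.diag(eig) @ Q.T


def er_normalized_laplacian(rng, d, p=0.3):
    A = (rng.random((d, d)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    deg = A.sum(1)
    dinv = np.where(deg > 0, 1 / np.sqrt(np.where(deg > 0, deg, 1)), 0.0)
    return np.eye(d) - dinv[:, None] * A * dinv[None, :]


class TestConditionNumber:
    def test_identity(self):
        assert condition_number(np.eye(3)) == 1.0

    def test_diagonal_ratio(self):
        assert condition_number(np.diag([4.0, 1.0])) == pytest.approx(4.0)

    def test_rectangular_uses_singular_values(self):
        M = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        # SVD oracle: singular values {2, 1}
        s = np.linalg.svd(M, compute_uv=False)
        assert condition_number(M) == pytest.approx(s[0] / s[-1]) == pytest.approx(2.0)

    def test_singular_matrix_is_infinite(self):
        assert np.isinf(condition_number(np.zeros((3, 3))))
        assert np.isinf(condition_number(np.ones((3, 3))))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            condition_number(np.zeros((0, 0)))

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, s):
        rng = np.random.default_rng(7)
        M = rng.standard_normal((5, 4))
        assert condition_number(s * M) == pytest.approx(condition_number(M), rel=1e-9)


class TestCrossCondition:
    def test_self_pair_equals_own_covariance_condition(self, rng):
        X = rng.standard_normal((30, 5))
        C = np.cov(X, rowvar=False)
        assert cross_condition(X, X) == pytest.approx(condition_number(C), rel=1e-9)

    def test_invariant_under_orthogonal_rotation(self, rng):
        X = rng.standard_normal((40, 6))
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        assert cross_condition(X, X @ Q) == pytest.approx(
            cross_condition(X, X), rel=1e-8
        )

    def test_shared_full_rank_structure_conditions_better_than_noise(self):
        # strongly shared pair (rotations of one latent space) vs independent;
        # n must comfortably exceed d or the latent Wishart itself is
        # ill-conditioned and the comparison is a coin flip
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, d = 150, 40
            Z = rng.standard_normal((n, d))
            Q1, _ = np.linalg.qr(rng.standard_normal((d, d)))
            Q2, _ = np.linalg.qr(rng.standard_normal((d, d)))
            Xa = Z @ Q1 + 0.3 * rng.standard_normal((n, d))
            Xb = Z @ Q2 + 0.3 * rng.standard_normal((n, d))
            Xc = rng.standard_normal((n, d))
            if cross_condition(Xa, Xb) < cross_condition(Xa, Xc):
                wins += 1
        assert wins == 20

    def test_sample_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_condition(rng.standard_normal((10, 3)), rng.standard_normal((11, 3)))


class TestSelectPair:
    def test_two_views_only_pair(self, rng):
        assert select_pair([rng.standard_normal((20, 3)) for _ in range(2)]) == (0, 1)

    def test_agrees_with_brute_force_enumeration(self, rng):
        for _ in range(10):
            views = [rng.standard_normal((25, int(rng.integers(2, 6)))) for _ in range(4)]
            table = {
                (i, j): cross_condition(views[i], views[j])
                for i in range(4)
                for j in range(i + 1, 4)
            }
            assert select_pair(views) == min(table, key=lambda p: (table[p], p))

    def test_singular_pair_never_selected(self, rng):
        good = rng.standard_normal((20, 3))
        shared = good + 0.1 * rng.standard_normal((20, 3))
        degenerate = np.zeros((20, 3))
        views = [degenerate, good, shared]
        assert select_pair(views) == (1, 2)
        kappas = {((s.i, s.j)): s.kappa for s in pair_table(views)}
        assert np.isinf(kappas[(0, 1)]) and np.isinf(kappas[(0, 2)])

    def test_fewer_than_two_views_rejected(self, rng):
        with pytest.raises(ValueError):
            select_pair([rng.standard_normal((10, 2))])


class TestReconditionAlpha:
    def test_known_eigenvalues(self):
        C = np.diag([10.0, 1.0])
        a = recondition_alpha(C, 4.0)
        # oracle: solve (10 + a) / (1 + a) = 4 -> a = 2
        assert a == pytest.approx(2.0)
        assert condition_number(C + a * np.eye(2)) == pytest.approx(4.0)

    def test_well_conditioned_matrix_gets_zero(self):
        assert recondition_alpha(np.diag([2.0, 1.0]), 4.0) == 0.0

    def test_c_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            recondition_alpha(np.eye(2), 1.0)

    def test_exactness_over_random_spd(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            C = random_spd(rng, int(rng.integers(2, 10)))
            if condition_number(C) <= 4.0:
                continue
            a = recondition_alpha(C, 4.0)
            assert a > 0
            kappa = condition_number(C + a * np.eye(C.shape[0]))
            assert abs(kappa - 4.0) < 1e-8
            checked += 1


class TestReconditionAlphaLaplacian:
    def test_known_eigenvalues_bound(self):
        C = np.diag([10.0, 1.0])
        a = recondition_alpha_laplacian(C, 4.0)
        assert a == pytest.approx(6.0)
        # Weyl bound: (10 + 3a) / (1 + a) = 4 at a = 6
        rng = np.random.default_rng(1)
        for _ in range(10):
            L = er_normalized_laplacian(rng, 2, p=1.0)
            kappa = condition_number(C + a * (np.eye(2) + L))
            assert kappa <= 4.0 + 1e-8

    def test_already_well_conditioned_gets_zero(self):
        assert recondition_alpha_laplacian(np.diag([2.0, 1.0]), 4.0) == 0.0

    def test_c_at_most_three_rejected(self):
        with pytest.raises(ValueError, match="Weyl"):
            recondition_alpha_laplacian(np.eye(2), 3.0)

    def test_bound_holds_over_random_graph_laplacians(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            d = int(rng.integers(3, 12))
            C = random_spd(rng, d)
            a = recondition_alpha_laplacian(C, 4.0)
            L = er_normalized_laplacian(rng, d, p=float(rng.uniform(0.1, 0.9)))
            kappa = condition_number(C + a * (np.eye(d) + L))
            if a > 0:
                assert kappa <= 4.0 + 1e-8
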