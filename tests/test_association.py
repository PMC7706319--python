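import numpy as np
import pytest
from scipy.stats import pearsonr

from hcca.association import (
    export_gene_list,
    factor_loadings,
    nearest_features,
    path_loadings,
)
from hcca.hierarchy import fit_hcca
from hcca.io import RunConfig
from hcca.simulate import gen_multiview


class TestFactorLoadings:
    def test_feature_equal_to_canonical_variable_loads_one(self, make_m, rng):
        U = rng.standard_normal((20, 2))
        X = make_m(np.column_stack([U[:, 0], rng.standard_normal(20)]))
        table = factor_loadings(X, U)
        assert table.loadings[0, 0] == pytest.approx(1.0)
        assert table.loadings[0, 1] == pytest.approx(
            pearsonr(U[:, 0], U[:, 1]).statistic
        )

    def test_orthogonal_feature_loads_zero(self, make_m):
        U = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        X = make_m([[0.0], [0.0], [1.0], [1.0]])  # wait, not orthogonal; replaced below
        # build a feature exactly uncorrelated with both canonical variables
        f = np.array([1.0, 1.0, -1.0, -1.0])
        assert abs(f @ U[:, 0]) < 1e-12 and abs(f @ U[:, 1]) < 1e-12
        X = make_m(f[:, None])
        table = factor_loadings(X, U)
        np.testing.assert_allclose(table.loadings[0], [0.0, 0.0], atol=1e-12)

    def test_matches_pearson_oracle_elementwise(self, make_m, rng):
        X = make_m(rng.standard_normal((5, 4)))
        U = rng.standard_normal((5, 2))
        table = factor_loadings(X, U)
        for i in range(4):
            for j in range(2):
                expect = pearsonr(X.values[:, i], U[:, j]).statistic
                assert table.loadings[i, j] == pytest.approx(expect, abs=1e-10)

    def test_constant_feature_flagged_with_zero_loading(self, make_m, rng):
        X = make_m(np.column_stack([np.full(10, 3.0), rng.standard_normal(10)]))
        table = factor_loadings(X, rng.standard_normal((10, 2)))
        assert table.constant_mask[0] and not table.constant_mask[1]
        np.testing.assert_array_equal(table.loadings[0], [0.0, 0.0])

    def test_too_few_samples_rejected(self, make_m, rng):
        with pytest.raises(ValueError):
            factor_loadings(make_m(np.ones((2, 1))), rng.standard_normal((2, 2)))


@pytest.fixture(scope="module")
def fitted():
    views, truth = gen_multiview(
        n=80, dims=[6, 6, 5], r_shared=3, noise_sd=0.3, loading="dense", seed=3
    )
    # pin the first merge so view 0 sits on a two-node root path
    model = fit_hcca(views, config=RunConfig(seed=3), fixed_first_pair=(0, 1))
    return views, model


class TestPathLoadings:

    def test_first_merge_matches_direct_loadings(self, fitted):
        views, model = fitted
        view_index = 0
        node = model.nodes_on_path(view_index)[0]
        level = int(node.node_id.removeprefix("merge"))
        table = path_loadings(model, views, view_index, level)
        # recompute directly from the node's own canonical variables
        proj = node.projection
        side_is_left = view_index in node.child_left.leaf_indices()
        child = node.child_left if side_is_left else node.child_right
        W = proj.w_left if side_is_left else proj.w_right
        mu = proj.mean_left if side_is_left else proj.mean_right
        U = (child.U.values - mu) @ W
        direct = factor_loadings(views[view_index], U)
        np.testing.assert_allclose(table.loadings, direct.loadings, atol=1e-12)

    def test_level_beyond_root_rejected(self, fitted):
        views, model = fitted
        with pytest.raises(ValueError, match="valid levels"):
            path_loadings(model, views, 0, 99)

    def test_levels_differ_when_later_view_adds_signal(self, fitted):
        views, model = fitted
        levels = [
            int(n.node_id.removeprefix("merge")) for n in model.nodes_on_path(0)
        ]
        assert len(levels) >= 2
        t1 = path_loadings(model, views, 0, levels[0], n_components=1)
        t2 = path_loadings(model, views, 0, levels[1], n_components=1)
        assert not np.allclose(t1.loadings, t2.loadings, atol=1e-6)


class TestNearestFeatures:
    def make_tables(self):
        from hcca.association import LoadingTable

        a = LoadingTable(["target"], np.array([[0.5, 0.5]]), node_id="m1")
        b = LoadingTable(
            ["w", "x", "y", "z"],
            np.array([[0.5, 0.5], [0.0, 0.0], [0.6, 0.5], [-0.5, -0.5]]),
            node_id="m1",
        )
        return a, b

    def test_exact_match_ranks_first_with_zero_distance(self):
        a, b = self.make_tables()
        ranked = nearest_features(a, b, "target", m=4)
        assert ranked[0] == ("w", 0.0)
        # hand-computed distance table: x at sqrt(0.5), y at 0.1, z at sqrt(2)
        assert [f for f, _ in ranked] == ["w", "y", "x", "z"]
        assert ranked[1][1] == pytest.approx(0.1)

    def test_m_larger_than_table_returns_all(self):
        a, b = self.make_tables()
        assert len(nearest_features(a, b, "target", m=100)) == 4

    def test_ties_break_by_feature_id(self):
        from hcca.association import LoadingTable

        a = LoadingTable(["t"], np.array([[0.0, 0.0]]), node_id="n")
        b = LoadingTable(
            ["beta", "alpha"], np.array([[0.3, 0.0], [0.0, 0.3]]), node_id="n"
        )
        ranked = nearest_features(a, b, "t", m=2)
        assert [f for f, _ in ranked] == ["alpha", "beta"]

    def test_cross_node_comparison_refused(self):
        a, b = self.make_tables()
        b.node_id = "other"
        with pytest.raises(ValueError, match="different nodes"):
            nearest_features(a, b, "target")

    def test_unknown_target_rejected(self):
        a, b = self.make_tables()
        with pytest.raises(KeyError, match="nope"):
            nearest_features(a, b, "nope")

    def test_zero_noise_shared_factor_is_mutual_nearest(self):
        # transitivity in the regime where it literally holds: feature g of
        # view A and feature e of view B load on the same factor, no noise
        views, truth = gen_multiview(
            n=50, dims=[3, 3], r_shared=1, noise_sd=0.0, loading="modular", seed=5
        )
        model = fit_hcca(views, config=RunConfig())
        node = model.nodes_on_path(0)[0]
        level = int(node.node_id.removeprefix("merge"))
        ta = path_loadings(model, views, 0, level, n_components=1)
        tb = path_loadings(model, views, 1, level, n_components=1)
        g = views[0].feature_ids[truth.module_map[0][0][0]]
        e = views[1].feature_ids[truth.module_map[1][0][0]]
        (top, dist) = nearest_features(ta, tb, g, m=1, n_components=1)[0]
        assert dist == pytest.approx(0.0, abs=1e-6)
        assert e in [f for f, d in nearest_features(ta, tb, g, m=3, n_components=1)]


class TestExport:
    def test_tsv_layout_and_determinism(self, tmp_path):
        ranked = [("g1", 0.0), ("g2", 0.25), ("g3", 1.5)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_gene_list(ranked, p1)
        export_gene_list(ranked, p2)
        lines = p1.read_text().splitlines()
        assert lines[0] == "rank\tfeature_id\tdistance"
        assert len(lines) == 4
        assert lines[1].startswith("1\tg1\t")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "e.tsv"
        export_gene_list([], p)
        assert p.read_text() == "rank\tfeature_id\tdistance\n"
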