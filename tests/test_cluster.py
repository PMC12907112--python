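"""Cluster-based permutation tests against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import ndimage, stats

import tgdecode as tg


def brute_force_1d(scores, chance, alpha=0.05):
    """Exhaustive sign-flip null of the max cluster mass (one-sided)."""
    centered = scores - chance
    n = len(centered)
    thr = stats.t.ppf(1.0 - alpha, n - 1)

    def t_map(x):
        sd = x.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = x.mean(0) / (sd / np.sqrt(n))
        return np.nan_to_num(t)

    def max_mass(x):
        t = t_map(x)
        lab, k = ndimage.label(t > thr)
        return max((t[lab == i].sum() for i in range(1, k + 1)), default=0.0)

    null = np.array([max_mass(centered * np.array(s)[:, None])
                     for s in itertools.product([1, -1], repeat=n)])
    obs_t = t_map(centered)
    lab, k = ndimage.label(obs_t > thr)
    out = []
    for i in range(1, k + 1):
        mass = obs_t[lab == i].sum()
        out.append((np.flatnonzero(lab == i),
                    mass, np.mean(null >= mass - 1e-12)))
    return out


class TestOneSampleCbpt:
    def test_exact_p_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        scores = 0.5 + rng.normal(0, 0.05, (5, 6))
        scores[:, 2:5] += 0.12
        res = tg.one_sample_cbpt(scores, 0.5,
                                 tg.ClusterConfig(n_perm=5000, seed=1))
        assert res.exact
        oracle = brute_force_1d(scores, 0.5)
        assert len(res.clusters) == len(oracle)
        for c, (idx, mass, p) in zip(res.clusters, oracle):
            assert np.array_equal(np.sort(c.indices), np.sort(idx))
            assert c.mass == pytest.approx(mass)
            assert c.p == pytest.approx(p)

    def test_scores_at_chance_give_empty_result(self):
        scores = np.full((6, 10), 0.5)
        res = tg.one_sample_cbpt(scores, 0.5, tg.ClusterConfig(n_perm=100))
        assert res.clusters == []
        assert not res.mask.any()

    def test_monte_carlo_within_binomial_band_of_exact(self):
        """Random-permutation p stays inside the 99% binomial interval of
        the exhaustively enumerated p over a battery of toy problems."""
        rng = np.random.default_rng(42)
        n_subj, n_perm = 11, 500  # 2^11 = 2048 > 500 -> Monte-Carlo mode
        checked = 0
        for trial in range(20):
            scores = 0.5 + rng.normal(0, 0.06, (n_subj, 7))
            scores[:, 2:5] += rng.uniform(0.02, 0.08)
            exact = tg.one_sample_cbpt(
                scores, 0.5, tg.ClusterConfig(n_perm=4096, seed=trial))
            assert exact.exact
            mc = tg.one_sample_cbpt(
                scores, 0.5, tg.ClusterConfig(n_perm=n_perm, seed=trial))
            assert not mc.exact
            for ce, cm in zip(exact.clusters, mc.clusters):
                lo, hi = stats.binom.interval(0.99, n_perm, ce.p)
                assert (lo + 1) / (n_perm + 1) - 1e-12 <= cm.p \
                    <= (hi + 1) / (n_perm + 1) + 1e-12
                checked += 1
        assert checked >= 15

    def test_p_values_bounded(self):
        rng = np.random.default_rng(3)
        scores = 0.5 + rng.normal(0, 0.08, (12, 30))
        res = tg.one_sample_cbpt(scores, 0.5,
                                 tg.ClusterConfig(n_perm=200, seed=0))
        for c in res.clusters:
            assert 1.0 / (200 + 1) <= c.p <= 1.0

    def test_mask_is_union_of_significant_clusters(self):
        rng = np.random.default_rng(4)
        scores = 0.5 + rng.normal(0, 0.05, (10, 40))
        scores[:, 5:15] += 0.1
        res = tg.one_sample_cbpt(scores, 0.5,
                                 tg.ClusterConfig(n_perm=500, seed=0))
        manual = np.zeros(40, dtype=bool)
        for c in res.significant_clusters:
            manual[c.indices] = True
        assert np.array_equal(res.mask, manual)

    def test_sign_symmetry_one_sided(self):
        rng = np.random.default_rng(5)
        scores = 0.5 + rng.normal(0, 0.03, (8, 12))
        scores[:, 4:8] += 0.15
        pos = tg.one_sample_cbpt(scores, 0.5,
                                 tg.ClusterConfig(n_perm=256, seed=0))
        neg = tg.one_sample_cbpt(1.0 - scores, 0.5,
                                 tg.ClusterConfig(n_perm=256, seed=0))
        assert pos.any_significant
        # the planted effect sits in the untested tail after negation:
        # only noise clusters remain and none reaches significance
        assert neg.significant_clusters == []
        two = tg.one_sample_cbpt(
            1.0 - scores, 0.5,
            tg.ClusterConfig(n_perm=256, seed=0, tail="two-sided"))
        assert any(c.mass < 0 for c in two.significant_clusters)

    def test_2d_grid_uses_orthogonal_adjacency(self):
        # two diagonal-touching blobs must form separate clusters; cells
        # outside the blobs sit exactly at chance (zero variance -> t = 0)
        scores = np.full((8, 6, 6), 0.5)
        rng = np.random.default_rng(6)
        scores[:, 1:3, 1:3] += 0.3 + rng.normal(0, 0.01, (8, 2, 2))
        scores[:, 3:5, 3:5] += 0.3 + rng.normal(0, 0.01, (8, 2, 2))
        res = tg.one_sample_cbpt(scores, 0.5,
                                 tg.ClusterConfig(n_perm=256, seed=0))
        sizes = sorted(len(c.indices) for c in res.significant_clusters)
        assert sizes == [4, 4]

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            tg.one_sample_cbpt(np.full((1, 5), 0.6), 0.5)


class TestPairedSensorCbpt:
    def _path_graph(self, n):
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_isolated_suprathreshold_electrode_forms_no_cluster(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.3, (8, 5))
        b = rng.normal(0, 0.3, (8, 5))
        a[:, 2] += 5.0  # strong effect on one electrode, neighbours null
        res = tg.paired_sensor_cbpt(a, b, self._path_graph(5),
                                    tg.ClusterConfig(n_perm=256,
                                                     tail="two-sided"))
        assert res.clusters == []

    def test_identical_conditions_empty(self):
        a = np.random.default_rng(2).normal(0, 1, (6, 4))
        res = tg.paired_sensor_cbpt(a, a.copy(), self._path_graph(4),
                                    tg.ClusterConfig(n_perm=64,
                                                     tail="two-sided"))
        assert res.clusters == []
        assert not res.mask.any()

    def test_exact_p_matches_exhaustive_label_swap_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (6, 4))
        b = rng.normal(0, 1, (6, 4))
        a[:, :2] += 3.5
        adj = self._path_graph(4)
        res = tg.paired_sensor_cbpt(
            a, b, adj, tg.ClusterConfig(n_perm=5000, tail="two-sided"))
        assert res.exact
        d = a - b
        thr = stats.t.ppf(0.975, 5)

        def max_mass(x):
            t = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(6))
            best = 0.0
            for sign in (1, -1):
                lab, k = ndimage.label(sign * t > thr)
                for i in range(1, k + 1):
                    if (lab == i).sum() >= 2:
                        best = max(best, abs(t[lab == i].sum()))
            return best

        null = np.array([max_mass(d * np.array(s)[:, None])
                         for s in itertools.product([1, -1], repeat=6)])
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert np.array_equal(np.sort(c.indices), [0, 1])
        assert c.p == pytest.approx(np.mean(null >= abs(c.mass) - 1e-12))


class TestTriangulationAdjacency:
    def test_three_points_fully_connected(self):
        m = tg.Montage(("A", "B", "C"),
                       np.array([[0, 0, 60.0], [80, 0, 60], [40, 70, 60]]))
        _, adj = tg.triangulation_adjacency(m)
        assert adj.sum() == 6  # 3 undirected edges
        assert not adj.diagonal().any()

    def test_unit_square_resolves_tie_lexicographically(self):
        m = tg.Montage(("A", "B", "C", "D"),
                       np.array([[0, 0, 50.0], [0, 100, 50],
                                 [100, 0, 50], [100, 100, 50]]))
        names, adj = tg.triangulation_adjacency(m)
        edges = sorted(tuple(sorted((names[i], names[j])))
                       for i, j in zip(*np.nonzero(np.triu(adj))))
        assert edges == [("A", "B"), ("A", "C"), ("A", "D"),
                         ("B", "D"), ("C", "D")]

    def test_default_montage_graph_connected_min_degree_two(self, montage):
        import scipy.sparse
        import scipy.sparse.csgraph
        names, adj = tg.triangulation_adjacency(montage)
        assert names == montage.channels
        assert np.array_equal(adj, adj.T)
        deg = adj.sum(axis=0)
        assert deg.min() >= 2
        n_comp, _ = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(adj))
        assert n_comp == 1

    def test_collinear_points_rejected(self):
        m = tg.Montage(("A", "B", "C"),
                       np.array([[0, 0, 50.0], [10, 0, 50], [20, 0, 50]]))
        with pytest.raises(ValueError):
            tg.triangulation_adjacency(m)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 6, 0.0083),
        (0.05, 1, 0.05),
        (0.01, 4, 0.0025),
    ])
    def test_threshold(self, alpha, m, expected):
        assert round(tg.bonferroni_adjust(alpha, m), 4) == expected

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            tg.bonferroni_adjust(0.05, 0)
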