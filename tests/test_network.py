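"""Co-occurrence network construction and graph-property reporting."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crustpipe.network import (
    NetworkConfig,
    NetworkError,
    OTHER_LABEL,
    build_network,
    combine_rare_features,
    network_properties,
    spearman_matrix,
)


def table_from(arr):
    a = np.asarray(arr)
    return pd.DataFrame(
        a,
        index=[f"f{i}" for i in range(a.shape[0])],
        columns=[f"s{j}" for j in range(a.shape[1])],
    )


class TestCombineRare:
    def test_zero_threshold_is_identity(self):
        t = table_from([[5, 5], [1, 1]])
        assert combine_rare_features(t, 0.0).equals(t)

    def test_rare_feature_merged_into_other(self):
        # mean relative abundances 50%, 49.95%, 0.05%
        t = table_from([[5000, 5000], [4995, 4995], [5, 5]])
        out = combine_rare_features(t, 0.001)
        assert OTHER_LABEL in out.index
        assert out.shape[0] == 3  # 2 kept + OTHER
        assert (out.sum() == t.sum()).all()

    def test_column_sums_preserved(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(0, 100, size=(50, 6)))
        out = combine_rare_features(t, 0.01)
        assert (out.sum() == t.sum()).all()

    def test_bad_threshold_rejected(self):
        with pytest.raises(NetworkError):
            combine_rare_features(table_from([[1]]), 1.5)


class TestSpearman:
    def test_monotone_pairs(self):
        t = table_from([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [10, 8, 6, 4, 2]])
        rho, p = spearman_matrix(t)
        assert rho.loc["f0", "f1"] == pytest.approx(1.0)
        assert rho.loc["f0", "f2"] == pytest.approx(-1.0)

    def test_hand_value_rank_differences(self):
        t = table_from([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]])
        rho, _ = spearman_matrix(t)
        assert rho.loc["f0", "f1"] == pytest.approx(0.8)

    def test_matches_scipy_with_ties(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        t = table_from(rng.integers(0, 6, size=(6, 10)))
        t = t[~(t.nunique(axis=1) == 1)]
        rho, p = spearman_matrix(t)
        ref_rho, ref_p = spearmanr(t.to_numpy(), axis=1)
        assert np.allclose(rho.to_numpy(), ref_rho, atol=1e-10)
        off = ~np.eye(len(rho), dtype=bool)
        assert np.allclose(p.to_numpy()[off], ref_p[off], atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(NetworkError):
            spearman_matrix(table_from([[1, 2, 3], [3, 2, 1]]))

    def test_constant_feature_dropped_with_warning(self):
        t = table_from([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7], [5, 4, 3, 2, 1]])
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(t)
        assert "f1" not in rho.index


class TestBuildNetwork:
    def _strong_table(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=12)
        a = 1000 + 200 * z + rng.normal(0, 5, 12)
        b = 2000 + 400 * z + rng.normal(0, 10, 12)
        c = 1500 - 300 * z + rng.normal(0, 8, 12)
        noise = rng.integers(500, 1500, size=(5, 12))
        t = np.vstack([a, b, c, noise]).clip(min=0).round()
        return table_from(t)

    def test_unsatisfiable_threshold_gives_empty_network(self):
        cfg = NetworkConfig(r_threshold=1.01)
        with pytest.warns(UserWarning, match="no feature pair"):
            net = build_network(self._strong_table(), cfg)
        assert net.graph.number_of_edges() == 0

    def test_signs_follow_correlations(self):
        net = build_network(self._strong_table(), NetworkConfig(min_rel_abundance=0.0))
        signs = {frozenset(e): d["sign"] for *e, d in net.graph.edges(data=True)}
        assert signs[frozenset({"f0", "f1"})] == "positive"
        assert signs[frozenset({"f0", "f2"})] == "negative"

    def test_sample_order_invariance(self):
        t = self._strong_table()
        cfg = NetworkConfig(min_rel_abundance=0.0)
        net1 = build_network(t, cfg)
        perm = t.sample(frac=1, axis=1, random_state=3)
        net2 = build_network(perm, cfg)
        assert set(map(frozenset, net1.graph.edges)) == set(
            map(frozenset, net2.graph.edges)
        )

    def test_edge_set_monotone_in_thresholds(self):
        t = self._strong_table()
        loose = build_network(t, NetworkConfig(min_rel_abundance=0.0, r_threshold=0.5, alpha_fdr=0.1))
        tight = build_network(
            t, NetworkConfig(min_rel_abundance=0.0, r_threshold=0.8, alpha_fdr=0.01)
        )
        assert set(map(frozenset, tight.graph.edges)) <= set(
            map(frozenset, loose.graph.edges)
        )

    def test_isolated_features_are_not_nodes(self):
        net = build_network(self._strong_table(), NetworkConfig(min_rel_abundance=0.0))
        for node in net.graph.nodes:
            assert net.graph.degree(node) >= 1


class TestProperties:
    def test_triangle(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], rho=0.9)
        p = network_properties(g)
        assert (p.n_nodes, p.n_edges) == (3, 3)
        assert p.density == pytest.approx(1.0)
        assert p.avg_degree == pytest.approx(2.0)
        assert p.avg_clustering == pytest.approx(1.0)
        assert p.pct_positive == pytest.approx(100.0)

    def test_path(self):
        g = nx.path_graph(3)
        p = network_properties(g)
        assert p.density == pytest.approx(2 / 3)
        assert p.avg_degree == pytest.approx(4 / 3)
        assert p.avg_clustering == pytest.approx(0.0)

    def test_too_small_rejected(self):
        with pytest.raises(NetworkError):
            network_properties(nx.Graph())

    def test_brute_force_oracle_on_random_graphs(self):
        """Clustering, density and degree match exhaustive triangle counting."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=int(rng.integers(2**31)))
            if g.number_of_nodes() < 2:
                continue
            p = network_properties(g)
            e = g.number_of_edges()
            assert p.density == pytest.approx(2 * e / (n * (n - 1)), abs=1e-12)
            assert p.avg_degree == pytest.approx(2 * e / n, abs=1e-12)
            local = []
            for v in g.nodes:
                nbrs = list(g.neighbors(v))
                k = len(nbrs)
                if k < 2:
                    local.append(0.0)
                    continue
                links = sum(
                    1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
                )
                local.append(2 * links / (k * (k - 1)))
            assert p.avg_clustering == pytest.approx(float(np.mean(local)), abs=1e-10)
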