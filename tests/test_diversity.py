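"""Rarefaction, alpha diversity, Bray-Curtis, PCoA and PERMANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from crustpipe.diversity import (
    DiversityError,
    bray_curtis,
    chao1,
    pcoa,
    permanova,
    rarefy,
    shannon,
)


def table_from(arr, prefix="s"):
    a = np.asarray(arr)
    return pd.DataFrame(
        a,
        index=[f"f{i}" for i in range(a.shape[0])],
        columns=[f"{prefix}{j}" for j in range(a.shape[1])],
    )


class TestRarefy:
    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(0, 50, size=(20, 5)))
        out = rarefy(t, depth=100, seed=1)
        assert (out.sum() == 100).all()

    def test_exhaustive_draw_is_identity(self):
        t = table_from([[5, 3], [0, 7], [2, 1]])
        out = rarefy(t, depth=7, seed=0)
        assert out["s0"].sum() == 7
        assert (out["s0"] == t["s0"]).all()  # s0 total is exactly 7

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        t = table_from(rng.integers(0, 100, size=(30, 4)))
        assert rarefy(t, "min", seed=42).equals(rarefy(t, "min", seed=42))

    def test_overdeep_depth_names_sample(self):
        t = table_from([[5, 100], [5, 100]])
        with pytest.raises(DiversityError, match="s0"):
            rarefy(t, depth=50)

    def test_subsampling_matches_hypergeometric_expectation(self):
        t = table_from(np.array([[40], [30], [20], [10]]))
        depth, n_rep = 50, 400
        rng = np.random.default_rng(5)
        means = np.mean(
            [rarefy(t, depth=depth, seed=rng).to_numpy()[:, 0] for _ in range(n_rep)],
            axis=0,
        )
        expected = depth * np.array([40, 30, 20, 10]) / 100
        # hypergeometric variance n*p*(1-p)*(N-n)/(N-1)
        var = depth * (np.array([40, 30, 20, 10]) / 100) * (1 - np.array([40, 30, 20, 10]) / 100) * (100 - depth) / 99
        se = np.sqrt(var / n_rep)
        assert (np.abs(means - expected) < 3 * se + 1e-9).all()


class TestAlpha:
    def test_chao1_hand_value(self):
        assert chao1([5, 3, 1, 1, 2]) == pytest.approx(5.5)

    def test_chao1_without_singletons_is_observed_richness(self):
        assert chao1([5, 3, 2, 2]) == pytest.approx(4.0)

    def test_chao1_never_below_observed(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = rng.integers(0, 5, size=12)
            if c.sum() == 0:
                continue
            assert chao1(c) >= (c > 0).sum()

    def test_chao1_matches_reference_implementation(self):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        rng = np.random.default_rng(2)
        for _ in range(30):
            c = rng.integers(0, 6, size=12)
            if c.sum() == 0:
                continue
            assert chao1(c) == pytest.approx(float(skbio_chao1(c)), abs=1e-10)

    @pytest.mark.parametrize(
        "counts, expected",
        [([1, 1, 1, 1], math.log(4)), ([7], 0.0), ([6, 2, 2], 0.9503)],
    )
    def test_shannon_hand_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_shannon_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            c = rng.integers(0, 20, size=10)
            if c.sum() == 0:
                continue
            p = c[c > 0] / c.sum()
            brute = -sum(pi * math.log(pi) for pi in p)
            assert shannon(c) == pytest.approx(brute, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(DiversityError):
            shannon([0, 0])
        with pytest.raises(DiversityError):
            chao1([0, 0])


class TestBrayCurtis:
    def test_hand_values(self):
        t = table_from(np.array([[6, 2], [2, 2]]))
        d = bray_curtis(t)
        assert d.iloc[0, 1] == pytest.approx(4 / 12)

    def test_identical_and_disjoint(self):
        t = table_from(np.array([[5, 5, 0], [3, 3, 0], [0, 0, 9]]))
        d = bray_curtis(t)
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_properties_and_feature_order_invariance(self):
        rng = np.random.default_rng(4)
        t = table_from(rng.integers(0, 30, size=(12, 6)))
        d = bray_curtis(t)
        a = d.to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 0)
        assert ((a >= 0) & (a <= 1)).all()
        shuffled = t.sample(frac=1, random_state=0)
        assert np.allclose(bray_curtis(shuffled).to_numpy(), a)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        t = table_from(rng.integers(0, 25, size=(8, 5)))
        d = bray_curtis(t).to_numpy()
        x = t.to_numpy()
        for i in range(5):
            for j in range(5):
                brute = np.abs(x[:, i] - x[:, j]).sum() / (x[:, i] + x[:, j]).sum()
                assert d[i, j] == pytest.approx(brute, abs=1e-10)


class TestPCoA:
    def test_collinear_points_recovered_on_first_axis(self):
        pts = np.array([0.0, 1.0, 2.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        axis = res.coordinates["PC1"].to_numpy()
        gaps = np.abs(np.diff(np.sort(axis)))
        assert np.allclose(gaps, [1.0, 1.0], atol=1e-8)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-8)

    def test_duplicate_samples_coincide(self):
        d = pd.DataFrame(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        res = pcoa(d)
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-10)

    def test_euclidean_distances_reproduced_from_coordinates(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(x)), index=range(7), columns=range(7))
        res = pcoa(d)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recon, d.to_numpy(), atol=1e-8)

    def test_positive_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 4))
        from scipy.spatial.distance import pdist, squareform

        a = squareform(pdist(x))
        d = pd.DataFrame(a, index=range(6), columns=range(6))
        res = pcoa(d)
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (a**2) @ j
        assert res.eigenvalues[res.eigenvalues > 0].sum() == pytest.approx(
            np.trace(b), abs=1e-8
        )

    def test_matches_skbio_reference(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        mine = pcoa(pd.DataFrame(d, index=range(9), columns=range(9)))
        ref = skbio_pcoa(d, method="eigh")
        k = min(3, mine.coordinates.shape[1])
        for i in range(k):
            a = mine.coordinates.iloc[:, i].to_numpy()
            b = ref.samples.iloc[:, i].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(DiversityError):
            pcoa(d)


class TestPermanova:
    def _euclidean(self, x):
        from scipy.spatial.distance import pdist, squareform

        return pd.DataFrame(squareform(pdist(x)), index=range(len(x)), columns=range(len(x)))

    def test_complete_separation_gives_minimal_p(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(50, 0.1, (6, 2))])
        groups = ["a"] * 6 + ["b"] * 6
        res = permanova(self._euclidean(x), groups, n_perm=199, seed=0)
        assert res["p_value"] == pytest.approx(1 / 200)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 3))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        d = self._euclidean(x)
        mine = permanova(d, groups, n_perm=99, seed=1)
        ref = skbio_permanova(DistanceMatrix(d.to_numpy()), groups, permutations=99)
        assert mine["pseudo_F"] == pytest.approx(float(ref["test statistic"]), abs=1e-8)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(12, 2))
        groups = ["a"] * 6 + ["b"] * 6
        d = self._euclidean(x)
        r1 = permanova(d, groups, n_perm=199, seed=5)
        r2 = permanova(d, groups, n_perm=199, seed=5)
        assert r1 == r2

    def test_relabeling_invariance(self):
        """Renaming groups consistently leaves statistic and p unchanged."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=(10, 2))
        d = self._euclidean(x)
        g1 = ["a"] * 5 + ["b"] * 5
        g2 = ["x"] * 5 + ["y"] * 5
        assert permanova(d, g1, 99, seed=2)["pseudo_F"] == pytest.approx(
            permanova(d, g2, 99, seed=2)["pseudo_F"]
        )

    def test_singleton_group_rejected(self):
        d = self._euclidean(np.random.default_rng(13).normal(size=(5, 2)))
        with pytest.raises(DiversityError):
            permanova(d, ["a", "a", "a", "a", "b"], 99, seed=0)
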