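"""Dissimilarity metrics, UPGMA clustering, and ANOSIM."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

import dyadcomm as dc
from dyadcomm.community import DistanceMatrix


def random_distance_matrix(rng, n):
    cond = rng.uniform(0.01, 0.99, size=n * (n - 1) // 2)
    return DistanceMatrix(list(range(n)), squareform(cond), "bray_curtis")


class TestMetrics:
    def test_bray_curtis_examples(self):
        assert dc.bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert dc.bray_curtis([1, 0], [0, 1]) == 1.0
        assert dc.bray_curtis([0.7, 0.3, 0], [0.3, 0.3, 0.4]) == pytest.approx(0.4)

    def test_jaccard_examples(self):
        assert dc.jaccard([1, 2, 3, 0], [9, 9, 9, 0]) == 0.0
        assert dc.jaccard([1, 0], [0, 1]) == 1.0
        # {A,B,C} vs {B,C,D}: 1 - 2/4
        assert dc.jaccard([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)

    def test_both_zero_errors(self):
        with pytest.raises(dc.InputError):
            dc.bray_curtis([0, 0], [0, 0])
        with pytest.raises(dc.InputError):
            dc.jaccard([0, 0], [0, 0])

    def test_metric_axioms_on_random_vectors(self, rng):
        for _ in range(30):
            x = rng.uniform(0, 1, 6)
            y = rng.uniform(0, 1, 6)
            for f in (dc.bray_curtis, lambda a, b: dc.jaccard(a, b),
                      lambda a, b: dc.jaccard(a, b, binary=False)):
                assert f(x, x) == pytest.approx(0.0, abs=1e-12)
                assert f(x, y) == pytest.approx(f(y, x), abs=1e-12)
                assert -1e-12 <= f(x, y) <= 1 + 1e-12

    def test_distance_matrix_matches_scalar_metrics(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, size=(5, 7)))
        dm = dc.distance_matrix(X, "bray_curtis")
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert dm.values[i, j] == pytest.approx(
                        dc.bray_curtis(X.iloc[i], X.iloc[j]), abs=1e-12)


class TestAverageLinkage:
    def test_forced_topology(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dm = DistanceMatrix(["a", "b", "c"], d)
        dend = dc.average_linkage(dm)
        assert dend.merges[0][3] == ("a", "b")
        assert dend.merges[0][2] == pytest.approx(0.1)
        assert dend.merges[1][2] == pytest.approx(0.9)
        assert dend.last_singleton == "c"

    def test_matches_scipy_average_linkage(self, rng):
        """Heights and clade composition agree with scipy's UPGMA."""
        for n in (5, 8, 12):
            dm = random_distance_matrix(rng, n)
            dend = dc.average_linkage(dm)
            Z = linkage(dm.condensed(), method="average")
            np.testing.assert_allclose(dend.heights, Z[:, 2], atol=1e-10)
            # clade sets identical
            members = {i: frozenset([i]) for i in range(n)}
            scipy_clades = set()
            for k, (a, b, h, _) in enumerate(Z):
                members[n + k] = members[int(a)] | members[int(b)]
                scipy_clades.add(members[n + k])
            assert set(dend.clades()) == scipy_clades

    def test_heights_monotone(self, rng):
        for _ in range(5):
            dend = dc.average_linkage(random_distance_matrix(rng, 9))
            h = dend.heights
            assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))

    def test_newick_parses_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        dm = random_distance_matrix(rng, 6)
        dm.ids = [f"leaf{i}" for i in range(6)]
        tree = skbio.TreeNode.read([dc.average_linkage(dm).to_newick()])
        assert {t.name for t in tree.tips()} == set(dm.ids)


def naive_anosim_r(d: np.ndarray, groups) -> float:
    """Brute-force ANOSIM R: explicit pair loops, mid-rank ties."""
    n = len(groups)
    dists, kinds = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(d[i, j])
            kinds.append(groups[i] == groups[j])
    ranks = rankdata(dists)
    within = [r for r, k in zip(ranks, kinds) if k]
    between = [r for r, k in zip(ranks, kinds) if not k]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4.0)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(list("abcd"), d)
        res = dc.anosim(dm, ["g1", "g1", "g2", "g2"], method="exact")
        assert res.R == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 3)

    def test_rank_formula_equals_brute_force(self, rng):
        for n, k in [(6, 2), (8, 2), (8, 4)]:
            dm = random_distance_matrix(rng, n)
            groups = [f"g{i % k}" for i in range(n)]
            res = dc.anosim(dm, groups, n_perm=9, seed=0)
            assert res.R == pytest.approx(naive_anosim_r(dm.values, groups),
                                          abs=1e-12)

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim
        dm = random_distance_matrix(rng, 10)
        groups = ["a"] * 5 + ["b"] * 5
        res = dc.anosim(dm, groups, n_perm=99, seed=1)
        sk = sk_anosim(skbio.DistanceMatrix(dm.values, [str(i) for i in dm.ids]),
                       grouping=groups, permutations=99)
        assert res.R == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_p_convention_includes_observed(self, rng):
        dm = random_distance_matrix(rng, 8)
        res = dc.anosim(dm, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=3)
        assert res.p_value >= 1 / 1000
        assert 0 < res.p_value <= 1

    def test_group_of_one_errors(self, rng):
        dm = random_distance_matrix(rng, 5)
        with pytest.raises(dc.InputError, match="fewer than 2"):
            dc.anosim(dm, ["a", "a", "a", "a", "b"])
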