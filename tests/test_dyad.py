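"""Cross-niche Spearman, logit CCA, matched-dyad test, diversity correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dyadcomm as dc
from dyadcomm.dyad import _ranksum
from dyadcomm.tables import AbundanceTable, DyadPairing


def paired_tables(milk_vals, feces_vals, zero_replaced=True):
    """Wrap two aligned value matrices as AbundanceTables + a DyadPairing."""
    n = len(milk_vals)
    dyads = [f"d{i}" for i in range(n)]
    m_ids = [f"M{i}" for i in range(n)]
    f_ids = [f"F{i}" for i in range(n)]

    def tab(vals, ids, niche):
        vals = np.asarray(vals, dtype=float)
        df = pd.DataFrame(vals, index=ids,
                          columns=[f"g{j}" for j in range(vals.shape[1])])
        meta = pd.DataFrame({"cohort": ["A"] * n, "dyad_id": dyads,
                             "niche": [niche] * n}, index=ids)
        return AbundanceTable(df, meta, zero_replaced=zero_replaced)

    pairs = DyadPairing(list(zip(dyads, m_ids, f_ids)), [], [])
    return tab(milk_vals, m_ids, "milk"), tab(feces_vals, f_ids, "feces"), pairs


def simplex(rng, n, g):
    x = rng.dirichlet(np.ones(g) * 2, size=n)
    return np.clip(x, 1e-6, None)


class TestCrossSpearman:
    def test_identical_and_reversed_columns(self, rng):
        m = simplex(rng, 8, 3)
        f = m.copy()
        f[:, 1] = 1.0 - m[:, 0]  # reversed ranks of milk g0
        milk, feces, pairs = paired_tables(m, f)
        cc = dc.cross_spearman(milk, feces, pairs)
        assert cc.rs.loc["g0", "g0"] == pytest.approx(1.0)
        assert cc.rs.loc["g0", "g1"] == pytest.approx(-1.0)

    def test_flag_rule(self):
        cc_rs = pd.DataFrame([[0.35]], index=["m"], columns=["f"])
        cc_p = pd.DataFrame([[0.02]], index=["m"], columns=["f"])
        flags = (cc_p < 0.01) & (cc_rs.abs() > 0.3)
        assert not flags.iloc[0, 0]  # rs passes but p fails

    def test_matches_scalar_spearman(self, rng):
        m = simplex(rng, 12, 2)
        f = simplex(rng, 12, 2)
        milk, feces, pairs = paired_tables(m, f)
        cc = dc.cross_spearman(milk, feces, pairs)
        for i in range(2):
            for j in range(2):
                r, p = stats.spearmanr(m[:, i], f[:, j])
                assert cc.rs.iloc[i, j] == pytest.approx(r, abs=1e-12)
                assert cc.p_values.iloc[i, j] == pytest.approx(p, abs=1e-9)

    def test_requires_three_dyads(self, rng):
        milk, feces, pairs = paired_tables(simplex(rng, 2, 3), simplex(rng, 2, 3))
        with pytest.raises(dc.InputError):
            dc.cross_spearman(milk, feces, pairs)


class TestLogitCCA:
    def test_affine_copy_gives_r1_one(self, rng):
        m = simplex(rng, 30, 4)
        milk, feces, pairs = paired_tables(m, m)
        res = dc.logit_canonical_correlation(milk, feces, pairs)
        assert res.r1 == pytest.approx(1.0, abs=1e-9)

    def test_grid_search_oracle_three_variables(self, rng):
        """r1 on X (2 vars) vs Y (1 var) equals maximized corr(a'X, Y)."""
        n = 200
        z = rng.normal(size=n)
        X = np.column_stack([z + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        Y = (0.8 * z + rng.normal(0, 0.6, n)).reshape(-1, 1)
        # pack through the logit pipeline by inverting it: feed expit values
        from scipy.special import expit
        milk, feces, pairs = paired_tables(expit(X), expit(Y))
        res = dc.logit_canonical_correlation(milk, feces, pairs)

        def neg_corr(theta):
            a = np.array([np.cos(theta), np.sin(theta)])
            return -abs(np.corrcoef(X @ a, Y[:, 0])[0, 1])

        grid = np.linspace(0, np.pi, 2001)
        best = min(grid, key=neg_corr)
        from scipy.optimize import minimize_scalar
        ref = minimize_scalar(neg_corr, bracket=(best - 0.01, best, best + 0.01))
        assert res.r1 == pytest.approx(-ref.fun, abs=1e-6)

    def test_r1_at_least_any_single_pair_correlation(self, rng):
        m = simplex(rng, 60, 4)
        f = simplex(rng, 60, 3)
        milk, feces, pairs = paired_tables(m, f)
        res = dc.logit_canonical_correlation(milk, feces, pairs)
        from scipy.special import logit
        for i in range(4):
            for j in range(3):
                r = abs(np.corrcoef(logit(m[:, i]), logit(f[:, j]))[0, 1])
                assert res.r1 >= r - 1e-9

    def test_invariant_to_affine_rescaling(self, rng):
        """Affine rescaling of one variable on the logit scale leaves r1
        unchanged (standardization absorbs it)."""
        from scipy.special import expit, logit
        m = simplex(rng, 40, 3)
        f = simplex(rng, 40, 3)
        milk, feces, pairs = paired_tables(m, f)
        base = dc.logit_canonical_correlation(milk, feces, pairs).r1
        m2 = m.copy()
        m2[:, 0] = expit(2.0 * logit(m2[:, 0]) - 1.0)
        milk2, feces2, pairs2 = paired_tables(m2, f)
        again = dc.logit_canonical_correlation(milk2, feces2, pairs2).r1
        assert base == pytest.approx(again, abs=1e-9)

    def test_correlations_sorted_in_unit_interval(self, rng):
        milk, feces, pairs = paired_tables(simplex(rng, 50, 4), simplex(rng, 50, 4))
        res = dc.logit_canonical_correlation(milk, feces, pairs)
        r = res.correlations
        assert (np.diff(r) <= 1e-12).all()
        assert ((0 <= r) & (r <= 1)).all()

    def test_bartlett_p_uniform_under_independence(self, rng):
        """Independent blocks: Bartlett P roughly uniform (KS check)."""
        ps = []
        for _ in range(120):
            milk, feces, pairs = paired_tables(simplex(rng, 200, 3),
                                               simplex(rng, 200, 3))
            ps.append(dc.logit_canonical_correlation(milk, feces, pairs).p_overall)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDyadSimilarityTest:
    def test_strong_coupling_small_p(self):
        n, g = 20, 6
        rng = np.random.default_rng(5)
        base = rng.dirichlet(np.ones(g) * 3, size=n)
        milk, feces, pairs = paired_tables(base, base + rng.normal(0, 1e-4, (n, g)).clip(-1e-5, 1e-5) + 1e-5)
        res = dc.dyad_similarity_test(milk, feces, pairs)
        assert res.p_value < 1e-3
        assert res.median_difference < 0
        assert len(res.unmatched) == n * n - n

    def test_exact_ranksum_oracle_untied(self):
        """Rank-sum z/P on untied data equals the closed-form calculation."""
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.4, 0.5, 0.6, 0.7])
        w, z, p = _ranksum(x, y)
        assert w == 6.0  # ranks 1+2+3
        mean = 3 * 8 / 2.0
        var = 3 * 4 * 8 / 12.0
        assert z == pytest.approx((6 - mean) / np.sqrt(var))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_complete_ties_give_p_one(self):
        w, z, p = _ranksum(np.full(5, 0.3), np.full(20, 0.3))
        assert z == 0.0 and p == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        m = simplex(rng, 10, 5)
        f = simplex(rng, 10, 5)
        milk, feces, pairs = paired_tables(m, f)
        res = dc.dyad_similarity_test(milk, feces, pairs)
        # recompute on squared distances: ranks unchanged
        from dyadcomm.dyad import _cross_distances
        D = _cross_distances(milk.abund.values, feces.abund.values, "bray_curtis")
        eye = np.eye(10, dtype=bool)
        w2, z2, p2 = _ranksum(D[eye] ** 2, D[~eye] ** 2)
        assert res.p_value == pytest.approx(p2, abs=1e-12)
        assert res.z == pytest.approx(z2, abs=1e-12)

    def test_too_few_dyads(self, rng):
        milk, feces, pairs = paired_tables(simplex(rng, 4, 3), simplex(rng, 4, 3))
        with pytest.raises(dc.InputError, match=">= 5 dyads"):
            dc.dyad_similarity_test(milk, feces, pairs)

    def test_null_calibration_permutation_vs_ranksum(self):
        """Under no coupling the pairing-permutation P is calibrated while
        the rank-sum P (overlapping, dependent sets) is conservative."""
        reps = 120
        rej_perm = rej_rank = 0
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            n, g = 40, 20
            m = rng.dirichlet(np.ones(g), size=n).clip(1e-6, None)
            f = rng.dirichlet(np.ones(g), size=n).clip(1e-6, None)
            milk, feces, pairs = paired_tables(m, f)
            res = dc.dyad_similarity_test(milk, feces, pairs,
                                          permutation=199, seed=r)
            rej_perm += res.p_permutation <= 0.05
            rej_rank += res.p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej_perm / reps - 0.05) <= 3 * se + 1e-9
        assert rej_rank / reps <= 0.05 + 3 * se  # conservative, never inflated


class TestDiversityCorrelation:
    @staticmethod
    def _div_frames(rng, n, cohorts=None):
        cohorts = cohorts or ["A"] * n
        idx_m = [f"M{i}" for i in range(n)]
        idx_f = [f"F{i}" for i in range(n)]
        cols = ["richness", "shannon", "inv_simpson", "fisher_alpha"]
        dm = pd.DataFrame(rng.uniform(1, 10, (n, 4)), index=idx_m, columns=cols)
        df = pd.DataFrame(rng.uniform(1, 10, (n, 4)), index=idx_f, columns=cols)
        for d, ids in ((dm, idx_m), (df, idx_f)):
            d["cohort"] = cohorts
        pairs = DyadPairing(list(zip([f"d{i}" for i in range(n)], idx_m, idx_f)),
                            [], [])
        return dm, df, pairs

    def test_identical_diversities_r_one(self, rng):
        dm, _, pairs = self._div_frames(rng, 12)
        df = dm.copy()
        df.index = [f"F{i}" for i in range(12)]
        out = dc.diversity_correlation(dm, df, pairs)
        np.testing.assert_allclose(out["r"], 1.0, atol=1e-12)

    def test_per_cohort_shape(self, rng):
        cohorts = sum([[c] * 6 for c in "ABC"], [])
        dm, df, pairs = self._div_frames(rng, 18, cohorts)
        out = dc.diversity_correlation(dm, df, pairs, per_cohort=True)
        assert set(out["scope"]) == {"A", "B", "C"}
        assert len(out) == 12  # 3 cohorts x 4 indices

    def test_small_scope_skipped(self, rng):
        cohorts = ["A"] * 10 + ["B"] * 3
        dm, df, pairs = self._div_frames(rng, 13, cohorts)
        out = dc.diversity_correlation(dm, df, pairs, per_cohort=True)
        assert set(out["scope"]) == {"A"}
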