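"""Fisher/MWU/Spearman statistics against independent brute-force oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from paradel import enrichment
from paradel.enrichment import StatsError, fisher_exact_or


def fisher_p_by_enumeration(a, b, c, d):
    """Oracle: two-sided point-probability Fisher p by enumerating every 2x2
    table with the same margins under the hypergeometric null."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logp(x):
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - (c1 - x) + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1)))
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: math.exp(logp(x)) for x in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in probs.values() if p <= cutoff))


class TestFisher:
    def test_symmetric_table(self):
        r = fisher_exact_or([[10, 10], [10, 10]])
        assert r.odds_ratio == 1.0 and r.p_value == pytest.approx(1.0)

    def test_sample_odds_ratio_is_ad_over_bc(self):
        assert fisher_exact_or([[30, 10], [10, 30]]).odds_ratio == 9.0

    @pytest.mark.parametrize("table", [
        (5, 1, 2, 8), (3, 7, 6, 2), (1, 9, 9, 1), (12, 3, 4, 11), (2, 2, 3, 17),
    ])
    def test_p_matches_enumeration(self, table):
        a, b, c, d = table
        r = fisher_exact_or([[a, b], [c, d]])
        assert r.p_value == pytest.approx(fisher_p_by_enumeration(a, b, c, d), rel=1e-9)

    def test_p_matches_scipy_on_random_tables(self):
        """Independent cross-check of the point-probability rule against the
        reference library implementation."""
        from scipy import stats as sps
        rng = np.random.default_rng(8)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = fisher_exact_or([[a, b], [c, d]]).p_value
            ref = float(sps.fisher_exact([[a, b], [c, d]])[1])
            assert ours == pytest.approx(ref, rel=1e-9), (a, b, c, d)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError, match="margin"):
            fisher_exact_or([[0, 0], [5, 5]])

    def test_zero_cell_gives_extreme_or_finite_p(self):
        r = fisher_exact_or([[5, 0], [2, 8]])
        assert np.isinf(r.odds_ratio) and 0 < r.p_value < 1

    def test_conditional_estimator_available(self):
        r = fisher_exact_or([[30, 10], [10, 30]], estimator="conditional")
        assert 5 < r.odds_ratio < 12 and r.odds_ratio != 9.0


class TestHDGroupEnrichment:
    def test_groups_and_percentages(self):
        tbl = pd.DataFrame({"n_full_hd": [0, 0, 1, 3, 5, 0, 2],
                            "flag": [True, False, True, True, False, False, True]})
        res = enrichment.hd_group_enrichment(tbl, "flag")
        assert res[0].comparison.startswith("0 vs 1+")
        # 1+ group: counts {T:3, F:1}; zero group {T:1, F:2}
        assert res[0].table.tolist() == [[3, 1], [1, 2]]
        pct = enrichment.group_percentages(tbl, "flag")
        assert pct.loc[0, "n_genes"] == 3 and pct.loc[2, "n_genes"] == 2

    def test_empty_group_raises(self):
        tbl = pd.DataFrame({"n_full_hd": [0, 0], "flag": [True, False]})
        with pytest.raises(StatsError):
            enrichment.hd_group_enrichment(tbl, "flag")


class TestHolm:
    def test_closed_form_two_tests(self):
        adj = enrichment.holm_adjust([0.01, 0.04])
        assert adj == pytest.approx([0.02, 0.04])

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=8)
            adj = enrichment.holm_adjust(p)
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_superset_of_bonferroni(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 0.2, size=6)
            holm = enrichment.holm_adjust(p) <= 0.05
            bonf = p * len(p) <= 0.05
            assert (holm | ~bonf).all()


class TestStratified:
    def _tbl(self):
        return pd.DataFrame({"n_full_hd": [0] * 10 + [1] * 6,
                             "flag": [True] * 5 + [False] * 5 + [True] * 5 + [False]})

    def test_small_strata_omitted_and_identical_tables_identical_ors(self):
        tabs = {"A": self._tbl(), "B": self._tbl(), "tiny": self._tbl()}
        sizes = {"A": 700, "B": 650, "tiny": 100}
        res = enrichment.stratified_enrichment(tabs, "flag", sizes, min_samples=600)
        assert {r.stratum for r in res} == {"A", "B"}
        assert res[0].odds_ratio == res[1].odds_ratio
        assert all(r.adjusted_p >= r.p_value - 1e-12 for r in res)


def mwu_p_by_enumeration(x, y):
    """Oracle: exact two-sided MWU p by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum(np.sum(xv > ys) + 0.5 * np.sum(xv == ys) for xv in xs)
    observed = u_stat(range(nx))
    mean_u = nx * len(y) / 2
    count = total = 0
    for ix in itertools.combinations(range(len(pooled)), nx):
        u = u_stat(ix)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-9:
            count += 1
    return count / total


class TestMWU:
    def test_identical_distributions_p_near_one(self):
        r = enrichment.mwu_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.p_value > 0.9

    def test_toy_vectors_match_rank_enumeration(self):
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        r = enrichment.mwu_compare(x, y)
        assert r.p_value == pytest.approx(mwu_p_by_enumeration(x, y), rel=1e-6)
        x2 = np.array([8.5, 9.5, 10.5, 11.5, 12.5])  # shifted, still tie-free
        r2 = enrichment.mwu_compare(x2, y)
        assert r2.p_value == pytest.approx(mwu_p_by_enumeration(x2, y), rel=1e-6)

    def test_all_tied_values_warn_p_one(self):
        r = enrichment.mwu_compare([2, 2, 2], [2, 2])
        assert r.p_value == 1.0

    def test_stochastic_shift_detected_with_direction(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(6, 300)
        y = rng.poisson(4, 300)
        r = enrichment.mwu_compare(x, y)
        assert r.p_value < 1e-4 and r.median_x > r.median_y


class TestSpearman:
    def test_perfectly_monotone(self):
        tbl = pd.DataFrame({"gene_length": [1, 2, 3, 4, 5],
                            "n_full_hd": [0, 1, 2, 3, 4]})
        rho, _ = enrichment.length_hd_correlation(tbl)
        assert rho == pytest.approx(1.0)

    def test_matches_pearson_of_ranks_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        tbl = pd.DataFrame({"gene_length": x, "n_full_hd": y})
        rho, _ = enrichment.length_hd_correlation(tbl)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        tbl = pd.DataFrame({"gene_length": [2, 2, 2], "n_full_hd": [1, 2, 3]})
        with pytest.raises(StatsError):
            enrichment.length_hd_correlation(tbl)


def expected_unique_closed_form(k_per_gene, n_total, n_sub):
    """Oracle: E[#unique genes] = sum_g 1 - C(N - k_g, n)/C(N, n)."""
    total = 0.0
    for k in k_per_gene:
        total += 1.0 - math.comb(n_total - k, n_sub) / math.comb(n_total, n_sub)
    return total


class TestSaturation:
    CALLS = pd.DataFrame({
        "sample": ["s1", "s1", "s2", "s3", "s3", "s4"],
        "gene_id": ["A", "B", "A", "C", "D", "A"],
    })
    SAMPLES = ["s1", "s2", "s3", "s4", "s5"]

    def test_full_cohort_point_exact_with_zero_spread(self):
        c = enrichment.saturation_curve(self.CALLS, self.SAMPLES, [0, 5], seed=0)
        assert c.mean[0] == c.min[0] == c.max[0] == 0
        assert c.mean[-1] == c.min[-1] == c.max[-1] == 4

    def test_monotone_in_subsample_size(self):
        c = enrichment.saturation_curve(self.CALLS, self.SAMPLES, [1, 2, 3, 4, 5],
                                        n_replicates=50, seed=1)
        assert (np.diff(c.mean) >= -1e-12).all()

    def test_expectation_matches_inclusion_exclusion(self):
        # per-gene sample counts: A:3, B:1, C:1, D:1 on a 5-sample cohort
        n_sub = 2
        c = enrichment.saturation_curve(self.CALLS, self.SAMPLES, [n_sub],
                                        n_replicates=4000, seed=2)
        expect = expected_unique_closed_form([3, 1, 1, 1], 5, n_sub)
        assert c.mean[0] == pytest.approx(expect, rel=0.05)
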