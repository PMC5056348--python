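import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from medipdmr import (
    DMRParams,
    SimConfig,
    bartlett_test,
    benjamini_hochberg,
    call_dmrs,
    candidate_regions,
    extend_region,
    find_seeds,
    make_genome,
    make_truth,
    simulate_depths,
    site_test,
)
from medipdmr.preprocess import filter_low_coverage, normalize
from conftest import make_matrix, recall_and_fdr


# ----------------------------------------------------------------------
# hand oracles
# ----------------------------------------------------------------------
def hand_bartlett_p(x, y):
    """Textbook two-group Bartlett statistic against chi-square(1)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    N = n1 + n2
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (N - 2)
    T = ((N - 2) * math.log(sp) - (n1 - 1) * math.log(v1) - (n2 - 1) * math.log(v2))
    T /= 1.0 + (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (N - 2)) / 3.0
    return float(stats.chi2.sf(T, 1))


def hand_pooled_t_p(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(2 * stats.t.sf(abs(t), n1 + n2 - 2))


def hand_mw_exact_p(x, y):
    """Two-sided exact Mann-Whitney by enumerating every group assignment."""
    pooled = np.r_[x, y]
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    mean = np.mean(sums)
    obs = abs(sum(ranks[:n1]) - mean)
    return float(np.mean([abs(s - mean) >= obs - 1e-9 for s in sums]))


def oracle_regions(pos, p, params):
    """Literal seed-and-extend enumeration of the stated rules."""
    n = len(p)
    raw = []
    for seed in [i for i in range(n) if p[i] < params.seed_alpha]:
        e = seed
        j = seed + 1
        while j < n and pos[j] - pos[e] <= params.join_window_bp and p[j] < params.seed_alpha:
            e = j
            j += 1
        raw.append((seed, e))
    merged = []
    for s, e in sorted(raw):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s + 1 >= params.min_sig_cpgs]


# ----------------------------------------------------------------------
class TestBartlett:
    def test_equal_spread_routes_parametric(self):
        assert bartlett_test([10, 11, 12], [20, 21, 22]) > 0.05

    def test_unequal_spread_matches_hand_formula(self):
        x, y = [10, 10.1, 9.9], [5, 60, 200]
        p = bartlett_test(x, y)
        assert p < 0.05
        assert p == pytest.approx(hand_bartlett_p(x, y), rel=1e-12)

    def test_location_invariance(self):
        x, y = [3.0, 7.0, 5.0], [1.0, 9.0, 2.0]
        assert bartlett_test(x, y) == pytest.approx(
            bartlett_test(np.array(x) + 100, np.array(y) + 100), rel=1e-12
        )

    def test_degenerate_variances(self):
        assert bartlett_test([5, 5, 5], [7, 7, 7]) == 1.0
        assert bartlett_test([5, 5, 5], [1, 9, 2]) == 0.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.normal(size=4), rng.normal(size=5)
            assert bartlett_test(x, y) == pytest.approx(
                stats.bartlett(x, y).pvalue, rel=1e-9
            )


class TestSiteTest:
    def test_identical_groups_p_one(self):
        assert site_test([5, 5, 5], [5, 5, 5], "parametric") == 1.0

    def test_parametric_matches_hand_and_scipy(self):
        x, y = [30, 31, 29], [90, 88, 92]
        p = site_test(x, y, "parametric")
        assert p < 0.01
        assert p == pytest.approx(hand_pooled_t_p(x, y), rel=1e-12)
        assert p == pytest.approx(stats.ttest_ind(x, y).pvalue, rel=1e-9)

    def test_exact_mann_whitney_minimum_p_at_3v3(self):
        """Full 20-assignment enumeration: separated 3v3 data gives 0.1,
        the smallest attainable two-sided exact P."""
        p = site_test([1, 2, 3], [4, 5, 6], "nonparametric")
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(hand_mw_exact_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_exact_mann_whitney_with_ties_matches_enumeration(self):
        x, y = [1.0, 2.0, 2.0, 7.0], [2.0, 5.0, 6.0]
        assert site_test(x, y, "nonparametric") == pytest.approx(
            hand_mw_exact_p(x, y), abs=1e-12
        )

    def test_untied_exact_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=5)  # continuous: no ties w.p. 1
            assert site_test(x, y, "nonparametric") == pytest.approx(
                stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue,
                rel=1e-9,
            )


class TestSeedsAndExtension:
    def test_find_seeds(self):
        params = DMRParams()
        assert find_seeds([0.5] * 5, params).size == 0
        assert find_seeds([0.005, 0.02, 0.009], params).tolist() == [0, 2]
        rng = np.random.default_rng(1)
        p = rng.random(500)
        assert np.array_equal(
            find_seeds(p, params), [i for i in range(500) if p[i] < 0.01]
        )

    def test_five_significant_run_is_reported(self):
        pos = np.array([1000, 1050, 1100, 1150, 1200, 1250])
        p = np.array([0.001] * 5 + [0.5])
        cands = candidate_regions(pos, np.zeros(6, int), p, DMRParams())
        assert len(cands) == 1
        row = cands.iloc[0]
        assert (row["start_idx"], row["end_idx"], row["n_sig"]) == (0, 4, 5)

    def test_four_significant_is_below_minimum(self):
        pos = np.arange(5) * 50 + 1000
        p = np.array([0.001] * 4 + [0.5])
        assert len(candidate_regions(pos, np.zeros(5, int), p, DMRParams())) == 0

    def test_gap_beyond_join_window_splits(self):
        pos = np.array([0, 100, 200, 300, 400, 3000, 3100, 3200, 3300, 3400])
        p = np.full(10, 0.001)
        cands = candidate_regions(pos, np.zeros(10, int), p, DMRParams())
        assert [(r.start_idx, r.end_idx) for r in cands.itertuples()] == [(0, 4), (5, 9)]

    def test_chromosome_boundary_splits(self):
        pos = np.array([0, 50, 100, 150, 200, 0, 50, 100, 150, 200])
        codes = np.array([0] * 5 + [1] * 5)
        p = np.full(10, 0.001)
        cands = candidate_regions(pos, codes, p, DMRParams())
        assert len(cands) == 2

    def test_matches_brute_force_on_random_chains(self):
        rng = np.random.default_rng(5)
        params = DMRParams()
        for _ in range(300):
            n = int(rng.integers(1, 31))
            pos = np.cumsum(rng.integers(10, 3001, n))
            p = np.where(rng.random(n) < 0.5, rng.random(n) * 0.009, rng.random(n))
            got = candidate_regions(pos, np.zeros(n, int), p, params)
            want = oracle_regions(pos, p, params)
            assert [(r.start_idx, r.end_idx) for r in got.itertuples()] == want

    def test_extend_region_wrapper(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(6) * 50 + 1000})
        p = np.array([0.001] * 5 + [0.5])
        reg = extend_region(2, sites, p, DMRParams())
        assert reg is not None and (reg["start_idx"], reg["end_idx"]) == (0, 4)
        assert extend_region(5, sites, p, DMRParams()) is None


class TestBenjaminiHochberg:
    def test_hand_cases(self):
        assert benjamini_hochberg([0.03]).tolist() == [0.03]
        assert np.allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert np.allclose(
            benjamini_hochberg([0.001, 0.004, 0.03, 0.5]), [0.004, 0.008, 0.04, 0.5]
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_dominates_p(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = benjamini_hochberg(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)


# ----------------------------------------------------------------------
class TestCallDmrs:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimConfig(seed=19, chromosomes=(("chr1", 600_000),), n_dmrs=3,
                        dmr_direction="hyper")
        genome = make_genome(cfg)
        truth = make_truth(genome, cfg)
        matrix = normalize(filter_low_coverage(simulate_depths(genome, truth, cfg)))
        return truth, matrix

    def test_recovers_planted_regions_with_direction(self, planted):
        truth, matrix = planted
        with pytest.warns(UserWarning, match="nonparametric route"):
            dmrs, meta = call_dmrs(matrix, DMRParams(seed=2, n_permutations=500))
        recall, fdr = recall_and_fdr(dmrs, truth)
        assert recall == 1.0
        assert fdr == 0.0
        assert (dmrs["direction"] == "hyper").all()
        assert (dmrs["n_sig"] >= 5).all()
        assert (dmrs["q"] <= dmrs["region_p"] * len(dmrs)).all()

    def test_extreme_candidate_gets_minimum_empirical_p(self, planted):
        """A candidate whose statistic beats every null draw attains the
        smallest empirical P, 1/(n_permutations + 1)."""
        truth, matrix = planted
        dmrs, _ = call_dmrs(matrix, DMRParams(seed=2, n_permutations=99), keep_all=True)
        assert np.isclose(dmrs["region_p"], 1 / 100).any()

    def test_null_matrix_yields_no_calls(self):
        cfg = SimConfig(seed=17, chromosomes=(("chr1", 400_000),), n_dmrs=0)
        genome = make_genome(cfg)
        matrix = normalize(
            filter_low_coverage(simulate_depths(genome, make_truth(genome, cfg), cfg))
        )
        dmrs, _ = call_dmrs(matrix, DMRParams(seed=3, n_permutations=300))
        assert len(dmrs) == 0

    def test_label_swap_flips_directions_only(self, planted):
        truth, matrix = planted
        idx = [3, 4, 5, 0, 1, 2]
        swapped = dataclasses.replace(
            matrix,
            depth=matrix.depth[:, idx],
            samples=[matrix.samples[i] for i in idx],
            groups=[matrix.groups[i] for i in idx],
            scale_factors=None,
            library_sizes=None,
        )
        a, _ = call_dmrs(matrix, DMRParams(seed=5, n_permutations=200))
        b, _ = call_dmrs(swapped, DMRParams(seed=5, n_permutations=200))
        cols = ["chrom", "start", "end", "n_cpg", "n_sig", "stat", "region_p", "q"]
        assert a[cols].equals(b[cols])
        assert all(
            (x == "hyper") == (y == "hypo")
            for x, y in zip(a["direction"], b["direction"])
        )

    def test_too_few_samples_rejected(self):
        m = make_matrix(np.ones((10, 3)), groups=["A", "A", "B"])
        with pytest.raises(ValueError):
            call_dmrs(m, DMRParams())

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DMRParams(seed_alpha=0)
        with pytest.raises(ValueError):
            DMRParams(n_permutations=0)
        with pytest.raises(ValueError):
            DMRParams(join_window_bp=5000, max_gap_bp=2000)
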