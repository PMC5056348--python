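import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipdmr import (
    DMRParams,
    GeneModel,
    SimConfig,
    call_dmrs,
    chromosome_correlations,
    cluster_samples,
    gene_metaprofile,
    make_genome,
    make_truth,
    simulate_depths,
    window_profile,
)
from medipdmr.genome import GenomeModel
from medipdmr.matrix import DepthMatrix
from medipdmr.preprocess import filter_low_coverage, normalize
from conftest import make_matrix


def grid_genome(chroms, window_bp=10_000, spacing=100):
    """Genome with evenly spaced CpGs and flat tracks."""
    windows = []
    sites = {}
    for name, size in chroms:
        starts = np.arange(0, size, window_bp)
        ends = np.minimum(starts + window_bp, size)
        windows.append(pd.DataFrame(
            {"chrom": name, "start": starts, "end": ends, "gc": 0.4,
             "cpg_oe": 0.3, "n_cpg": (ends - starts) // spacing}
        ))
        sites[name] = np.arange(0, size - 2, spacing)
    return GenomeModel(list(chroms), window_bp, pd.concat(windows, ignore_index=True), sites)


def matrix_on(genome, depth_fn, samples=("a", "b"), groups=("A", "B")):
    sites = genome.sites_frame()
    depth = np.column_stack([depth_fn(sites, j) for j in range(len(samples))])
    return DepthMatrix(sites=sites, depth=depth, samples=list(samples),
                       groups=list(groups), normalized=True)


class TestWindowProfile:
    def test_constant_field_gives_constant_window_means(self):
        genome = grid_genome([("chr1", 50_000)])
        m = matrix_on(genome, lambda s, j: np.full(len(s), 7.0))
        wp = window_profile(m, genome, window_bp=10_000)
        assert np.allclose(wp.windows["mean_a"], 7.0)

    def test_hand_average_in_single_window(self):
        genome = grid_genome([("chr1", 1_000)], window_bp=1_000, spacing=100)
        vals = np.arange(10, dtype=float) * 3 + 1
        m = matrix_on(genome, lambda s, j: vals)
        wp = window_profile(m, genome, window_bp=1_000)
        assert wp.windows["mean_a"].iloc[0] == pytest.approx(vals.mean())
        assert wp.windows["n_cpg"].iloc[0] == 10

    def test_empty_windows_reported_missing(self):
        genome = grid_genome([("chr1", 30_000)])
        genome.cpg_sites["chr1"] = np.array([100, 200])  # only first window
        m = DepthMatrix(
            sites=pd.DataFrame({"chrom": "chr1", "pos": [100, 200]}),
            depth=np.ones((2, 2)), samples=["a", "b"], groups=["A", "B"],
        )
        wp = window_profile(m, genome, window_bp=10_000)
        assert wp.windows["mean_a"].isna().tolist() == [False, True, True]

    def test_half_step_doubles_windows(self):
        genome = grid_genome([("chr1", 100_000)])
        m = matrix_on(genome, lambda s, j: np.ones(len(s)))
        full = window_profile(m, genome, window_bp=20_000)
        half = window_profile(m, genome, window_bp=20_000, step_bp=10_000)
        assert len(half.windows) == pytest.approx(2 * len(full.windows), abs=1)

    def test_window_validation(self):
        genome = grid_genome([("chr1", 10_000)])
        m = matrix_on(genome, lambda s, j: np.ones(len(s)))
        with pytest.raises(ValueError):
            window_profile(m, genome, window_bp=0)


class TestChromosomeCorrelations:
    def test_linear_relation_with_length(self):
        chroms = [(f"chr{i}", 20_000 * (i + 1)) for i in range(5)]
        genome = grid_genome(chroms)
        sizes = dict(chroms)
        m = matrix_on(genome, lambda s, j: 1.0 + 2e-5 * np.vectorize(sizes.get)(s["chrom"]))
        wp = window_profile(m, genome, window_bp=10_000)
        corr = chromosome_correlations(wp, genome)
        row = corr[corr["variable"] == "length"].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-9)
        neg = matrix_on(genome, lambda s, j: 10.0 - 2e-5 * np.vectorize(sizes.get)(s["chrom"]))
        wneg = window_profile(neg, genome, window_bp=10_000)
        rneg = chromosome_correlations(wneg, genome)
        assert rneg[rneg["variable"] == "length"].iloc[0]["r"] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_flagged(self):
        chroms = [(f"chr{i}", 20_000 * (i + 1)) for i in range(4)]
        genome = grid_genome(chroms)  # constant gc track
        m = matrix_on(genome, lambda s, j: np.ones(len(s)))
        wp = window_profile(m, genome, window_bp=10_000)
        corr = chromosome_correlations(wp, genome)
        assert not corr[corr["variable"] == "gc"].iloc[0]["ok"]

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(10), rng.random(10)
        r, _ = stats.pearsonr(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        want = cov / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(want, abs=1e-12)

    def test_needs_three_chromosomes(self):
        genome = grid_genome([("chr1", 20_000), ("chr2", 20_000)])
        m = matrix_on(genome, lambda s, j: np.ones(len(s)))
        wp = window_profile(m, genome, window_bp=10_000)
        with pytest.raises(ValueError):
            chromosome_correlations(wp, genome)


class TestGeneMetaprofile:
    def test_constant_data_gives_flat_profile(self):
        genome = grid_genome([("chr1", 50_000)], spacing=50)
        m = matrix_on(genome, lambda s, j: np.full(len(s), 4.0))
        genes = [GeneModel("g", "chr1", "+", 10_000, 20_000, exons=[(10_000, 20_000)])]
        mp = gene_metaprofile(m, genes)
        curve = mp.bins["mean_A"]
        assert np.nanstd(curve) == 0
        assert np.nanmean(curve) == pytest.approx(4.0)

    def test_minus_strand_mirrors_plus_strand(self):
        genome = grid_genome([("chr1", 50_000)], spacing=50)
        pos = genome.sites_frame()["pos"].to_numpy()
        ramp = pos / 1_000.0
        m = matrix_on(genome, lambda s, j: ramp)
        plus = gene_metaprofile(
            m, [GeneModel("g", "chr1", "+", 10_000, 20_000, exons=[(10_000, 20_000)])]
        )
        minus = gene_metaprofile(
            m, [GeneModel("g", "chr1", "-", 10_000, 20_000, exons=[(10_000, 20_000)])]
        )
        a = plus.bins["mean_A"].to_numpy()
        b = minus.bins["mean_A"].to_numpy()
        assert np.allclose(a, b[::-1], atol=0.11)  # bin-offset discretisation

    def test_hand_placed_depths_match_bin_means(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [4_950, 5_050, 5_150, 7_050]})
        depth = np.array([[2.0], [4.0], [6.0], [10.0]])
        m = DepthMatrix(sites=sites, depth=depth, samples=["a"], groups=["A"])
        genes = [GeneModel("g", "chr1", "+", 5_000, 7_000, exons=[(5_000, 7_000)])]
        mp = gene_metaprofile(m, genes, flank_bp=2_000, body_bins=4, flank_bin_bp=1_000)
        bins = mp.bins
        up = bins[bins["segment"] == "upstream"]["mean_a"].tolist()
        body = bins[bins["segment"] == "body"]["mean_a"].tolist()
        down = bins[bins["segment"] == "downstream"]["mean_a"].tolist()
        assert np.isnan(up[0]) and up[1] == 2.0  # 4,950 sits in the near flank bin
        # 5,050 and 5,150 both fall in the first 500 bp body bin
        assert body[0] == pytest.approx(5.0)
        assert all(np.isnan(v) for v in body[1:])
        assert down[0] == pytest.approx(10.0) and np.isnan(down[1])

    def test_short_gene_skipped_with_warning(self):
        genome = grid_genome([("chr1", 10_000)], spacing=50)
        m = matrix_on(genome, lambda s, j: np.ones(len(s)))
        genes = [GeneModel("tiny", "chr1", "+", 100, 120, exons=[(100, 120)])]
        with pytest.warns(UserWarning, match="skipped"):
            mp = gene_metaprofile(m, genes)
        assert mp.n_genes_skipped == 1


class TestClusterSamples:
    @pytest.fixture(scope="class")
    def planted(self):
        # mixed directions (separation must come from profile shape) and a
        # density-linked baseline (shared genome-wide structure, as in real
        # MeDIP coverage, so replicates correlate within groups)
        cfg = SimConfig(seed=23, chromosomes=(("chr1", 900_000),), n_dmrs=12,
                        dmr_direction="alternate", density_exponent=1.0)
        genome = make_genome(cfg)
        truth = make_truth(genome, cfg)
        matrix = normalize(filter_low_coverage(simulate_depths(genome, truth, cfg)))
        dmrs = truth.regions[["chrom", "start", "end"]].copy()
        return matrix, dmrs

    def test_groups_separate_at_top_split(self, planted):
        matrix, dmrs = planted
        assert len(dmrs) >= 2
        res = cluster_samples(matrix, dmrs)
        split = sorted(res.top_split(), key=len)
        groups = [sorted(s[: s.index("_")] for s in side) for side in split]
        assert groups in ([["LBF"] * 3, ["RBF"] * 3], [["RBF"] * 3, ["LBF"] * 3])
        corr = res.correlation.to_numpy()
        within = [corr[i, j] for i in range(3) for j in range(3) if i != j]
        within += [corr[i, j] for i in range(3, 6) for j in range(3, 6) if i != j]
        between = [corr[i, j] for i in range(3) for j in range(3, 6)]
        assert min(within) > max(between)

    def test_duplicated_sample_merges_first_at_zero_height(self, planted):
        matrix, dmrs = planted
        dup = dataclasses.replace(
            matrix,
            depth=np.column_stack([matrix.depth, matrix.depth[:, 0]]),
            samples=matrix.samples + ["dup"],
            groups=matrix.groups + [matrix.groups[0]],
            scale_factors=None,
            library_sizes=None,
        )
        res = cluster_samples(dup, dmrs)
        assert res.correlation.loc["dup", matrix.samples[0]] == pytest.approx(1.0)
        first_merge = res.linkage[0]
        assert first_merge[3] == 2 and first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_sample_order_permutation_consistent(self, planted):
        matrix, dmrs = planted
        idx = [5, 2, 0, 4, 1, 3]
        perm = dataclasses.replace(
            matrix,
            depth=matrix.depth[:, idx],
            samples=[matrix.samples[i] for i in idx],
            groups=[matrix.groups[i] for i in idx],
            scale_factors=None,
            library_sizes=None,
        )
        a = cluster_samples(matrix, dmrs).correlation
        b = cluster_samples(perm, dmrs).correlation
        assert np.allclose(
            a.loc[perm.samples, perm.samples].to_numpy(), b.to_numpy()
        )

    def test_constant_sample_rejected(self, planted):
        matrix, dmrs = planted
        bad = dataclasses.replace(matrix, depth=np.ones_like(matrix.depth))
        with pytest.raises(ValueError):
            cluster_samples(bad, dmrs)
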