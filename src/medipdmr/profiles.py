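"""Genome-scale methylome description.

Window tracks (1 Mb default) of mean normalized depth, chromosome-level
correlations of methylation with length / GC / CpG_o/e, strand-aware
gene-body metaprofiles (2 kb flanks around the scaled gene body), and
hierarchical clustering of samples on DMR depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotate import GeneModel
from .genome import GenomeModel
from .matrix import DepthMatrix


@dataclass
class WindowProfile:
    """Per-window mean depth with GC and CpG_o/e covariates.

    ``windows`` columns: chrom, start, end, n_cpg, gc, cpg_oe, one mean
    column per sample and one ``mean_<group>`` per group.  Windows with no
    member CpG keep NaN means (missing, not zero).
    """

    windows: pd.DataFrame
    samples: list
    groups: list


@dataclass
class MetaProfile:
    """Gene-body metaprofile: flank bins + scaled body bins per group."""

    bins: pd.DataFrame  # columns: segment, bin, mean_<group>...
    n_genes_used: int
    n_genes_skipped: int


@dataclass
class ClusterResult:
    correlation: pd.DataFrame  # sample x sample Pearson r
    linkage: np.ndarray  # scipy hierarchy linkage (average, 1 - r)
    samples: list

    def top_split(self) -> list:
        """Sample labels of the two clusters at the dendrogram's top split."""
        assign = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        return [
            [s for s, a in zip(self.samples, assign) if a == k]
            for k in sorted(set(assign))
        ]


# ----------------------------------------------------------------------
def window_profile(
    matrix: DepthMatrix,
    genome: GenomeModel,
    window_bp: int = 1_000_000,
    step_bp: int | None = None,
) -> WindowProfile:
    """Mean member-CpG depth per sliding window.

    Default step equals the window (non-overlapping tiling); pass a smaller
    ``step_bp`` for overlapping smoothing.  GC and CpG_o/e are
    length-weighted means of the genome-track windows each profile window
    covers.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step_bp = step_bp or window_bp
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    rows = []
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    gw = genome.windows
    for chrom, size in genome.chromosomes:
        m = chrom_arr == chrom
        pos = pos_arr[m]
        depth = matrix.depth[m]
        track = gw[gw["chrom"] == chrom]
        for start in range(0, size, step_bp):
            end = min(start + window_bp, size)
            sel = (pos >= start) & (pos < end)
            n = int(sel.sum())
            over = track[(track["start"] < end) & (track["end"] > start)]
            w = (np.minimum(over["end"], end) - np.maximum(over["start"], start)).to_numpy()
            gc = float(np.average(over["gc"], weights=w)) if len(over) else np.nan
            oe = float(np.average(over["cpg_oe"], weights=w)) if len(over) else np.nan
            row = {"chrom": chrom, "start": start, "end": end, "n_cpg": n, "gc": gc, "cpg_oe": oe}
            means = depth[sel].mean(axis=0) if n else np.full(matrix.n_samples, np.nan)
            for j, s in enumerate(matrix.samples):
                row[f"mean_{s}"] = means[j]
            for g in matrix.group_names:
                idx = matrix.group_indices(g)
                row[f"mean_{g}"] = means[idx].mean() if n else np.nan
            rows.append(row)
            if end >= size:
                break
    return WindowProfile(
        windows=pd.DataFrame(rows), samples=list(matrix.samples), groups=list(matrix.groups)
    )


def chromosome_correlations(
    profile: WindowProfile, genome: GenomeModel, group: str | None = None
) -> pd.DataFrame:
    """Pearson r (and two-sided P) of chromosome methylation against
    chromosome length, GC and CpG_o/e — one point per chromosome.

    Methylation per chromosome is the CpG-count-weighted mean of its window
    means.  Needs at least 3 chromosomes; zero-variance covariates are
    flagged with NaN r.
    """
    if len(genome.chromosomes) < 3:
        raise ValueError("need at least 3 chromosomes")
    col = f"mean_{group}" if group else None
    if col is None:
        grp_cols = [f"mean_{g}" for g in dict.fromkeys(profile.groups)]
    w = profile.windows
    meth, length, gc, oe = [], [], [], []
    for chrom, size in genome.chromosomes:
        sub = w[(w["chrom"] == chrom) & (w["n_cpg"] > 0)]
        if len(sub) == 0:
            continue
        vals = sub[col] if col else sub[grp_cols].mean(axis=1)
        weights = sub["n_cpg"].to_numpy()
        meth.append(float(np.average(vals, weights=weights)))
        length.append(size)
        gc.append(float(np.average(sub["gc"], weights=weights)))
        oe.append(float(np.average(sub["cpg_oe"], weights=weights)))
    out = []
    meth = np.asarray(meth)
    for name, x in [("length", np.asarray(length, float)), ("gc", np.asarray(gc)), ("cpg_oe", np.asarray(oe))]:
        if np.std(x) == 0 or np.std(meth) == 0:
            out.append((name, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(meth, x)
        out.append((name, r, p, True))
    return pd.DataFrame(out, columns=["variable", "r", "p", "ok"])


# ----------------------------------------------------------------------
def gene_metaprofile(
    matrix: DepthMatrix,
    genes: list,
    flank_bp: int = 2000,
    body_bins: int = 40,
    flank_bin_bp: int = 100,
) -> MetaProfile:
    """Mean depth around gene bodies, 5'->3' (strand-aware).

    Bins: ``flank_bp/flank_bin_bp`` upstream bins before the TSS, the gene
    body rescaled to ``body_bins`` bins, the same number of downstream bins
    after the TES.  Bin means are site-weighted across genes.  Genes
    shorter than ``body_bins`` bp are skipped with a warning.
    """
    n_flank = flank_bp // flank_bin_bp
    total = 2 * n_flank + body_bins
    sums = np.zeros((total, matrix.n_samples))
    counts = np.zeros(total)
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    used = skipped = 0
    for g in genes:
        body = g.end - g.start
        if body < body_bins:
            skipped += 1
            continue
        used += 1
        m = (
            (chrom_arr == g.chrom)
            & (pos_arr >= g.start - flank_bp)
            & (pos_arr < g.end + flank_bp)
        )
        if not m.any():
            continue
        pos = pos_arr[m]
        depth = matrix.depth[m]
        # signed distance in transcript orientation
        if g.strand == "+":
            upstream = pos < g.start
            downstream = pos >= g.end
            d_up = g.start - 1 - pos  # 0 = base just before TSS
            frac = (pos - g.start) / body
            d_dn = pos - g.end
        else:
            upstream = pos >= g.end
            downstream = pos < g.start
            d_up = pos - g.end  # 0 = base just past gene end = just before TSS
            frac = (g.end - 1 - pos) / body
            d_dn = g.start - 1 - pos
        bins = np.empty(len(pos), dtype=int)
        bins[upstream] = n_flank - 1 - (d_up[upstream] // flank_bin_bp)
        bodym = ~upstream & ~downstream
        bins[bodym] = n_flank + np.clip((frac[bodym] * body_bins).astype(int), 0, body_bins - 1)
        bins[downstream] = n_flank + body_bins + (d_dn[downstream] // flank_bin_bp)
        ok = (bins >= 0) & (bins < total)
        np.add.at(sums, bins[ok], depth[ok])
        np.add.at(counts, bins[ok], 1)
    if skipped:
        warnings.warn(f"skipped {skipped} gene(s) shorter than {body_bins} bp")
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    segment = (
        ["upstream"] * n_flank + ["body"] * body_bins + ["downstream"] * n_flank
    )
    out = pd.DataFrame({"segment": segment, "bin": range(total), "n_sites": counts})
    for j, s in enumerate(matrix.samples):
        out[f"mean_{s}"] = means[:, j]
    for gname in matrix.group_names:
        idx = matrix.group_indices(gname)
        out[f"mean_{gname}"] = means[:, idx].mean(axis=1)
    return MetaProfile(bins=out, n_genes_used=used, n_genes_skipped=skipped)


# ----------------------------------------------------------------------
def cluster_samples(matrix: DepthMatrix, dmrs: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of samples on per-DMR mean depths.

    Distance is ``1 - Pearson r`` with average linkage — the usual check of
    biological reproducibility across MeDIP libraries.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if len(dmrs) < 2:
        raise ValueError("need at least 2 DMRs")
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    prof = np.empty((len(dmrs), matrix.n_samples))
    for i, t in enumerate(dmrs.itertuples(index=False)):
        m = (chrom_arr == t.chrom) & (pos_arr >= t.start) & (pos_arr < t.end)
        prof[i] = matrix.depth[m].mean(axis=0) if m.any() else np.nan
    prof = prof[~np.isnan(prof).any(axis=1)]
    if prof.shape[0] < 2:
        raise ValueError("fewer than 2 DMRs with member CpGs")
    if (prof.std(axis=0) == 0).any():
        raise ValueError("constant sample vector: correlation undefined")
    corr = np.corrcoef(prof.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(
        correlation=pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples),
        linkage=link,
        samples=list(matrix.samples),
    )


# ----------------------------------------------------------------------
def plot_metaprofile(profile: MetaProfile, path) -> None:
    """Optional PNG of the group metaprofile curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    groups = [c for c in profile.bins.columns if c.startswith("mean_")]
    for c in groups:
        ax.plot(profile.bins["bin"], profile.bins[c], label=c.removeprefix("mean_"))
    ax.set_xlabel("bin (5' flank - body - 3' flank)")
    ax.set_ylabel("mean normalized depth")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
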