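"""Synthetic-data generator for the whole pipeline.

Emulates a small multi-chromosome genome whose CpG density tracks window GC,
two groups x 3 replicate MeDIP depth tracks with negative-binomial noise,
planted DMRs of configurable size and effect, aligned fragments + FASTQ for
the QC stage, bisulfite clone matrices and qPCR Ct tables.  A
:class:`TruthSet` records the planted regions for recovery testing.

Noise convention: depths are NB1 negative binomial, ``var = (1 + a) * mu``
with dispersion ``a`` (gamma-Poisson with shape ``mu/a``); ``a -> 0`` is the
Poisson limit.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeModel
from .matrix import DepthMatrix
from .validate import CloneMatrix

_QUAL_HIGH = 40
_QUAL_LOW = 4  # below the Phred 5 QC threshold


@dataclass
class SimConfig:
    """All generator knobs, serializable to/from YAML.

    The defaults mirror the study design: two breeds x three biological
    replicates, ~30x mean depth at retained CpGs, 50 bp reads from
    100-500 bp sonication fragments.
    """

    seed: int = 0
    chromosomes: tuple = (("chr1", 2_000_000), ("chr2", 1_500_000), ("chr3", 700_000))
    window_bp: int = 10_000
    gc_mean: float = 0.41
    gc_sd: float = 0.05
    cpg_oe_mean: float = 0.30
    cpg_oe_sd: float = 0.05
    n_samples_per_group: int = 3
    group_names: tuple = ("LBF", "RBF")
    baseline_mean: float = 30.0
    dispersion: float = 0.2  # NB1: var = (1 + dispersion) * mean
    density_exponent: float = 0.0  # depth ~ baseline * (local CpG density)^g
    n_dmrs: int = 50
    dmr_n_cpg: int = 10
    dmr_max_span_bp: int = 2_000
    dmr_intra_gap_bp: int = 200
    dmr_effect: float = 3.0
    dmr_direction: str = "alternate"  # alternate | hyper | hypo
    dmr_min_separation_bp: int = 10_000
    read_length: int = 50
    fragment_min_bp: int = 100
    fragment_max_bp: int = 500
    n_injection_rate: float = 0.0
    low_quality_rate: float = 0.0
    multi_hit_fraction: float = 0.0
    n_genes: int = 150
    gene_min_bp: int = 5_000
    gene_max_bp: int = 40_000
    exons_per_gene: tuple = (2, 8)

    def __post_init__(self) -> None:
        for name in (
            "window_bp",
            "n_samples_per_group",
            "read_length",
            "fragment_min_bp",
            "fragment_max_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive chromosome length for {name}")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dmr_effect <= 0:
            raise ValueError("dmr_effect must be positive")
        if not 0 <= self.n_injection_rate <= 1:
            raise ValueError("n_injection_rate must be in [0, 1]")
        if not 0 <= self.low_quality_rate <= 1:
            raise ValueError("low_quality_rate must be in [0, 1]")
        if not 0 <= self.multi_hit_fraction <= 1:
            raise ValueError("multi_hit_fraction must be in [0, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "chromosomes" in d:
            d["chromosomes"] = tuple(tuple(c) for c in d["chromosomes"])
        for key in ("group_names", "exons_per_gene"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{g}_{i + 1}"
            for g in self.group_names
            for i in range(self.n_samples_per_group)
        ]

    @property
    def sample_groups(self) -> list[str]:
        return [g for g in self.group_names for _ in range(self.n_samples_per_group)]


@dataclass
class TruthSet:
    """Planted DMR locations and effects — the recovery-test oracle.

    ``effect`` is the multiplicative depth ratio group1/group2 inside the
    region; ``direction`` is ``hyper`` in group1 iff effect > 1.
    """

    regions: pd.DataFrame  # chrom, start, end, effect, direction

    def __post_init__(self) -> None:
        r = self.regions.reset_index(drop=True)
        self.regions = r
        if len(r) == 0:
            return
        if (r["effect"] <= 0).any():
            raise ValueError("effects must be positive")
        if (r["effect"] == 1).any():
            raise ValueError("effect 1 is not a DMR")
        want = np.where(r["effect"] > 1, "hyper", "hypo")
        if (r["direction"].to_numpy() != want).any():
            raise ValueError("direction inconsistent with effect")
        for _, grp in r.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError("truth regions overlap")

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path) -> None:
        df = self.regions.copy()
        df["name"] = [f"truth_{i}" for i in range(len(df))]
        df["score"] = 0
        df["strand"] = "."
        df[["chrom", "start", "end", "name", "score", "strand", "effect"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    @classmethod
    def from_bed(cls, path) -> "TruthSet":
        df = pd.read_csv(
            path,
            sep="\t",
            names=["chrom", "start", "end", "name", "score", "strand", "effect"],
        )
        df["direction"] = np.where(df["effect"] > 1, "hyper", "hypo")
        return cls(df[["chrom", "start", "end", "effect", "direction"]])


# ----------------------------------------------------------------------
# genome
# ----------------------------------------------------------------------
def make_genome(config: SimConfig, seed: int | None = None) -> GenomeModel:
    """Draw a genome whose CpG count per window follows the density link.

    Expected CpG count of a window is ``len * cpg_oe * (GC/2)^2`` — CpG
    density rises monotonically with window GC, which later drives the
    methylation-vs-GC profile correlations.  Realized counts are Poisson;
    positions are uniform within the window (minimum spacing 2 bp so
    dinucleotides cannot overlap).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    cpg_sites: dict[str, np.ndarray] = {}
    for name, length in config.chromosomes:
        starts = np.arange(0, length, config.window_bp)
        ends = np.minimum(starts + config.window_bp, length)
        gc = np.clip(rng.normal(config.gc_mean, config.gc_sd, len(starts)), 0.0, 0.9)
        oe = np.clip(
            rng.normal(config.cpg_oe_mean, config.cpg_oe_sd, len(starts)), 0.0, 1.2
        )
        expected = (ends - starts) * oe * (gc / 2.0) ** 2
        counts = rng.poisson(expected)
        pos_all = []
        for s, e, m in zip(starts, ends, counts):
            hi = min(e, length - 2)
            if m <= 0 or hi <= s:
                pos_all.append(np.array([], dtype=int))
                continue
            p = np.unique(rng.integers(s, hi, m))
            keep = np.ones(len(p), bool)  # enforce >= 2 bp spacing
            last = -10
            for i, v in enumerate(p):
                if v - last < 2:
                    keep[i] = False
                else:
                    last = v
            pos_all.append(p[keep])
        pos = np.concatenate(pos_all) if pos_all else np.array([], dtype=int)
        cpg_sites[name] = pos
        n_obs = np.array([len(a) for a in pos_all])
        with np.errstate(divide="ignore", invalid="ignore"):
            exp0 = (ends - starts) * (gc / 2.0) ** 2
            oe_obs = np.where(exp0 > 0, n_obs / np.maximum(exp0, 1e-300), 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "start": starts,
                    "end": ends,
                    "gc": gc,
                    "cpg_oe": oe_obs,
                    "n_cpg": n_obs,
                }
            )
        )
    windows = pd.concat(rows, ignore_index=True)
    return GenomeModel(list(config.chromosomes), config.window_bp, windows, cpg_sites)


def expected_cpg_count(length_bp: float, gc: float, cpg_oe: float) -> float:
    """Closed form of the generator's density link (for calibration checks)."""
    return length_bp * cpg_oe * (gc / 2.0) ** 2


# ----------------------------------------------------------------------
# truth
# ----------------------------------------------------------------------
def make_truth(
    genome: GenomeModel, config: SimConfig, seed: int | None = None
) -> TruthSet:
    """Plant ``n_dmrs`` non-overlapping regions on CpG-dense runs.

    Each planted region spans ``dmr_n_cpg`` consecutive CpGs whose internal
    spacing is at most ``dmr_intra_gap_bp`` and whose total span is at most
    ``dmr_max_span_bp`` — i.e. the CpG-cluster geometry real DMRs live in.
    Directions alternate hyper/hypo at ``effect`` and ``1/effect``.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 7_654_321
    )
    if config.n_dmrs == 0:
        return TruthSet(
            pd.DataFrame(columns=["chrom", "start", "end", "effect", "direction"])
        )
    if config.dmr_effect == 1.0:
        raise ValueError("dmr_effect must differ from 1 when planting DMRs")
    k = config.dmr_n_cpg
    candidates = []
    for name, _ in genome.chromosomes:
        pos = genome.cpg_sites.get(name, np.array([], int))
        if len(pos) < k:
            continue
        span = pos[k - 1:] - pos[: len(pos) - k + 1]
        gaps = np.diff(pos)
        max_gap = np.array(
            [gaps[i : i + k - 1].max() if k > 1 else 0 for i in range(len(pos) - k + 1)]
        )
        ok = (span + 2 <= config.dmr_max_span_bp) & (max_gap <= config.dmr_intra_gap_bp)
        for i in np.flatnonzero(ok):
            candidates.append((name, int(pos[i]), int(pos[i + k - 1] + 2)))
    rng.shuffle(candidates)
    chosen: list[tuple[str, int, int]] = []
    sep = config.dmr_min_separation_bp
    for cand in candidates:
        if len(chosen) >= config.n_dmrs:
            break
        if all(
            c[0] != cand[0] or cand[1] >= c[2] + sep or cand[2] <= c[1] - sep
            for c in chosen
        ):
            chosen.append(cand)
    if len(chosen) < config.n_dmrs:
        raise ValueError(
            f"genome supports only {len(chosen)} of {config.n_dmrs} requested DMRs"
        )
    chosen.sort()
    base_eff = max(config.dmr_effect, 1.0 / config.dmr_effect)
    rows = []
    for i, (chrom, start, end) in enumerate(chosen):
        if config.dmr_direction == "alternate":
            hyper = i % 2 == 0
        elif config.dmr_direction in ("hyper", "hypo"):
            hyper = config.dmr_direction == "hyper"
        else:
            raise ValueError(f"unknown dmr_direction {config.dmr_direction!r}")
        eff = base_eff if hyper else 1.0 / base_eff
        rows.append((chrom, start, end, eff, "hyper" if eff > 1 else "hypo"))
    return TruthSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "effect", "direction"])
    )


# ----------------------------------------------------------------------
# depths
# ----------------------------------------------------------------------
def _nb1(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB1 draw: var = (1 + dispersion) * mean; Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(shape[pos], p)
    return out


def simulate_depths(
    genome: GenomeModel,
    truth: TruthSet,
    config: SimConfig,
    seed: int | None = None,
) -> DepthMatrix:
    """Raw per-CpG depths: NB1 around ``baseline_mean``, boosted by
    ``effect`` for group-1 samples at sites inside planted regions.

    With ``density_exponent > 0`` the baseline is additionally modulated by
    the local window CpG density (normalized to genome mean), making the
    MeDIP enrichment link between methylation signal and CpG density
    explicit.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_234_567
    )
    sites = genome.sites_frame()
    n = len(sites)
    base = np.full(n, config.baseline_mean, dtype=float)
    if config.density_exponent != 0.0:
        dens = np.empty(n)
        offset = 0
        w = genome.windows
        mean_density = (w["n_cpg"].sum() / (w["end"] - w["start"]).sum()) or 1.0
        for name, _ in genome.chromosomes:
            pos = genome.cpg_sites.get(name, np.array([], int))
            if len(pos) == 0:
                continue
            widx = genome.window_of(name, pos)
            local = (
                w["n_cpg"].to_numpy()[widx]
                / (w["end"] - w["start"]).to_numpy()[widx]
            )
            dens[offset : offset + len(pos)] = local / mean_density
            offset += len(pos)
        base = base * np.maximum(dens, 1e-6) ** config.density_exponent

    effect = np.ones(n)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    lengths = dict(genome.chromosomes)
    for _, r in truth.regions.iterrows():
        if r["chrom"] not in lengths:
            raise ValueError(f"truth region on unknown chromosome {r['chrom']}")
        if r["end"] > lengths[r["chrom"]] or r["start"] < 0:
            raise ValueError("truth region outside chromosome bounds")
        inside = (chrom_arr == r["chrom"]) & (pos_arr >= r["start"]) & (pos_arr < r["end"])
        effect[inside] = r["effect"]

    n_per = config.n_samples_per_group
    depth = np.empty((n, 2 * n_per), dtype=float)
    for j in range(n_per):  # group 1 carries the effect
        depth[:, j] = _nb1(rng, base * effect, config.dispersion)
    for j in range(n_per):
        depth[:, n_per + j] = _nb1(rng, base, config.dispersion)
    return DepthMatrix(
        sites=sites,
        depth=depth,
        samples=config.sample_names,
        groups=config.sample_groups,
        normalized=False,
    )


# ----------------------------------------------------------------------
# reads
# ----------------------------------------------------------------------
@dataclass
class SimReads:
    """Aligned fragments plus the matching FASTQ records for one run."""

    alignments: pd.DataFrame  # sample, chrom, start, end, name, n_hits, strand
    fastq: dict  # sample -> list of (read_id, sequence, quality string)

    def write_bed(self, outdir) -> None:
        """One BED6 per sample; the name field carries ``id|n_hits``."""
        os.makedirs(outdir, exist_ok=True)
        for sample, grp in self.alignments.groupby("sample", sort=False):
            df = grp.copy()
            df["bedname"] = df["name"] + "|" + df["n_hits"].astype(str)
            df["score"] = 0
            df[["chrom", "start", "end", "bedname", "score", "strand"]].to_csv(
                os.path.join(outdir, f"{sample}.bed"),
                sep="\t",
                index=False,
                header=False,
            )

    def write_fastq(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for sample, recs in self.fastq.items():
            with open(os.path.join(outdir, f"{sample}.fastq"), "w") as fh:
                for rid, seq, qual in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def emit_reads(
    depths: DepthMatrix,
    genome: GenomeModel,
    config: SimConfig,
    seed: int | None = None,
) -> SimReads:
    """Emit aligned fragments realizing the simulated depths, plus FASTQ.

    Fragments are clipped so that each overlaps exactly its own CpG
    dinucleotide and no neighbouring one; the per-site fragment-overlap
    count therefore round-trips exactly through duplicate collapse and
    depth counting.  A ``multi_hit_fraction`` of fragments is emitted as
    multi-hit records whose decoy coordinates sort after the primary
    alignment, so coordinate-first collapse retains the true location.
    FASTQ reads mirror the fragments one-to-one, with configured fractions
    violating the N-count and low-quality QC rules.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 999_331
    )
    lengths = dict(genome.chromosomes)
    aln_rows = []
    fastq: dict[str, list] = {s: [] for s in depths.samples}
    chrom_arr = depths.sites["chrom"].to_numpy()
    pos_arr = depths.sites["pos"].to_numpy()
    for j, sample in enumerate(depths.samples):
        counts = depths.depth[:, j].astype(int)
        frag_id = 0
        for name in pd.unique(chrom_arr):
            m = chrom_arr == name
            pos = pos_arr[m]
            cnt = counts[m]
            if cnt.sum() == 0:
                continue
            lo = np.concatenate([[0], pos[:-1] + 2])
            hi = np.concatenate([pos[1:], [lengths[name]]])
            site_idx = np.repeat(np.arange(len(pos)), cnt)
            flen = rng.integers(
                config.fragment_min_bp, config.fragment_max_bp + 1, len(site_idx)
            )
            offset = rng.integers(0, np.maximum(flen - 1, 1))
            start = np.maximum(lo[site_idx], pos[site_idx] - offset)
            end = np.minimum(hi[site_idx], start + flen)
            end = np.maximum(end, pos[site_idx] + 2)  # always cover the CpG
            multi = rng.random(len(site_idx)) < config.multi_hit_fraction
            n_hits = np.where(multi, rng.integers(2, 5, len(site_idx)), 1)
            for i in range(len(site_idx)):
                rid = f"{sample}:frag{frag_id}"
                frag_id += 1
                aln_rows.append(
                    (sample, name, int(start[i]), int(end[i]), rid, int(n_hits[i]), "+")
                )
                for k in range(1, int(n_hits[i])):  # decoys sort after primary
                    ds = int(start[i]) + 10_000 * k
                    de = ds + int(end[i] - start[i])
                    if de > lengths[name]:
                        ds = int(start[i]) + k
                        de = min(ds + int(end[i] - start[i]), lengths[name])
                    aln_rows.append((sample, name, ds, de, rid, int(n_hits[i]), "+"))
                fastq[sample].append(
                    _make_read(rng, rid, config)
                )
    alignments = pd.DataFrame(
        aln_rows, columns=["sample", "chrom", "start", "end", "name", "n_hits", "strand"]
    )
    return SimReads(alignments=alignments, fastq=fastq)


def _make_read(rng: np.random.Generator, rid: str, config: SimConfig):
    L = config.read_length
    seq = rng.choice(list("ACGT"), L)
    qual = np.full(L, _QUAL_HIGH)
    u = rng.random()
    if u < config.n_injection_rate:
        k = int(rng.integers(6, min(11, L + 1)))  # > 5 Ns -> QC drop
        seq[rng.choice(L, k, replace=False)] = "N"
    elif u < config.n_injection_rate + config.low_quality_rate:
        k = int(rng.integers(L // 2 + 1, L + 1))  # > 50% below Phred 5
        qual[rng.choice(L, k, replace=False)] = _QUAL_LOW
    return rid, "".join(seq), "".join(chr(33 + q) for q in qual)


# ----------------------------------------------------------------------
# validation-arm inputs
# ----------------------------------------------------------------------
def simulate_clone_matrix(
    n_clones: int,
    n_sites: int,
    site_methylation_probs,
    seed: int = 0,
    region: str = "region",
    group: str = "group1",
) -> CloneMatrix:
    """Bernoulli clone x CpG matrix (1 = methylated, as in BSP subcloning)."""
    probs = np.broadcast_to(np.asarray(site_methylation_probs, float), (n_sites,))
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("methylation probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = (rng.random((n_clones, n_sites)) < probs).astype(np.int8)
    return CloneMatrix(values=values, region=region, group=group)


def simulate_qpcr(
    true_fold_changes: dict,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_samples_per_group: int = 3,
    n_replicates: int = 3,
    group_names: tuple = ("LBF", "RBF"),
    reference_genes: tuple = ("ACTB", "TBP", "TOP2B"),
) -> pd.DataFrame:
    """Ct table for the 2^-ddCt computation.

    ``Ct = base + sample loading offset - log2(expression) + noise``; the
    second group is the calibrator (expression 1), the first group expresses
    each target at its configured fold change.  Reference genes carry the
    loading offset only, so ddCt recovers the fold change.
    """
    for g, fc in true_fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for {g} must be positive")
    rng = np.random.default_rng(seed)
    base_ct = {g: 18.0 + 1.5 * i for i, g in enumerate(reference_genes)}
    rows = []
    for gi, gname in enumerate(group_names):
        for si in range(n_samples_per_group):
            sample = f"{gname}_{si + 1}"
            loading = rng.normal(0.0, 0.5)
            for gene, fc in true_fold_changes.items():
                expr = fc if gi == 0 else 1.0
                mu = 24.0 + loading - np.log2(expr)
                for _ in range(n_replicates):
                    rows.append(
                        (sample, gname, gene, mu + rng.normal(0.0, ct_noise_sd))
                    )
            for gene in reference_genes:
                mu = base_ct[gene] + loading
                for _ in range(n_replicates):
                    rows.append(
                        (sample, gname, gene, mu + rng.normal(0.0, ct_noise_sd))
                    )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


# ----------------------------------------------------------------------
# gene models
# ----------------------------------------------------------------------
def make_genes(
    genome: GenomeModel, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Random non-overlapping gene models (for annotation and profiles).

    Returns a DataFrame with columns ``gene_id, chrom, strand, start, end,
    exon_starts, exon_ends`` (exon lists comma-joined, BED12-style).
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 24_680
    )
    rows = []
    total = sum(l for _, l in genome.chromosomes)
    gid = 0
    for name, length in genome.chromosomes:
        n_here = max(1, round(config.n_genes * length / total))
        taken: list[tuple[int, int]] = []
        tries = 0
        while len(taken) < n_here and tries < 50 * n_here:
            tries += 1
            span = int(rng.integers(config.gene_min_bp, config.gene_max_bp + 1))
            if span + 4000 >= length:
                continue
            start = int(rng.integers(2000, length - span - 2000))
            end = start + span
            if any(start < e + 4000 and end > s - 4000 for s, e in taken):
                continue
            taken.append((start, end))
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), 2 * n_ex, replace=False))
            ex_s = cuts[0::2]
            ex_e = cuts[1::2]
            ex_s[0] = start
            ex_e[-1] = end
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                (
                    f"gene{gid}",
                    name,
                    strand,
                    start,
                    end,
                    ",".join(map(str, ex_s)),
                    ",".join(map(str, ex_e)),
                )
            )
            gid += 1
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "exon_starts", "exon_ends"],
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_genes_gtf(genes: pd.DataFrame, path) -> None:
    """Write simulator gene models as GTF (1-based, inclusive)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in zip(g.exon_starts.split(","), g.exon_ends.split(",")):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{int(s) + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_genes_bed12(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            ex_s = [int(x) for x in g.exon_starts.split(",")]
            ex_e = [int(x) for x in g.exon_ends.split(",")]
            sizes = ",".join(str(e - s) for s, e in zip(ex_s, ex_e)) + ","
            offsets = ",".join(str(s - g.start) for s in ex_s) + ","
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            g.start,
                            g.end,
                            g.gene_id,
                            0,
                            g.strand,
                            g.start,
                            g.end,
                            0,
                            len(ex_s),
                            sizes,
                            offsets,
                        ],
                    )
                )
                + "\n"
            )
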