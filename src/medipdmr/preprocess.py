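"""From raw/aligned reads to the filtered, normalized CpG depth matrix.

Stages, in pipeline order:

1. :func:`qc_filter` — drop reads with more than 5 ``N`` bases or with
   bases below Phred 5 for more than 50% of the sequence.
2. :func:`collapse_duplicates` — a read mapping to multiple genomic
   locations counts as one read (coordinate-first alignment kept).
3. :func:`cpg_depth` — fragment-overlap count at each CpG dinucleotide.
4. :func:`filter_low_coverage` — discard CpGs below a 10 read depth.
5. :func:`normalize` — rescale each sample to its group's mean library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .matrix import DepthMatrix

MAX_N_BASES = 5          # reads with more than this many Ns are discarded
LOW_QUALITY_PHRED = 5    # bases below this Phred score count as low quality
LOW_QUALITY_FRACTION = 0.5


@dataclass
class ReadRecord:
    """A raw sequencing read (sequence + offset-33 Phred qualities)."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class AlignedRead:
    """One alignment record; ``n_hits`` counts the read's genomic locations."""

    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int
    read_id: str
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: start must be < end")
        if self.n_hits < 1:
            raise ValueError(f"{self.read_id}: n_hits must be >= 1")


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_n: int = 0
    n_dropped_quality: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_fastq(path):
    """Yield :class:`ReadRecord` from a FASTQ file (Phred offset 33)."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=np.array(rec.letter_annotations["phred_quality"]),
            )
        except (KeyError, ValueError) as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed FASTQ record #{i}: {exc}") from exc


def read_bed_alignments(path, sample: str = ""):
    """Read BED6 alignments; the name field is ``read_id|n_hits``."""
    out = []
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "name", "score", "strand"]
    )
    for t in df.itertuples(index=False):
        name = str(t.name)
        rid, _, nh = name.rpartition("|")
        if rid == "" or not nh.isdigit():
            rid, nh = name, "1"
        out.append(
            AlignedRead(
                chrom=t.chrom,
                start=int(t.start),
                end=int(t.end),
                strand=str(t.strand),
                n_hits=int(nh),
                read_id=rid,
                sample=sample,
            )
        )
    return out


def read_sam_alignments(path, sample: str = ""):
    """Read mapped, non-secondary SAM records; NH tag supplies n_hits."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    n_hits=rec.get_tag("NH") if rec.has_tag("NH") else 1,
                    read_id=rec.query_name,
                    sample=sample,
                )
            )
    return out


def read_cpg_bed(path) -> pd.DataFrame:
    """BED3 of CpG dinucleotides -> (chrom, pos) frame."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"].astype(int)})


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def qc_filter(reads) -> tuple[list, QCReport]:
    """Apply the read-level QC rules; returns (passing reads, report).

    A read is discarded iff it contains more than ``MAX_N_BASES`` Ns or
    more than ``LOW_QUALITY_FRACTION`` of its bases fall below Phred
    ``LOW_QUALITY_PHRED``.  Both inequalities are strict, so a 50 bp read
    with exactly 5 Ns, or exactly half its bases at Phred 4, is kept.
    """
    report = QCReport()
    passing = []
    for read in reads:
        report.n_input += 1
        n_count = read.sequence.upper().count("N")
        low_frac = (
            (read.qualities < LOW_QUALITY_PHRED).mean() if len(read.qualities) else 0.0
        )
        bad_n = n_count > MAX_N_BASES
        bad_q = low_frac > LOW_QUALITY_FRACTION
        if bad_n:
            report.n_dropped_n += 1
        if bad_q:
            report.n_dropped_quality += 1
        if not (bad_n or bad_q):
            report.n_kept += 1
            passing.append(read)
    return passing, report


def collapse_duplicates(reads) -> list:
    """One alignment per read: multi-location reads collapse to the
    coordinate-first record (lexicographic chrom, then start, then end).

    Returns records sorted by coordinate; ``n_hits`` is preserved for
    reporting.
    """
    best: dict[tuple, AlignedRead] = {}
    for r in reads:
        key = (r.sample, r.read_id)
        cur = best.get(key)
        if cur is None or (r.chrom, r.start, r.end) < (cur.chrom, cur.start, cur.end):
            best[key] = r
    out = list(best.values())
    out.sort(key=lambda r: (r.sample, r.chrom, r.start, r.end, r.read_id))
    return out


def cpg_depth(
    aligned_by_sample: dict,
    cpg_sites: pd.DataFrame,
    groups: dict | None = None,
) -> DepthMatrix:
    """Raw depth matrix: fragments of each sample overlapping ``[pos, pos+2)``.

    Parameters
    ----------
    aligned_by_sample
        Mapping sample name -> iterable of :class:`AlignedRead`
        (post-collapse).
    cpg_sites
        (chrom, pos) frame of CpG sites.
    groups
        Mapping sample -> group label; defaults to one group.
    """
    sites = cpg_sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    samples = list(aligned_by_sample)
    depth = np.zeros((len(sites), len(samples)))
    lib_sizes = np.zeros(len(samples))
    chrom_index: dict[str, tuple[np.ndarray, int]] = {}
    for name, grp in sites.groupby("chrom", sort=False):
        chrom_index[name] = (grp["pos"].to_numpy(), int(grp.index[0]))
    warned: set[str] = set()
    for j, sample in enumerate(samples):
        diff = np.zeros(len(sites) + 1)
        n_frag = 0
        for r in aligned_by_sample[sample]:
            n_frag += 1
            if r.chrom not in chrom_index:
                if r.chrom not in warned:
                    warned.add(r.chrom)
                    warnings.warn(f"alignments on unknown chromosome {r.chrom}")
                continue
            pos, base = chrom_index[r.chrom]
            lo = np.searchsorted(pos, r.start - 1, side="left")
            hi = np.searchsorted(pos, r.end, side="left")
            if lo < hi:
                diff[base + lo] += 1
                diff[base + hi] -= 1
        depth[:, j] = np.cumsum(diff[:-1])
        lib_sizes[j] = n_frag
    groups = groups or {s: "group1" for s in samples}
    return DepthMatrix(
        sites=sites,
        depth=depth,
        samples=samples,
        groups=[groups[s] for s in samples],
        library_sizes=lib_sizes,
        normalized=False,
    )


def filter_low_coverage(
    matrix: DepthMatrix, min_depth: float = 10.0, mode: str = "group-mean"
) -> DepthMatrix:
    """Drop CpGs below the depth threshold (default 10).

    ``mode="group-mean"`` (default) retains a site iff the mean raw depth is
    at least ``min_depth`` in *both* groups; ``mode="per-sample"`` requires
    every sample individually to reach it.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if matrix.normalized:
        raise ValueError("coverage filter applies to the raw matrix")
    if mode == "group-mean":
        gm = matrix.group_mean_depth().to_numpy()
        keep = (gm >= min_depth).all(axis=1)
    elif mode == "per-sample":
        keep = (matrix.depth >= min_depth).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return matrix.subset_sites(keep)


def normalize(matrix: DepthMatrix, library_sizes=None) -> DepthMatrix:
    """Scale each sample to the overall average library size of its group.

    Factor for sample *s* = (mean library size of *s*'s group) / (library
    size of *s*); the group's mean library size is invariant under the
    transform and within-sample depth ratios are preserved exactly.
    """
    if library_sizes is None:
        library_sizes = (
            matrix.library_sizes
            if matrix.library_sizes is not None
            else matrix.depth.sum(axis=0)
        )
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (library_sizes <= 0).any():
        raise ValueError("zero library size")
    factors = np.empty(matrix.n_samples)
    for g in matrix.group_names:
        idx = matrix.group_indices(g)
        factors[idx] = library_sizes[idx].mean() / library_sizes[idx]
    return matrix.with_depth(
        matrix.depth * factors,
        normalized=True,
        scale_factors=factors,
        library_sizes=library_sizes,
    )
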