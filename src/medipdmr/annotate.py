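"""Assign DMRs to the five canonical gene features and tabulate counts.

Features, in precedence order when a DMR overlaps several: promoter (2 kb
upstream of the TSS, strand-aware), exon, intron, downstream 2 kb (past the
TES), intergenic (the complement).  Gene-linked features carry their gene
id; a DMR overlapping the same feature of two genes is counted for both
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURES = ["promoter", "exon", "intron", "downstream2kb", "intergenic"]
DIRECTIONS = ["hyper", "hypo"]


@dataclass
class GeneModel:
    """A gene: strand-aware TSS/TES plus exon intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class FeatureSet:
    """Labeled genomic intervals; ``gene_id`` is empty for intergenic."""

    intervals: pd.DataFrame  # chrom, start, end, feature, gene_id
    chrom_sizes: dict

    def of(self, feature: str) -> pd.DataFrame:
        return self.intervals[self.intervals["feature"] == feature]

    def resolved(self) -> pd.DataFrame:
        """Non-overlapping tiling after precedence resolution.

        Every base of every chromosome receives exactly one label
        (promoter > exon > intron > downstream2kb > intergenic).
        """
        out = []
        prec = {f: i for i, f in enumerate(FEATURES)}
        for chrom, size in self.chrom_sizes.items():
            sub = self.intervals[self.intervals["chrom"] == chrom]
            bounds = {0, size}
            bounds.update(sub["start"].tolist())
            bounds.update(sub["end"].tolist())
            edges = sorted(b for b in bounds if 0 <= b <= size)
            starts = np.array(sub["start"])
            ends = np.array(sub["end"])
            feats = sub["feature"].to_numpy()
            for a, b in zip(edges[:-1], edges[1:]):
                over = (starts < b) & (ends > a)
                if over.any():
                    label = min((prec[f] for f in feats[over]))
                    out.append((chrom, a, b, FEATURES[label]))
                else:
                    out.append((chrom, a, b, "intergenic"))
        df = pd.DataFrame(out, columns=["chrom", "start", "end", "feature"])
        # merge adjacent same-label segments
        merged = []
        for _, row in df.iterrows():
            if (
                merged
                and merged[-1][0] == row["chrom"]
                and merged[-1][2] == row["start"]
                and merged[-1][3] == row["feature"]
            ):
                merged[-1][2] = row["end"]
            else:
                merged.append([row["chrom"], row["start"], row["end"], row["feature"]])
        return pd.DataFrame(merged, columns=["chrom", "start", "end", "feature"])


@dataclass
class AnnotationTable:
    """Hyper/hypo counts per feature (genes for genic features, DMRs for
    intergenic) with derived totals and percentages."""

    counts: pd.DataFrame  # index hyper/hypo, columns FEATURES

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(index=DIRECTIONS, columns=FEATURES).fillna(0).astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_counts(cls, hyper: dict, hypo: dict) -> "AnnotationTable":
        return cls(pd.DataFrame([hyper, hypo], index=DIRECTIONS))

    def feature_total(self, feature: str) -> int:
        """Hyper + hypo count of one feature (e.g. all promoter DMR genes)."""
        return int(self.counts[feature].sum())

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def feature_share_pct(self, feature: str, ndigits: int = 0) -> float:
        """Feature's percentage of the grand total."""
        return round(100.0 * self.feature_total(feature) / self.grand_total, ndigits)

    def percentages(self) -> pd.Series:
        return 100.0 * self.counts.sum(axis=0) / self.grand_total

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="direction")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t", index_col="direction"))


# ----------------------------------------------------------------------
# gene-model I/O
# ----------------------------------------------------------------------
def read_genes_gtf(path) -> list:
    """Parse gene models (gene + exon records) from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=g.attributes["gene_id"][0],
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons or [(g.start - 1, g.end)],
            )
        )
    return genes


def read_genes_bed12(path) -> list:
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "n_blocks", "sizes", "offsets",
    ]
    df = pd.read_csv(path, sep="\t", names=names)
    genes = []
    for t in df.itertuples(index=False):
        sizes = [int(x) for x in str(t.sizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(t.offsets).rstrip(",").split(",")]
        exons = [(t.start + o, t.start + o + s) for o, s in zip(offs, sizes)]
        genes.append(
            GeneModel(
                gene_id=str(t.name),
                chrom=t.chrom,
                strand=t.strand,
                start=int(t.start),
                end=int(t.end),
                exons=exons,
            )
        )
    return genes


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def build_features(
    genes: list,
    chrom_sizes: dict,
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> FeatureSet:
    """Promoter/exon/intron/downstream intervals per gene plus intergenic.

    Flanks are strand-aware and clipped at chromosome bounds; introns are
    the gene span minus its exons; intergenic is the per-chromosome
    complement of the union of all gene-linked features.
    """
    rows = []
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
        size = chrom_sizes[g.chrom]
        if not (0 <= g.tss <= size):
            raise ValueError(f"{g.gene_id}: TSS outside chromosome")
        if g.strand == "+":
            prom = (max(0, g.tss - promoter_bp), g.tss)
            down = (g.tes, min(size, g.tes + downstream_bp))
        else:
            prom = (g.tss, min(size, g.tss + promoter_bp))
            down = (max(0, g.tes - downstream_bp), g.tes)
        if prom[0] < prom[1]:
            rows.append((g.chrom, prom[0], prom[1], "promoter", g.gene_id))
        if down[0] < down[1]:
            rows.append((g.chrom, down[0], down[1], "downstream2kb", g.gene_id))
        exons = sorted(g.exons)
        for s, e in exons:
            rows.append((g.chrom, s, e, "exon", g.gene_id))
        cursor = g.start
        for s, e in exons:
            if s > cursor:
                rows.append((g.chrom, cursor, s, "intron", g.gene_id))
            cursor = max(cursor, e)
        if cursor < g.end:
            rows.append((g.chrom, cursor, g.end, "intron", g.gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "gene_id"])
    # intergenic = complement of the union of gene-linked features
    inter = []
    for chrom, size in chrom_sizes.items():
        sub = df[df["chrom"] == chrom].sort_values("start")
        cursor = 0
        for _, r in sub.iterrows():
            if r["start"] > cursor:
                inter.append((chrom, cursor, r["start"], "intergenic", ""))
            cursor = max(cursor, r["end"])
        if cursor < size:
            inter.append((chrom, cursor, size, "intergenic", ""))
    df = pd.concat(
        [df, pd.DataFrame(inter, columns=df.columns)], ignore_index=True
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return FeatureSet(intervals=df, chrom_sizes=dict(chrom_sizes))


def assign_dmrs(dmrs: pd.DataFrame, features: FeatureSet) -> pd.DataFrame:
    """Label each DMR with the highest-precedence feature it overlaps.

    A one-base-pair overlap suffices; gene ids of *all* genes whose
    feature of the winning label overlaps are attached (semicolon-joined).
    Returns the input columns plus ``feature`` and ``gene_ids``.
    """
    labels = []
    gene_ids = []
    iv = features.intervals
    by_chrom = {c: g for c, g in iv.groupby("chrom", sort=False)}
    for t in dmrs.itertuples(index=False):
        sub = by_chrom.get(t.chrom)
        label, genes = "intergenic", ""
        if sub is not None:
            over = sub[(sub["start"] < t.end) & (sub["end"] > t.start)]
            for feat in FEATURES:
                hit = over[over["feature"] == feat]
                if len(hit):
                    label = feat
                    genes = ";".join(sorted(set(g for g in hit["gene_id"] if g)))
                    break
        labels.append(label)
        gene_ids.append(genes)
    out = dmrs.copy()
    out["feature"] = labels
    out["gene_ids"] = gene_ids
    return out


def count_table(assignments: pd.DataFrame) -> AnnotationTable:
    """Hyper/hypo count table over the five features.

    Genic features count each (gene, direction) pair once; the intergenic
    column counts DMRs.  ``assignments`` needs columns ``feature``,
    ``gene_ids`` and ``direction``.
    """
    counts = {d: {f: 0 for f in FEATURES} for d in DIRECTIONS}
    seen = set()
    for t in assignments.itertuples(index=False):
        if t.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {t.direction!r}")
        if t.feature == "intergenic":
            counts[t.direction]["intergenic"] += 1
            continue
        for gid in str(t.gene_ids).split(";"):
            if not gid:
                continue
            key = (t.feature, t.direction, gid)
            if key not in seen:
                seen.add(key)
                counts[t.direction][t.feature] += 1
    return AnnotationTable.from_counts(counts["hyper"], counts["hypo"])


def fraction_hypermethylated(directions) -> float:
    """Percent of promoter calls that are hypermethylated, to two decimals."""
    dirs = list(directions)
    if not dirs:
        raise ValueError("empty direction list")
    bad = set(dirs) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown directions {bad}")
    return round(100.0 * sum(d == "hyper" for d in dirs) / len(dirs), 2)
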