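"""The CpG depth matrix — the central container of the pipeline.

Rows are retained CpG sites (0-based position of the C on the forward
strand), columns are samples carrying a two-group label.  Depths are raw
fragment-overlap counts until :func:`medipdmr.preprocess.normalize` rescales
each sample to its group's mean library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class DepthMatrix:
    """Per-CpG read depth for a set of samples.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` and ``pos``, sorted by
        (chrom, pos).  ``pos`` is the 0-based coordinate of the C of the
        CpG dinucleotide; the site occupies ``[pos, pos + 2)``.
    depth
        Array of shape ``(n_sites, n_samples)``; integer counts before
        normalization, non-negative reals after.
    samples
        Sample identifiers, one per depth column.
    groups
        Group label per sample (two distinct labels for a two-group design).
    library_sizes
        Post-collapse aligned-fragment count per sample; used by
        normalization.  Optional — column sums are the fallback.
    """

    sites: pd.DataFrame
    depth: np.ndarray
    samples: list[str]
    groups: list[str]
    library_sizes: np.ndarray | None = None
    normalized: bool = False
    scale_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.samples = list(self.samples)
        self.groups = list(self.groups)
        if self.depth.ndim != 2:
            raise ValueError("depth must be 2-D (sites x samples)")
        if len(self.sites) != self.depth.shape[0]:
            raise ValueError("sites and depth row count differ")
        if len(self.samples) != self.depth.shape[1]:
            raise ValueError("samples and depth column count differ")
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample required")
        if (self.depth < 0).any():
            raise ValueError("negative depths")
        if not {"chrom", "pos"}.issubset(self.sites.columns):
            raise ValueError("sites needs 'chrom' and 'pos' columns")
        if self.library_sizes is not None:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if self.library_sizes.shape != (len(self.samples),):
                raise ValueError("library_sizes length mismatch")
        self.sites = self.sites.reset_index(drop=True)
        # enforce (chrom, pos) sort; chromosome blocks in first-seen order
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        order = {c: i for i, c in enumerate(pd.unique(chrom))}
        codes = np.array([order[c] for c in chrom])
        if len(pos) and not np.all(
            (np.diff(codes) > 0) | ((np.diff(codes) == 0) & (np.diff(pos) > 0))
        ):
            idx = np.lexsort((pos, codes))
            self.sites = self.sites.iloc[idx].reset_index(drop=True)
            self.depth = self.depth[idx]

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.depth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.depth.shape[1]

    @property
    def group_names(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def group_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.groups) == np.asarray(name))

    def group_mean_depth(self) -> pd.DataFrame:
        """Per-site mean depth of each group (columns in group order)."""
        out = {}
        for g in self.group_names:
            out[g] = self.depth[:, self.group_indices(g)].mean(axis=1)
        return pd.DataFrame(out)

    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per site (first-seen order)."""
        chrom = self.sites["chrom"].to_numpy()
        order = {c: i for i, c in enumerate(pd.unique(chrom))}
        return np.array([order[c] for c in chrom], dtype=int)

    def subset_sites(self, mask: np.ndarray) -> "DepthMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            sites=self.sites.loc[mask].reset_index(drop=True),
            depth=self.depth[mask],
        )

    def with_depth(self, depth: np.ndarray, **kw) -> "DepthMatrix":
        return replace(self, depth=depth, **kw)

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with ``#`` header lines carrying sample metadata."""
        with open(path, "w") as fh:
            fh.write("#groups\t" + "\t".join(self.groups) + "\n")
            if self.library_sizes is not None:
                fh.write(
                    "#library_sizes\t"
                    + "\t".join(repr(float(x)) for x in self.library_sizes)
                    + "\n"
                )
            fh.write(f"#normalized\t{str(self.normalized).lower()}\n")
            df = self.sites.copy()
            for j, s in enumerate(self.samples):
                df[s] = self.depth[:, j]
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DepthMatrix":
        meta: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *vals = line[1:].rstrip("\n").split("\t")
                meta[key] = vals
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        groups = meta.get("groups", ["group1"] * len(samples))
        lib = meta.get("library_sizes")
        return cls(
            sites=df[["chrom", "pos"]],
            depth=df[samples].to_numpy(dtype=float),
            samples=samples,
            groups=list(groups),
            library_sizes=np.array([float(x) for x in lib]) if lib else None,
            normalized=meta.get("normalized", ["false"])[0] == "true",
        )

    def to_bedgraph(self, path, sample: str) -> None:
        j = self.samples.index(sample)
        df = self.sites.copy()
        df["end"] = df["pos"] + 2
        df["value"] = self.depth[:, j]
        df[["chrom", "pos", "end", "value"]].to_csv(
            path, sep="\t", index=False, header=False
        )
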