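"""Genome model: chromosome sizes, windowed GC / CpG_o/e tracks, CpG sites.

CpG_o/e is the observed/expected CpG dinucleotide ratio of a window, the
usual CpG-island-ness measure: observed count divided by
``length * (GC/2)^2``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml


@dataclass
class GenomeModel:
    """Chromosome lengths plus per-window GC and CpG_o/e and CpG positions.

    ``windows`` has columns ``chrom, start, end, gc, cpg_oe, n_cpg``;
    windows tile each chromosome with a fixed ``window_bp`` (last window may
    be short).  ``cpg_sites`` maps chromosome name to the sorted 0-based
    positions of the C of each CpG dinucleotide (forward strand).
    """

    chromosomes: list[tuple[str, int]]
    window_bp: int
    windows: pd.DataFrame
    cpg_sites: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        gc = self.windows["gc"].to_numpy()
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("GC fractions must lie in [0, 1]")
        if (self.windows["cpg_oe"].to_numpy() < 0).any():
            raise ValueError("CpG_o/e must be >= 0")
        for name, pos in self.cpg_sites.items():
            pos = np.asarray(pos, dtype=int)
            self.cpg_sites[name] = pos
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"CpG positions not strictly increasing on {name}")
            if len(pos) and (pos[-1] + 2 > lengths[name] or pos[0] < 0):
                raise ValueError(f"CpG position outside {name}")

    # ------------------------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        return dict(self.chromosomes)[name]

    @property
    def n_cpg(self) -> int:
        return int(sum(len(p) for p in self.cpg_sites.values()))

    def sites_frame(self) -> pd.DataFrame:
        """All CpG sites as a (chrom, pos) DataFrame in genome order."""
        frames = [
            pd.DataFrame({"chrom": name, "pos": self.cpg_sites.get(name, np.array([], int))})
            for name, _ in self.chromosomes
        ]
        return pd.concat(frames, ignore_index=True)

    def window_of(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Index into ``windows`` of the window containing each position."""
        w = self.windows
        base = np.flatnonzero((w["chrom"] == chrom).to_numpy())
        if len(base) == 0:
            raise KeyError(chrom)
        return base[np.asarray(pos) // self.window_bp]

    # ------------------------------------------------------------------
    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")
        self.windows.to_csv(os.path.join(outdir, "windows.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "cpg_sites.bed"), "w") as fh:
            for name, _ in self.chromosomes:
                for p in self.cpg_sites.get(name, []):
                    fh.write(f"{name}\t{p}\t{p + 2}\n")
        with open(os.path.join(outdir, "genome.yaml"), "w") as fh:
            yaml.safe_dump({"window_bp": self.window_bp}, fh)

    @classmethod
    def load(cls, outdir) -> "GenomeModel":
        chroms = []
        with open(os.path.join(outdir, "chrom.sizes")) as fh:
            for line in fh:
                name, length = line.split()
                chroms.append((name, int(length)))
        windows = pd.read_csv(os.path.join(outdir, "windows.tsv"), sep="\t")
        bed = pd.read_csv(
            os.path.join(outdir, "cpg_sites.bed"),
            sep="\t",
            names=["chrom", "start", "end"],
        )
        sites = {
            name: grp["start"].to_numpy(dtype=int)
            for name, grp in bed.groupby("chrom", sort=False)
        }
        with open(os.path.join(outdir, "genome.yaml")) as fh:
            meta = yaml.safe_load(fh)
        return cls(chroms, int(meta["window_bp"]), windows, sites)
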