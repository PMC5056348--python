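"""Orthogonal validation computations.

Bisulfite sequencing PCR (BSP) clone summaries with text lollipop output,
2^-ddCt relative expression from qPCR Ct tables, fatty-acid composition
class sums (SFA/MUFA/PUFA) with the PUFA:SFA ratio, and histology-derived
mean adipocyte volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MRNA_REFERENCES = ("ACTB", "TBP", "TOP2B")
DEFAULT_MIRNA_REFERENCE = ("U6",)

# percent-of-total classification of the commonly reported species
FATTY_ACID_CLASSES = {
    "C12:0": "SFA",
    "C14:0": "SFA",
    "C16:0": "SFA",
    "C17:0": "SFA",
    "C18:0": "SFA",
    "C20:0": "SFA",
    "C14:1": "MUFA",
    "C16:1": "MUFA",
    "C18:1n-9": "MUFA",
    "C20:1": "MUFA",
    "C18:2n-6": "PUFA",
    "C18:3n-3": "PUFA",
    "C20:2": "PUFA",
    "C20:3n-3": "PUFA",
    "C20:4n-6": "PUFA",
    "C22:6n-3": "PUFA",
}


@dataclass
class CloneMatrix:
    """Binary clones x CpG-sites matrix from BSP subcloning.

    1 = methylated (protected C), 0 = unmethylated (converted to T).
    """

    values: np.ndarray
    region: str = "region"
    group: str = ""
    site_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("clone matrix must be 2-D with at least one clone")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("clone matrix entries must be 0 or 1")
        if self.site_positions is not None:
            sp = np.asarray(self.site_positions)
            if len(sp) != self.values.shape[1]:
                raise ValueError("site_positions length mismatch")
            if len(sp) > 1 and (np.diff(sp) <= 0).any():
                raise ValueError("site_positions must be increasing")
            self.site_positions = sp

    @property
    def n_clones(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.values, columns=[f"site{i + 1}" for i in range(self.n_sites)]
        )
        df.insert(0, "clone", [f"clone{i + 1}" for i in range(self.n_clones)])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, region: str = "region", group: str = "") -> "CloneMatrix":
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c != "clone"]
        return cls(values=df[cols].to_numpy(), region=region, group=group)


def bsp_summary(clone_matrix: CloneMatrix) -> dict:
    """Per-site and region methylation percentages plus a text lollipop.

    Site percent = 100 x methylated clones / clones; region mean is the
    average over sites.  The lollipop uses the conventional filled circle
    for a methylated CpG and an open circle otherwise, one row per clone.
    """
    if clone_matrix.n_sites == 0:
        raise ValueError("clone matrix has no CpG sites")
    v = clone_matrix.values
    site_pct = 100.0 * v.mean(axis=0)
    lollipop = "\n".join("".join("●" if x else "○" for x in row) for row in v)
    return {
        "site_pct": site_pct,
        "region_mean_pct": float(site_pct.mean()),
        "lollipop": lollipop,
    }


# ----------------------------------------------------------------------
def ddct(
    ct_table: pd.DataFrame,
    reference_genes=DEFAULT_MRNA_REFERENCES,
    calibrator_group: str | None = None,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt = mean target Ct - mean reference Ct per sample (references
    aggregated as the arithmetic mean of their Ct, i.e. the geometric mean
    of their quantities); ddCt subtracts the calibrator group's mean dCt
    per gene; expression = 2^-ddCt, so the calibrator group's geometric
    mean expression is 1.

    ``ct_table`` columns: sample, group, gene, ct (replicate rows).
    ``calibrator_group`` defaults to the last group in table order.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    groups = list(dict.fromkeys(ct_table["group"]))
    calibrator_group = calibrator_group or groups[-1]
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    mean_ct = (
        ct_table.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    refs = set(reference_genes)
    ref_ct = (
        mean_ct[mean_ct["gene"].isin(refs)]
        .groupby("sample", sort=False)["ct"]
        .agg(["mean", "count"])
    )
    targets = mean_ct[~mean_ct["gene"].isin(refs)]
    rows = []
    for t in targets.itertuples(index=False):
        if t.sample not in ref_ct.index or ref_ct.loc[t.sample, "count"] < len(refs):
            raise ValueError(f"sample {t.sample} lacks a reference gene")
        rows.append((t.sample, t.group, t.gene, t.ct - ref_ct.loc[t.sample, "mean"]))
    dct = pd.DataFrame(rows, columns=["sample", "group", "gene", "delta_ct"])
    calib = (
        dct[dct["group"] == calibrator_group].groupby("gene")["delta_ct"].mean()
    )
    missing = set(dct["gene"]) - set(calib.index)
    if missing:
        raise ValueError(f"calibrator group lacks genes {sorted(missing)}")
    dct["ddct"] = dct["delta_ct"] - dct["gene"].map(calib)
    dct["expression"] = 2.0 ** (-dct["ddct"])
    return dct


# ----------------------------------------------------------------------
def fatty_acid_summary(
    fa_table: pd.DataFrame,
    classes: dict | None = None,
    paired: bool = False,
    sum_tolerance: float = 2.0,
) -> dict:
    """SFA/MUFA/PUFA class sums, the PUFA:SFA ratio and group contrasts.

    ``fa_table``: one row per sample with a ``sample`` column, a ``group``
    column and one percent-of-total column per fatty-acid species.  Per
    sample the species must sum to 100 within ``sum_tolerance``.  Returns
    per-sample class sums, per-group mean class sums, the per-group
    PUFA:SFA ratio rounded to two decimals, and a two-sided Student t
    contrast per class (unpaired by default; ``paired=True`` switches to
    the paired form).
    """
    classes = classes or FATTY_ACID_CLASSES
    species = [c for c in fa_table.columns if c not in ("sample", "group")]
    unknown = [s for s in species if s not in classes]
    if unknown:
        raise ValueError(f"unclassified species: {unknown}")
    sums = fa_table[species].sum(axis=1)
    if (np.abs(sums - 100.0) > sum_tolerance).any():
        raise ValueError("per-sample percentages do not sum to ~100")
    per_sample = pd.DataFrame({"sample": fa_table["sample"], "group": fa_table["group"]})
    for cls in ("SFA", "MUFA", "PUFA"):
        cols = [s for s in species if classes[s] == cls]
        per_sample[cls] = fa_table[cols].sum(axis=1) if cols else 0.0
    group_means = per_sample.groupby("group", sort=False)[["SFA", "MUFA", "PUFA"]].mean()
    ratios = {}
    for g, row in group_means.iterrows():
        if row["SFA"] == 0:
            warnings.warn(f"group {g}: SFA sum is zero, PUFA:SFA undefined")
            ratios[g] = np.nan
        else:
            ratios[g] = round(row["PUFA"] / row["SFA"], 2)
    tests = {}
    groups = list(group_means.index)
    sizes = per_sample["group"].value_counts()
    if len(groups) == 2 and (sizes >= 2).all():
        a = per_sample[per_sample["group"] == groups[0]]
        b = per_sample[per_sample["group"] == groups[1]]
        for cls in ("SFA", "MUFA", "PUFA"):
            if paired:
                res = stats.ttest_rel(a[cls], b[cls])
            else:
                res = stats.ttest_ind(a[cls], b[cls])
            tests[cls] = {"t": float(res.statistic), "p": float(res.pvalue)}
    return {
        "per_sample": per_sample,
        "group_means": group_means,
        "pufa_sfa_ratio": ratios,
        "tests": tests,
    }


# ----------------------------------------------------------------------
def adipocyte_volume(diameters_um, counts) -> float:
    """Count-weighted mean sphere volume in cubic micrometres.

    ``V = sum fi * (pi/6) * Di^3 / sum fi`` for histogram bins of mean
    diameter Di (um) and absolute cell count fi.
    """
    d = np.asarray(diameters_um, dtype=float)
    f = np.asarray(counts, dtype=float)
    if d.shape != f.shape:
        raise ValueError("diameters and counts length mismatch")
    if (d <= 0).any():
        raise ValueError("diameters must be positive")
    if (f < 0).any():
        raise ValueError("counts must be non-negative")
    if f.sum() <= 0:
        raise ValueError("total cell count must be positive")
    vol = (np.pi / 6.0) * d**3
    return float((f * vol).sum() / f.sum())
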