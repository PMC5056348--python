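import numpy as np
import pandas as pd
import pytest

from medipdmr import DepthMatrix, DMRParams, SimConfig, make_genome, make_truth, simulate_depths
from medipdmr.preprocess import filter_low_coverage, normalize


def make_matrix(depth, groups=None, chrom="chr1", spacing=50, start=1000, **kw):
    """DepthMatrix with evenly spaced sites on one chromosome."""
    depth = np.asarray(depth, dtype=float)
    n, k = depth.shape
    groups = groups or ["A"] * (k // 2) + ["B"] * (k - k // 2)
    sites = pd.DataFrame({"chrom": chrom, "pos": start + spacing * np.arange(n)})
    return DepthMatrix(
        sites=sites,
        depth=depth,
        samples=[f"s{i}" for i in range(k)],
        groups=groups,
        **kw,
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig(
        seed=11,
        chromosomes=(("chr1", 400_000), ("chr2", 250_000), ("chr3", 150_000)),
        n_dmrs=6,
        dmr_direction="hyper",
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_cfg):
    """Genome + truth + normalized matrix for a small planted simulation."""
    genome = make_genome(tiny_cfg)
    truth = make_truth(genome, tiny_cfg)
    raw = simulate_depths(genome, truth, tiny_cfg)
    matrix = normalize(filter_low_coverage(raw))
    return genome, truth, matrix


def region_overlaps(a, b) -> bool:
    return a["chrom"] == b["chrom"] and a["start"] < b["end"] and a["end"] > b["start"]


def recall_and_fdr(dmrs: pd.DataFrame, truth) -> tuple[float, float]:
    tr = truth.regions.to_dict("records")
    called = dmrs.to_dict("records")
    recall = (
        float(np.mean([any(region_overlaps(c, r) for c in called) for r in tr]))
        if tr
        else float("nan")
    )
    fdr = (
        float(np.mean([not any(region_overlaps(c, r) for r in tr) for c in called]))
        if called
        else 0.0
    )
    return recall, fdr
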