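"""Seed-and-extend DMR calling with permutation-based BH FDR.

Per retained CpG, read depths of the two groups are compared with a
parametric or non-parametric two-sample test, routed by Bartlett's
variance-equality test (parametric iff Bartlett P > 0.05).  CpGs with
P < 0.01 seed candidate regions; a seed absorbs each next downstream CpG
that is itself significant and lies within 200 bp of the region edge, and a
non-significant CpG (or a gap beyond the join window) terminates the
region.  Candidates with at least five significant CpGs are scored by the
sum of -log10 site P over members, ranked against a permutation null
(group-label relabelings, 1,000 draws), and reported at
Benjamini-Hochberg FDR < 0.01.

Note: Bartlett's test examines homoscedasticity only, not normality; it is
used here purely as the routing gate, as is conventional for this design.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .matrix import DepthMatrix

_P_FLOOR = 1e-300


@dataclass
class DMRParams:
    """Tunables of the caller (defaults follow the published procedure)."""

    seed_alpha: float = 0.01
    bartlett_alpha: float = 0.05
    join_window_bp: int = 200
    max_gap_bp: int = 2000
    min_sig_cpgs: int = 5
    n_permutations: int = 1000
    fdr: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.seed_alpha, self.bartlett_alpha, self.fdr):
            if not 0 < a < 1:
                raise ValueError("alphas must lie strictly in (0, 1)")
        if self.join_window_bp > self.max_gap_bp:
            raise ValueError("join_window_bp must not exceed max_gap_bp")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_sig_cpgs < 1:
            raise ValueError("min_sig_cpgs must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "DMRParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


# ----------------------------------------------------------------------
# elementary two-group tests (scalar API)
# ----------------------------------------------------------------------
def bartlett_test(depths_g1, depths_g2) -> float:
    """Two-group Bartlett statistic against chi-square(1).

    Convention: both variances zero -> P = 1 (perfect homoscedasticity);
    exactly one variance zero -> P = 0 (maximal heteroscedasticity).
    """
    x = np.asarray(depths_g1, float)
    y = np.asarray(depths_g2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    return float(
        _bartlett_vec(x[None, :], y[None, :])[0]
    )


def _bartlett_vec(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-group Bartlett P over rows of x (n, k1) and y (n, k2)."""
    n1, n2 = x.shape[1], y.shape[1]
    N = n1 + n2
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (N - 2)
    corr = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (N - 2)) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (
            (N - 2) * np.log(sp)
            - (n1 - 1) * np.log(v1)
            - (n2 - 1) * np.log(v2)
        ) / corr
        p = stats.chi2.sf(T, 1)
    both_zero = (v1 == 0) & (v2 == 0)
    one_zero = (v1 == 0) ^ (v2 == 0)
    p = np.where(both_zero, 1.0, np.where(one_zero, 0.0, p))
    return p


def _pooled_t_vec(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided pooled-variance t-test P over rows."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    degenerate = sp == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return p


def _mw_exact_vec(depth: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Exact two-sided Mann-Whitney P for every balanced relabeling.

    ``depth`` is (n_sites, k); ``masks`` is (k, m) with column j the 0/1
    group-1 indicator of relabeling j, enumerating *all* balanced
    relabelings.  Because the exact null is uniform over those relabelings,
    the rank-sum of column j evaluated against all m columns *is* the exact
    permutation distribution (midranks handle ties, conditional on the
    observed values).  Returns (n_sites, m).
    """
    ranks = stats.rankdata(depth, axis=1)
    rs = ranks @ masks  # (n, m)
    dev = np.abs(rs - rs.mean(axis=1, keepdims=True))
    # p[i, j] = fraction of relabelings with deviation >= dev[i, j]
    p = (dev[:, None, :] >= dev[:, :, None] - 1e-9).mean(axis=2)
    return p


def site_test(depths_g1, depths_g2, route: str) -> float:
    """Two-sided two-group test at one CpG.

    ``route="parametric"``: pooled-variance t-test.  ``route="nonparametric"``:
    Mann-Whitney U, exact by full relabeling enumeration for group sizes
    <= 8 (midranks under ties), normal approximation beyond.
    """
    x = np.asarray(depths_g1, float)
    y = np.asarray(depths_g2, float)
    if route == "parametric":
        return float(_pooled_t_vec(x[None, :], y[None, :])[0])
    if route != "nonparametric":
        raise ValueError(f"unknown route {route!r}")
    n1, n2 = len(x), len(y)
    if max(n1, n2) <= 8:
        masks = _balanced_masks(n1, n2)
        return float(_mw_exact_vec(np.r_[x, y][None, :], masks)[0, 0])
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _balanced_masks(n1: int, n2: int) -> np.ndarray:
    """0/1 masks (n1+n2, m) of all balanced group-1 relabelings.

    The identity assignment (first n1 columns as group 1) is column 0;
    the rest follow in lexicographic order.
    """
    combos = sorted(
        itertools.combinations(range(n1 + n2), n1),
        key=lambda c: (c != tuple(range(n1)), c),
    )
    masks = np.zeros((n1 + n2, len(combos)))
    for j, c in enumerate(combos):
        masks[list(c), j] = 1.0
    return masks


def _site_pvalues_all_relabelings(
    depth: np.ndarray, n1: int, n2: int, bartlett_alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Site P-values for every balanced relabeling.

    Returns ``(p, parametric)`` of shape (n_sites, m): the routed P and the
    route indicator, with column 0 the observed labeling.
    """
    masks = _balanced_masks(n1, n2)
    m = masks.shape[1]
    n = depth.shape[0]
    p_t = np.empty((n, m))
    p_b = np.empty((n, m))
    for j in range(m):
        g1 = depth[:, masks[:, j].astype(bool)]
        g2 = depth[:, ~masks[:, j].astype(bool)]
        p_b[:, j] = _bartlett_vec(g1, g2)
        p_t[:, j] = _pooled_t_vec(g1, g2)
    p_mw = _mw_exact_vec(depth, masks)
    parametric = p_b > bartlett_alpha
    p = np.where(parametric, p_t, p_mw)
    return p, parametric


def site_tests(matrix: DepthMatrix, params: DMRParams) -> pd.DataFrame:
    """Observed-label per-site tests: bartlett_p, route, p, group means."""
    g1n, g2n = matrix.group_names[:2]
    i1, i2 = matrix.group_indices(g1n), matrix.group_indices(g2n)
    x, y = matrix.depth[:, i1], matrix.depth[:, i2]
    bp = _bartlett_vec(x, y)
    parametric = bp > params.bartlett_alpha
    p = np.where(
        parametric,
        _pooled_t_vec(x, y),
        _mw_exact_vec(
            np.concatenate([x, y], axis=1), _balanced_masks(x.shape[1], y.shape[1])
        )[:, 0],
    )
    return pd.DataFrame(
        {
            "bartlett_p": bp,
            "route": np.where(parametric, "parametric", "nonparametric"),
            "p": p,
            f"mean_{g1n}": x.mean(axis=1),
            f"mean_{g2n}": y.mean(axis=1),
        }
    )


# ----------------------------------------------------------------------
# seeds and extension
# ----------------------------------------------------------------------
def find_seeds(pvals, params: DMRParams) -> np.ndarray:
    """Indices of seed CpGs (site P below the seeding threshold), in order."""
    return np.flatnonzero(np.asarray(pvals) < params.seed_alpha)


def candidate_regions(
    positions: np.ndarray,
    chrom_codes: np.ndarray,
    pvals: np.ndarray,
    params: DMRParams,
) -> pd.DataFrame:
    """All candidate regions from seed-and-extend over a site track.

    Under the stated rules — only significant CpGs within the join window
    are absorbed, any non-significant next CpG (whether within the
    ``max_gap_bp`` termination distance or beyond it) ends the region, and
    overlapping candidates from different seeds merge — candidates are
    exactly the maximal runs of consecutive significant CpGs whose
    inter-site spacing stays within ``join_window_bp``.  Runs with fewer
    than ``min_sig_cpgs`` members are dropped.

    Returns a frame with ``start_idx, end_idx`` (inclusive site indices),
    ``n_sig`` and the region statistic ``stat`` (sum of -log10 site P).
    """
    p = np.asarray(pvals, float)
    positions = np.asarray(positions)
    chrom_codes = np.asarray(chrom_codes)
    n = len(p)
    if n == 0:
        return pd.DataFrame(columns=["start_idx", "end_idx", "n_sig", "stat"])
    sig = p < params.seed_alpha
    joinable = np.empty(n, bool)
    joinable[0] = False
    joinable[1:] = (chrom_codes[1:] == chrom_codes[:-1]) & (
        positions[1:] - positions[:-1] <= params.join_window_bp
    )
    run_start = sig & (~np.concatenate([[False], sig[:-1]]) | ~joinable)
    run_end = sig & (~np.concatenate([sig[1:], [False]]) | ~np.concatenate([joinable[1:], [False]]))
    starts = np.flatnonzero(run_start)
    ends = np.flatnonzero(run_end)
    n_sig = ends - starts + 1
    keep = n_sig >= params.min_sig_cpgs
    starts, ends, n_sig = starts[keep], ends[keep], n_sig[keep]
    logp = -np.log10(np.maximum(p, _P_FLOOR))
    cs = np.concatenate([[0.0], np.cumsum(logp * sig)])
    stat = cs[ends + 1] - cs[starts]
    return pd.DataFrame(
        {"start_idx": starts, "end_idx": ends, "n_sig": n_sig, "stat": stat}
    )


def extend_region(
    seed: int, sites: pd.DataFrame, pvals, params: DMRParams
) -> dict | None:
    """Candidate region containing one seed CpG (None if below the
    five-significant-CpG minimum).  Convenience wrapper over
    :func:`candidate_regions`.
    """
    chrom = sites["chrom"].to_numpy()
    order = {c: i for i, c in enumerate(pd.unique(chrom))}
    codes = np.array([order[c] for c in chrom])
    cands = candidate_regions(sites["pos"].to_numpy(), codes, pvals, params)
    hit = cands[(cands["start_idx"] <= seed) & (cands["end_idx"] >= seed)]
    if len(hit) == 0:
        return None
    row = hit.iloc[0]
    return {
        "start_idx": int(row["start_idx"]),
        "end_idx": int(row["end_idx"]),
        "n_sig": int(row["n_sig"]),
        "stat": float(row["stat"]),
    }


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------
def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH q-values: q_(i) = min_{j>=i} p_(j) * n / j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ----------------------------------------------------------------------
# permutation FDR and orchestration
# ----------------------------------------------------------------------
def _null_max_stats(
    p_all: np.ndarray,
    positions: np.ndarray,
    chrom_codes: np.ndarray,
    params: DMRParams,
    rng: np.random.Generator,
    masks: np.ndarray,
) -> np.ndarray:
    """One null statistic per permutation: the max region statistic after
    relabeling (plus a circular site shift for topped-up permutations).

    ``p_all`` holds the site P-vector of every balanced relabeling
    (column 0 = observed).  The observed group partition — the identity
    relabeling and its mirror image, which reproduce the observed two-sided
    statistics exactly — is excluded from the null (the ``+1`` in the
    empirical P plays the identity's role).  The first permutations are the
    remaining distinct relabelings; with 3 vs 3 samples only 18 of those
    exist, so further draws resample one of them uniformly and circularly
    shift the site-to-depth assignment.
    """
    m = p_all.shape[1]
    n_sites = p_all.shape[0]
    obs = masks[:, 0]
    cols = [  # drop the observed partition: identity and its mirror image
        c
        for c in range(1, m)
        if not np.array_equal(masks[:, c], obs)
        and not np.array_equal(masks[:, c], 1.0 - obs)
    ]
    out = np.empty(params.n_permutations)
    for k in range(params.n_permutations):
        if k < len(cols):
            col, shift = cols[k], 0
        else:
            col = cols[int(rng.integers(0, len(cols)))]
            shift = int(rng.integers(1, max(n_sites, 2)))
        pv = p_all[:, col] if shift == 0 else np.roll(p_all[:, col], shift)
        cands = candidate_regions(positions, chrom_codes, pv, params)
        out[k] = cands["stat"].max() if len(cands) else 0.0
    return out


def permutation_fdr(
    candidates: pd.DataFrame,
    matrix: DepthMatrix,
    params: DMRParams,
    p_all: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach empirical region P and BH q to observed candidates.

    ``region_p = (1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    g1n, g2n = matrix.group_names[:2]
    n1 = len(matrix.group_indices(g1n))
    n2 = len(matrix.group_indices(g2n))
    if p_all is None:
        p_all, _ = _site_pvalues_all_relabelings(
            matrix.depth, n1, n2, params.bartlett_alpha
        )
    rng = np.random.default_rng(params.seed)
    null_max = _null_max_stats(
        p_all,
        matrix.sites["pos"].to_numpy(),
        matrix.chrom_codes(),
        params,
        rng,
        masks=_balanced_masks(n1, n2),
    )
    out = candidates.copy()
    stat = out["stat"].to_numpy()
    out["region_p"] = (
        1.0 + (null_max[None, :] >= stat[:, None] - 1e-12).sum(axis=1)
    ) / (params.n_permutations + 1.0)
    out["q"] = benjamini_hochberg(out["region_p"].to_numpy()) if len(out) else []
    return out


def call_dmrs(
    matrix: DepthMatrix, params: DMRParams | None = None, keep_all: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Run the full caller on a normalized, coverage-filtered matrix.

    Returns ``(dmrs, meta)``.  ``dmrs`` rows carry chrom, start, end
    (0-based half-open span of the member dinucleotides), n_cpg, n_sig,
    per-group mean normalized depth, direction (hyper/hypo in the first
    group), empirical region_p and BH q; only regions with ``q < fdr``
    are returned unless ``keep_all``.
    """
    params = params or DMRParams()
    if len(matrix.group_names) != 2:
        raise ValueError("exactly two groups required")
    g1n, g2n = matrix.group_names
    n1, n2 = len(matrix.group_indices(g1n)), len(matrix.group_indices(g2n))
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    p_all, parametric = _site_pvalues_all_relabelings(
        matrix.depth, n1, n2, params.bartlett_alpha
    )
    p_obs = p_all[:, 0]
    n_nonpar = int((~parametric[:, 0]).sum())
    min_exact_p = 2.0 / p_all.shape[1]
    if n_nonpar and min_exact_p > params.seed_alpha:
        warnings.warn(
            f"{n_nonpar} CpG(s) routed to the exact Mann-Whitney test, whose "
            f"minimum two-sided P ({min_exact_p:.3g}) cannot reach the seed "
            f"threshold {params.seed_alpha}; the nonparametric route cannot "
            "seed regions at these group sizes."
        )
    positions = matrix.sites["pos"].to_numpy()
    codes = matrix.chrom_codes()
    cands = candidate_regions(positions, codes, p_obs, params)
    cands = permutation_fdr(cands, matrix, params, p_all=p_all)

    chrom_arr = matrix.sites["chrom"].to_numpy()
    gm = matrix.group_mean_depth().to_numpy()
    rows = []
    for t in cands.itertuples(index=False):
        s, e = int(t.start_idx), int(t.end_idx)
        m1 = gm[s : e + 1, 0].mean()
        m2 = gm[s : e + 1, 1].mean()
        rows.append(
            {
                "chrom": chrom_arr[s],
                "start": int(positions[s]),
                "end": int(positions[e] + 2),
                "n_cpg": e - s + 1,
                "n_sig": int(t.n_sig),
                f"mean_{g1n}": m1,
                f"mean_{g2n}": m2,
                "direction": "hyper" if m1 > m2 else "hypo",
                "stat": float(t.stat),
                "region_p": float(t.region_p),
                "q": float(t.q),
            }
        )
    dmrs = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_cpg",
            "n_sig",
            f"mean_{g1n}",
            f"mean_{g2n}",
            "direction",
            "stat",
            "region_p",
            "q",
        ],
    )
    if not keep_all:
        dmrs = dmrs[dmrs["q"] < params.fdr].reset_index(drop=True)
    meta = {
        "n_sites": matrix.n_sites,
        "n_candidates": len(cands),
        "n_reported": len(dmrs),
        "n_nonparametric_sites": n_nonpar,
        "n_permutations": params.n_permutations,
        "permutation_scheme": (
            "distinct non-identity balanced relabelings first, topped up by "
            "resampled relabelings with circular site shifts"
        ),
        "groups": (g1n, g2n),
    }
    return dmrs, meta


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+ output: score = -10*log10(q) capped at 1000, strand '.'."""
    df = dmrs.copy()
    df["name"] = [f"DMR_{i + 1}" for i in range(len(df))]
    with np.errstate(divide="ignore"):
        df["score"] = np.minimum(
            np.round(-10.0 * np.log10(np.maximum(df["q"], 1e-100))), 1000
        ).astype(int)
    df["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand"] + [
        c for c in dmrs.columns if c not in ("chrom", "start", "end")
    ]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_dmrs_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    base = ["chrom", "start", "end", "name", "score", "strand"]
    extra = ["n_cpg", "n_sig", "mean_g1", "mean_g2", "direction", "stat", "region_p", "q"]
    df.columns = base + extra[: df.shape[1] - 6]
    return df
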