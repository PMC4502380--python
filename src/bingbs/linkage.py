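"""Linkage maps from binned F2 genotypes.

Two-point recombination fractions are maximum-likelihood estimates for
an F2 intercross: each parent transmits a two-locus gamete that is
parental with probability (1-r)/2 per phase and recombinant with
probability r/2, giving a 3x3 joint offspring genotype table as a
function of r.  Composite calls (C = MF/FF, D = MM/MF) enter the
likelihood as partial observations summed over their compatible states;
missing genotypes drop the pair.  LOD is the log10 likelihood ratio
against r = 1/2.

Linkage groups are connected components of the graph with an edge where
LOD >= lod_min and r <= rf_max.  Within a group, markers are ordered by
seriation (greedy nearest-neighbour chain plus 2-opt polish) minimizing
the sum of adjacent r, and genetic distances come from the Haldane or
Kosambi mapping function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar

from .core import A, B, C, D, H, MISSING, COMPATIBLE, LinkageMap

_OBS = (A, H, B, C, D)
# indicator: observable code x true state
_S = np.zeros((5, 3))
for _o in _OBS:
    for _t in COMPATIBLE[_o]:
        _S[_o, _t] = 1.0

# gamete haplotypes over two loci (freshwater dosage at locus 1, locus 2)
_HAP_D1 = np.array([0, 0, 1, 1])
_HAP_D2 = np.array([0, 1, 0, 1])
_T = np.zeros((4, 4, 3, 3))
for _a in range(4):
    for _b in range(4):
        _T[_a, _b, _HAP_D1[_a] + _HAP_D1[_b], _HAP_D2[_a] + _HAP_D2[_b]] = 1.0


def joint_genotype_probs(r) -> np.ndarray:
    """P(g1, g2 | r) for an F2 intercross; shape (..., 3, 3)."""
    r = np.asarray(r, dtype=float)
    hp = np.stack([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2], axis=-1)
    return np.einsum("...a,...b,abij->...ij", hp, hp, _T)


def observable_probs(r) -> np.ndarray:
    """P(obs1, obs2 | r) over the 5 observable codes; shape (..., 5, 5)."""
    P = joint_genotype_probs(r)
    return np.einsum("...ij,oi,pj->...op", P, _S, _S)


@dataclass
class TwoPointEstimate:
    rhat: float
    lod: float
    n_informative: int


def _pair_class_counts(gA: np.ndarray, gB: np.ndarray) -> np.ndarray:
    ok = (gA != MISSING) & (gB != MISSING)
    return np.bincount(5 * gA[ok] + gB[ok], minlength=25).astype(float)


def estimate_rf(gA: np.ndarray, gB: np.ndarray) -> TwoPointEstimate:
    """MLE of the recombination fraction for one marker pair."""
    gA = np.asarray(gA, dtype=np.int64)
    gB = np.asarray(gB, dtype=np.int64)
    if gA.shape != gB.shape:
        raise ValueError("genotype vectors must have equal length")
    N = _pair_class_counts(gA, gB)
    n_inf = int(N.sum())
    if n_inf < 2:
        return TwoPointEstimate(float("nan"), float("nan"), n_inf)

    def negll(r: float) -> float:
        with np.errstate(divide="ignore"):
            logp = np.log(observable_probs(r).reshape(25))
        logp = np.where(N > 0, logp, 0.0)
        return -float((N * logp).sum())

    res = minimize_scalar(negll, bounds=(1e-9, 0.5), method="bounded",
                          options={"xatol": 1e-8})
    rhat = float(np.clip(res.x, 0.0, 0.5))
    ll_half = -negll(0.5)
    ll_hat = -negll(rhat)
    if ll_half >= ll_hat:  # boundary: independence fits at least as well
        rhat, ll_hat = 0.5, ll_half
    lod = max(0.0, (ll_hat - ll_half) / np.log(10.0))
    return TwoPointEstimate(rhat, lod, n_inf)


def pairwise_rf(
    G: np.ndarray, grid_step: float = 0.005
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs RF estimation; returns (rhat, lod, n_informative) matrices.

    The likelihood is evaluated on an r grid via indicator-matrix
    products (one matmul per observable class pair) and the optimum is
    refined by parabolic interpolation of the log-likelihood around the
    best grid point.
    """
    G = np.asarray(G, dtype=np.int64)
    n_m, n_f2 = G.shape
    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    with np.errstate(divide="ignore"):
        logP = np.log(observable_probs(grid))  # (n_grid, 5, 5)
    logP = np.nan_to_num(logP, neginf=-745.0)

    Ind = np.stack([(G == o).astype(np.float32) for o in _OBS])  # (5, n_m, n_f2)
    LL = np.zeros((n_m, n_m, len(grid)), dtype=np.float32)
    Ninf = np.zeros((n_m, n_m), dtype=np.float32)
    for oa in range(5):
        for ob in range(5):
            Nc = Ind[oa] @ Ind[ob].T  # (n_m, n_m) counts of this class pair
            Ninf += Nc
            LL += Nc[..., None] * logP[None, None, :, oa, ob].astype(np.float32)

    best = np.argmax(LL, axis=-1)
    # parabolic refinement on interior grid points
    i0 = np.clip(best, 1, len(grid) - 2)
    y0 = np.take_along_axis(LL, (i0 - 1)[..., None], axis=-1)[..., 0]
    y1 = np.take_along_axis(LL, i0[..., None], axis=-1)[..., 0]
    y2 = np.take_along_axis(LL, (i0 + 1)[..., None], axis=-1)[..., 0]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    rhat = grid[i0] + delta * grid_step
    at_edge = (best == 0) | (best == len(grid) - 1)
    rhat = np.where(at_edge, grid[best], rhat)
    rhat = np.clip(rhat, 0.0, 0.5)

    ll_best = np.take_along_axis(LL, best[..., None], axis=-1)[..., 0]
    lod = np.maximum(0.0, (ll_best - LL[..., -1]) / np.log(10.0))
    np.fill_diagonal(rhat, 0.0)
    np.fill_diagonal(lod, 0.0)
    return rhat.astype(float), lod.astype(float), Ninf.astype(int)


def group_markers(
    rhat: np.ndarray, lod: np.ndarray, lod_min: float = 6.0, rf_max: float = 0.35
) -> list[np.ndarray]:
    """Single-linkage groups: connected components of the linkage graph."""
    edges = (lod >= lod_min) & (rhat <= rf_max)
    np.fill_diagonal(edges, False)
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(edges), directed=False
    )
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups.sort(key=lambda idx: int(idx[0]))
    return groups


def order_markers(
    group: np.ndarray, rhat: np.ndarray, physical_keys: list | None = None
) -> np.ndarray:
    """Seriation of one linkage group minimizing the sum of adjacent r.

    Greedy nearest-neighbour chain growth followed by deterministic
    2-opt segment reversals.  The overall orientation is arbitrary; it
    is normalized so the end with the smaller physical key (when given)
    or smaller marker index comes first.
    """
    group = np.asarray(group)
    k = len(group)
    if k <= 2:
        order = np.sort(group)
    else:
        d = rhat[np.ix_(group, group)].copy()
        d = np.where(np.isnan(d), 0.5, d)
        np.fill_diagonal(d, np.inf)
        start = np.unravel_index(np.argmin(d), d.shape)
        chain = [int(start[0]), int(start[1])]
        used = set(chain)
        while len(chain) < k:
            free = [i for i in range(k) if i not in used]
            cand = [(d[chain[0], i], 0, i) for i in free]
            cand += [(d[chain[-1], i], 1, i) for i in free]
            dist, end, i = min(cand)
            if end == 0:
                chain.insert(0, i)
            else:
                chain.append(i)
            used.add(i)
        # 2-opt polish
        improved = True
        passes = 0
        while improved and passes < 50:
            improved = False
            passes += 1
            for i in range(1, k - 1):
                for j in range(i + 1, k):
                    before = d[chain[i - 1], chain[i]]
                    before += d[chain[j], chain[j + 1]] if j + 1 < k else 0.0
                    after = d[chain[i - 1], chain[j]]
                    after += d[chain[i], chain[j + 1]] if j + 1 < k else 0.0
                    if after < before - 1e-12:
                        chain[i:j + 1] = chain[i:j + 1][::-1]
                        improved = True
        order = group[chain]

    if physical_keys is not None:
        first, last = physical_keys[order[0]], physical_keys[order[-1]]
        if last < first:
            order = order[::-1]
    elif order[-1] < order[0]:
        order = order[::-1]
    return order


def map_distances(r_adjacent, mapping_function: str = "haldane") -> np.ndarray:
    """Cumulative cM positions from adjacent recombination fractions."""
    r = np.asarray(r_adjacent, dtype=float)
    if (r >= 0.5).any():
        raise ValueError("r = 0.5 between adjacent markers: infinite distance; "
                         "group markers first")
    if mapping_function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    elif mapping_function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise ValueError(f"unknown mapping function {mapping_function!r}")
    return np.concatenate([[0.0], np.cumsum(d)])


def build_linkage_map(
    codes: np.ndarray,
    marker_names: list[str],
    lod_min: float = 6.0,
    rf_max: float = 0.35,
    mapping_function: str = "haldane",
    physical_keys: list | None = None,
    min_group_size: int = 2,
) -> tuple[LinkageMap, np.ndarray, np.ndarray]:
    """Full map pipeline: pairwise RF -> group -> order -> distances.

    Returns the LinkageMap plus the pairwise (rhat, lod) matrices.
    Singleton groups (fewer than ``min_group_size`` markers) are
    reported with group id ``"ungrouped"`` and cM 0.
    """
    rhat, lod, _ = pairwise_rf(codes)
    groups = group_markers(rhat, lod, lod_min=lod_min, rf_max=rf_max)
    rows = []
    gid = 0
    for group in groups:
        if len(group) < min_group_size:
            for m in group:
                rows.append({"group": "ungrouped", "marker": marker_names[m],
                             "order": 0, "cM": 0.0})
            continue
        gid += 1
        order = order_markers(group, rhat, physical_keys=physical_keys)
        r_adj = np.array([min(rhat[order[i], order[i + 1]], 0.4999)
                          for i in range(len(order) - 1)])
        cm = map_distances(r_adj, mapping_function)
        for k, m in enumerate(order):
            rows.append({"group": f"LG{gid}", "marker": marker_names[m],
                         "order": k, "cM": float(cm[k])})
    lm = LinkageMap(pd.DataFrame(rows), mapping_function)
    return lm, rhat, lod


def marey_profile(
    map_table: pd.DataFrame,
    physical: pd.DataFrame,
    min_zero_run: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genetic-vs-physical (Marey) profile and suppression candidates.

    ``map_table`` needs columns (group, marker, cM); ``physical`` maps
    marker -> (chromosome, bp) on the revised assembly.  Markers without
    a physical position are excluded.  Returns the per-interval profile
    (chromosome, bp midpoints, cM/Mb) and flagged maximal runs of at
    least ``min_zero_run`` consecutive zero-cM intervals.
    """
    merged = map_table.merge(physical, on="marker", how="left")
    missing = merged["bp"].isna()
    if missing.any():
        import logging

        logging.getLogger(__name__).warning(
            "marey_profile: excluding %d unplaced marker(s)", int(missing.sum())
        )
        merged = merged[~missing]
    prof_rows, supp_rows = [], []
    for chrom, sub in merged.groupby("chromosome", sort=False):
        sub = sub.sort_values("bp")
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        cm = np.abs(cm - cm[0])  # map orientation may oppose physical
        dbp = np.diff(bp)
        dcm = np.abs(np.diff(cm))
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(dbp > 0, dcm / (dbp / 1e6), np.nan)
        for i in range(len(dbp)):
            prof_rows.append({"chromosome": chrom, "start_bp": bp[i],
                              "end_bp": bp[i + 1], "cM_per_Mb": rate[i]})
        zero = dcm <= 1e-9
        i = 0
        while i < len(zero):
            if zero[i]:
                j = i
                while j + 1 < len(zero) and zero[j + 1]:
                    j += 1
                if j - i + 1 >= min_zero_run:
                    supp_rows.append({"chromosome": chrom, "start_bp": bp[i],
                                      "end_bp": bp[j + 1],
                                      "n_intervals": j - i + 1})
                i = j + 1
            else:
                i += 1
    profile = pd.DataFrame(prof_rows, columns=["chromosome", "start_bp",
                                               "end_bp", "cM_per_Mb"])
    suppression = pd.DataFrame(supp_rows, columns=["chromosome", "start_bp",
                                                   "end_bp", "n_intervals"])
    return profile, suppression
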