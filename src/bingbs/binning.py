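"""Bin SNPs per scaffold, pool reads, and call binned genotypes.

Scaffolds are split into evenly sized bins of at most 500 kb: one bin
below 100 kb, two bins from 100 kb up to 1 Mb, and floor(L / 500 kb) + 1
bins at 1 Mb and above (three bins for 1-1.5 Mb, four for 1.5-2 Mb, and
so on).  Pooling the member SNPs' reads turns many ~1.5x SNPs into one
high-coverage (~150x) marker per F2, which is then genotyped from a
binomial posterior over the three F2 states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .core import A, B, C, D, H, MISSING, AlleleCountMatrix, marker_name


@dataclass
class BinningConfig:
    max_bin_bp: int = 500_000
    small_scaffold_bp: int = 100_000
    two_bin_upper_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.small_scaffold_bp < self.two_bin_upper_bp:
            raise ValueError("thresholds must be positive and ordered")
        if self.max_bin_bp <= 0:
            raise ValueError("max_bin_bp must be positive")


@dataclass
class GenoConfig:
    error_rate: float = 0.02  # per-read wrong-allele probability
    prior: tuple[float, float, float] = (0.25, 0.5, 0.25)  # MM, MF, FF
    call_posterior: float = 0.95
    min_reads: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if abs(sum(self.prior) - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")


@dataclass
class QcConfig:
    max_fish_missing: float = 0.5  # drop fish with MORE than this fraction missing
    max_marker_missing: float = 0.2  # drop markers with AT LEAST this fraction
    ratio_alpha: float = 0.001  # chi-square vs 1:2:1


def n_bins_for_scaffold(length_bp: int, config: BinningConfig | None = None) -> int:
    config = config or BinningConfig()
    if length_bp <= 0:
        raise ValueError("scaffold length must be positive")
    if length_bp < config.small_scaffold_bp:
        return 1
    if length_bp < config.two_bin_upper_bp:
        return 2
    return length_bp // config.max_bin_bp + 1


def bin_spans(length_bp: int, config: BinningConfig | None = None) -> list[tuple[int, int]]:
    """Contiguous, equal (+-1 bp), covering 1-based inclusive bin spans."""
    n = n_bins_for_scaffold(length_bp, config)
    edges = [length_bp * k // n for k in range(n + 1)]
    return [(edges[k] + 1, edges[k + 1]) for k in range(n)]


def assign_bins(
    snps: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    config: BinningConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the marker (bin) table and map each SNP to its bin.

    Returns ``(markers, snp_to_marker)`` where ``markers`` has one row
    per bin -- including empty bins -- with columns marker, scaffold,
    bin_index, start, end, snp_count; and ``snp_to_marker`` gives the
    marker row index for each SNP row.
    """
    config = config or BinningConfig()
    marker_rows = []
    marker_index: dict[tuple[str, int], int] = {}
    for s, L in scaffold_lengths.items():
        for b, (start, end) in enumerate(bin_spans(L, config)):
            marker_index[(s, b)] = len(marker_rows)
            marker_rows.append(
                {"marker": marker_name(s, b), "scaffold": s, "bin_index": b,
                 "start": start, "end": end, "snp_count": 0}
            )
    markers = pd.DataFrame(marker_rows)

    snp_to_marker = np.empty(len(snps), dtype=np.int64)
    for row, rec in enumerate(snps.itertuples(index=False)):
        s = rec.scaffold
        if s not in scaffold_lengths:
            raise ValueError(f"SNP {s}:{rec.pos}: unknown scaffold")
        L = scaffold_lengths[s]
        if not 1 <= rec.pos <= L:
            raise ValueError(f"SNP {s}:{rec.pos} beyond scaffold end ({L} bp)")
        n = n_bins_for_scaffold(L, config)
        b = min(n - 1, (rec.pos - 1) * n // L)
        # guard against floor interaction at uneven edges
        while rec.pos < markers.at[marker_index[(s, b)], "start"]:
            b -= 1
        while rec.pos > markers.at[marker_index[(s, b)], "end"]:
            b += 1
        snp_to_marker[row] = marker_index[(s, b)]
    counts = np.bincount(snp_to_marker, minlength=len(markers))
    markers["snp_count"] = counts
    return markers, snp_to_marker


def pool_counts(
    counts: AlleleCountMatrix, snp_to_marker: np.ndarray, n_markers: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sum member-SNP reads per (marker, F2); empty bins stay all-zero."""
    M = np.zeros((n_markers, counts.n_f2), dtype=np.int64)
    F = np.zeros((n_markers, counts.n_f2), dtype=np.int64)
    np.add.at(M, snp_to_marker, counts.m)
    np.add.at(F, snp_to_marker, counts.f)
    return M, F


def genotype_posteriors(
    M: np.ndarray, F: np.ndarray, config: GenoConfig | None = None
) -> np.ndarray:
    """Posterior over (MM, MF, FF) from pooled marine/freshwater reads.

    Freshwater reads are Binomial(m+f, p) with p = eps, 1/2, 1-eps for
    the three states; the binomial coefficient cancels in normalization.
    """
    config = config or GenoConfig()
    eps = config.error_rate
    ps = np.array([eps, 0.5, 1.0 - eps])
    M = np.asarray(M, dtype=float)
    F = np.asarray(F, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = (
            F[..., None] * np.log(ps)[None, :]
            + M[..., None] * np.log(1.0 - ps)[None, :]
        )
    loglik = np.where(np.isnan(loglik), -np.inf, loglik)
    logpost = loglik + np.log(np.asarray(config.prior))
    logpost -= logsumexp(logpost, axis=-1, keepdims=True)
    return np.exp(logpost)


def call_genotypes(
    M: np.ndarray, F: np.ndarray, config: GenoConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized genotype calls; returns (codes, posteriors).

    A state is called when its posterior reaches ``call_posterior``;
    otherwise an adjacent pair (MM,MF) or (MF,FF) reaching it yields the
    composite codes D (not FF) or C (not MM); otherwise, or when total
    reads fall below ``min_reads``, the call is missing.
    """
    config = config or GenoConfig()
    post = genotype_posteriors(M, F, config)
    tau = config.call_posterior
    codes = np.full(post.shape[:-1], MISSING, dtype=np.int8)
    top = np.argmax(post, axis=-1)
    pmax = np.take_along_axis(post, top[..., None], axis=-1)[..., 0]
    hard = pmax >= tau
    codes[hard] = top[hard].astype(np.int8)
    not_ff = post[..., A] + post[..., H]
    not_mm = post[..., H] + post[..., B]
    comp_d = ~hard & (not_ff >= tau)
    comp_c = ~hard & ~comp_d & (not_mm >= tau)
    codes[comp_d] = D
    codes[comp_c] = C
    codes[(M + F) < config.min_reads] = MISSING
    return codes, post


def call_bin_genotype(m: int, f: int, config: GenoConfig | None = None):
    """Single-bin convenience wrapper; returns (code, posterior 3-vector)."""
    codes, post = call_genotypes(np.array([[m]]), np.array([[f]]), config)
    return int(codes[0, 0]), post[0, 0]


def _marker_skew_direction(codes_row: np.ndarray) -> int:
    """Sign of the freshwater allele-frequency deviation from 1/2 (hard calls)."""
    nA = int((codes_row == A).sum())
    nH = int((codes_row == H).sum())
    nB = int((codes_row == B).sum())
    n2 = 2 * (nA + nH + nB)
    if n2 == 0:
        return 0
    return int(np.sign((nH + 2 * nB) / n2 - 0.5))


def apply_qc(
    codes: np.ndarray,
    markers: pd.DataFrame,
    config: QcConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Drop bad fish, then bad markers; returns (codes, fish_idx, marker_idx, log).

    Order is fixed: fish with >50% missing genotypes first (their
    missingness would otherwise inflate marker missingness), then
    markers missing in >=20% of remaining fish, then markers whose hard-
    call MM:MF:FF counts fail a chi-square test against 1:2:1 at
    ``ratio_alpha`` -- unless an adjacent marker on the same scaffold is
    skewed in the same direction (genuine segregation distortion spans
    neighbouring bins; an isolated aberrant marker does not).
    """
    config = config or QcConfig()
    n_markers, n_f2 = codes.shape
    drop_rows = []

    fish_missing = (codes == MISSING).mean(axis=0)
    fish_keep = fish_missing <= config.max_fish_missing
    for i in np.flatnonzero(~fish_keep):
        drop_rows.append({"kind": "fish", "id": i,
                          "reason": f"missing fraction {fish_missing[i]:.3f} > "
                                    f"{config.max_fish_missing}"})
    codes = codes[:, fish_keep]

    marker_missing = (codes == MISSING).mean(axis=1)
    keep = marker_missing < config.max_marker_missing
    for i in np.flatnonzero(~keep):
        drop_rows.append({"kind": "marker", "id": markers["marker"].iloc[i],
                          "reason": f"missing fraction {marker_missing[i]:.3f} >= "
                                    f"{config.max_marker_missing}"})

    # aberrant allelic ratio with same-scaffold adjacency rescue
    nA = (codes == A).sum(axis=1)
    nH = (codes == H).sum(axis=1)
    nB = (codes == B).sum(axis=1)
    n = nA + nH + nB
    directions = np.array([_marker_skew_direction(codes[i]) for i in range(n_markers)])
    aberrant = np.zeros(n_markers, dtype=bool)
    for i in range(n_markers):
        if not keep[i] or n[i] == 0:
            continue
        expected = n[i] * np.array([0.25, 0.5, 0.25])
        chi2 = float((((np.array([nA[i], nH[i], nB[i]]) - expected) ** 2)
                      / expected).sum())
        if stats.chi2.sf(chi2, df=2) < config.ratio_alpha:
            aberrant[i] = True
    scaf = markers["scaffold"].to_numpy()
    order = np.lexsort((markers["bin_index"].to_numpy(), scaf))
    pos_in_order = np.empty(n_markers, dtype=int)
    pos_in_order[order] = np.arange(n_markers)
    for i in np.flatnonzero(aberrant & keep):
        rescued = False
        j = pos_in_order[i]
        for k in (j - 1, j + 1):
            if 0 <= k < n_markers:
                nb = order[k]
                if (scaf[nb] == scaf[i] and aberrant[nb]
                        and directions[nb] == directions[i] != 0):
                    rescued = True
        if not rescued:
            keep[i] = False
            drop_rows.append({"kind": "marker", "id": markers["marker"].iloc[i],
                              "reason": "aberrant allelic ratio (1:2:1 chi-square)"})

    log = pd.DataFrame(drop_rows, columns=["kind", "id", "reason"])
    fish_idx = np.flatnonzero(fish_keep)
    marker_idx = np.flatnonzero(keep)
    return codes[keep], fish_idx, marker_idx, log
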