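"""Identify phased homozygous-difference SNPs and sieve them.

The sieve keeps SNPs whose pooled (cross-wide) behaviour is consistent
with a properly segregating marker: pooled freshwater allele fraction
near 1:1 and pooled coverage in a band that excludes poorly covered and
repetitive sites.  Coverage is expressed in RPMM (reads per million
mapped): an allele's read counts summed over F2s, divided by the summed
total mapped reads, times 1e6 -- i.e. the total-reads-weighted mean of
per-F2 normalized counts.

Regions under genuine segregation distortion (meiotic drive, genotype-
class lethality) produce runs of SNPs skewed in the same direction; an
adjacency rule keeps those while discarding isolated skewed SNPs, which
are more likely alignment or phasing artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlleleCountMatrix

log = logging.getLogger(__name__)


@dataclass
class SieveConfig:
    min_fraction: float = 0.2
    max_fraction: float = 0.8
    min_total_rpmm: float = 0.2
    max_total_rpmm: float = 3.0
    skew_window: int = 1_000_000  # bp
    skew_test_alpha: float = 0.001
    weighted: bool = True  # pooled-ratio RPMM; False = unweighted per-F2 mean

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction < self.max_fraction <= 1.0:
            raise ValueError("fraction bounds must satisfy 0 <= min < max <= 1")
        if not 0.0 <= self.min_total_rpmm < self.max_total_rpmm:
            raise ValueError("RPMM bounds must satisfy 0 <= min < max")


def identify_homozygous_snps(
    grandparents: pd.DataFrame,
    marine_col: str = "marine_gt",
    freshwater_col: str = "freshwater_gt",
) -> pd.DataFrame:
    """Return sites where both grandparents are homozygous for different alleles.

    ``grandparents`` carries one row per site with columns ``scaffold``,
    ``pos`` and two diploid genotype strings like ``"A/A"``.  Sites with
    a missing call are skipped.  The marine/freshwater phase comes from
    the grandparent population labels (column roles).
    """
    rows = []
    for rec in grandparents.itertuples(index=False):
        gm = getattr(rec, marine_col)
        gf = getattr(rec, freshwater_col)
        if not isinstance(gm, str) or not isinstance(gf, str):
            continue
        am = gm.split("/")
        af = gf.split("/")
        if len(am) != 2 or len(af) != 2 or "." in am + af:
            continue
        if am[0] != am[1] or af[0] != af[1]:
            continue  # heterozygous grandparent
        if am[0] == af[0]:
            continue  # no homozygous difference
        rows.append(
            {"scaffold": rec.scaffold, "pos": rec.pos,
             "marine_allele": am[0], "freshwater_allele": af[0]}
        )
    return pd.DataFrame(rows, columns=["scaffold", "pos", "marine_allele",
                                       "freshwater_allele"])


def compute_rpmm(counts: AlleleCountMatrix, weighted: bool = True) -> pd.DataFrame:
    """Per-SNP RPMM records: marine/freshwater RPMM, total, fraction, pooled counts.

    F2s with zero total mapped reads are excluded from the sums with a
    logged warning.  ``weighted=True`` (default) is the pooled ratio
    10^6 * sum_i c_i / sum_i T_i; ``weighted=False`` averages the per-F2
    normalized counts 10^6 * c_i / T_i without weighting.
    """
    ok = counts.total_reads > 0
    if not ok.all():
        log.warning("excluding %d F2(s) with zero total mapped reads",
                    int((~ok).sum()))
    m = counts.m[:, ok].astype(float)
    f = counts.f[:, ok].astype(float)
    T = counts.total_reads[ok].astype(float)
    if weighted:
        denom = T.sum()
        rpmm_m = 1e6 * m.sum(axis=1) / denom
        rpmm_f = 1e6 * f.sum(axis=1) / denom
    else:
        rpmm_m = (1e6 * m / T[None, :]).mean(axis=1)
        rpmm_f = (1e6 * f / T[None, :]).mean(axis=1)
    total = rpmm_m + rpmm_f
    with np.errstate(invalid="ignore"):
        fraction = np.where(total > 0, rpmm_f / total, np.nan)
    out = counts.snps.copy()
    out["rpmm_marine"] = rpmm_m
    out["rpmm_freshwater"] = rpmm_f
    out["total_rpmm"] = total
    out["freshwater_fraction"] = fraction
    out["pooled_m"] = counts.m[:, ok].sum(axis=1)
    out["pooled_f"] = counts.f[:, ok].sum(axis=1)
    return out


def apply_sieve(records: pd.DataFrame, config: SieveConfig | None = None) -> pd.Series:
    """Inclusive-bounds pass/fail on fraction and total RPMM (NaN fraction fails)."""
    config = config or SieveConfig()
    frac = records["freshwater_fraction"]
    total = records["total_rpmm"]
    ok = (
        (frac >= config.min_fraction)
        & (frac <= config.max_fraction)
        & (total >= config.min_total_rpmm)
        & (total <= config.max_total_rpmm)
    )
    return ok.fillna(False)


def coverage_pass(records: pd.DataFrame, config: SieveConfig | None = None) -> pd.Series:
    config = config or SieveConfig()
    total = records["total_rpmm"]
    return (total >= config.min_total_rpmm) & (total <= config.max_total_rpmm)


def skew_flags(records: pd.DataFrame,
               config: SieveConfig | None = None) -> pd.DataFrame:
    """Two-sided binomial test of the pooled counts against 1:1.

    Returns columns ``skewed`` (bool) and ``skew_direction`` (+1 toward
    freshwater, -1 toward marine, 0 if not skewed).  The two-sided
    p-value is the doubled smaller tail (capped at 1).
    """
    m = records["pooled_m"].to_numpy(dtype=np.int64)
    f = records["pooled_f"].to_numpy(dtype=np.int64)
    n = m + f
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = stats.binom.cdf(f, n, 0.5)
        hi = stats.binom.sf(f - 1, n, 0.5)
    config = config or SieveConfig()
    pval = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    pval = np.where(n > 0, pval, 1.0)
    skewed = pval < config.skew_test_alpha
    direction = np.where(skewed, np.sign(f - m).astype(int), 0)
    return pd.DataFrame({"skewed": skewed, "skew_direction": direction},
                        index=records.index)


def rescue_skewed_snps(records: pd.DataFrame,
                       config: SieveConfig | None = None) -> pd.Series:
    """Final keep set combining coverage, fraction, and skew-adjacency rules.

    Within coverage-passing SNPs: a non-skewed SNP is kept iff its
    fraction lies inside the sieve bounds; a skewed SNP is kept iff at
    least one of its nearest flanking coverage-passing SNPs on the same
    scaffold, within ``skew_window``, is skewed in the same direction
    (so genuine distorted regions survive, isolated skewed SNPs do not).
    Coverage failures are never rescued.
    """
    config = config or SieveConfig()
    cov = coverage_pass(records, config).to_numpy()
    frac_ok = apply_sieve(records, config).to_numpy()
    sk = skew_flags(records, config)
    skewed = sk["skewed"].to_numpy()
    direction = sk["skew_direction"].to_numpy()

    keep = np.zeros(len(records), dtype=bool)
    keep[cov & ~skewed & frac_ok] = True

    scaf = records["scaffold"].to_numpy()
    pos = records["pos"].to_numpy()
    for s in pd.unique(scaf):
        idx = np.flatnonzero((scaf == s) & cov)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        for j, i in enumerate(idx):
            if not skewed[i]:
                continue
            neigh_ok = False
            for k in (j - 1, j + 1):
                if 0 <= k < len(idx):
                    nb = idx[k]
                    if (
                        skewed[nb]
                        and direction[nb] == direction[i]
                        and abs(int(pos[nb]) - int(pos[i])) <= config.skew_window
                    ):
                        neigh_ok = True
            keep[i] = neigh_ok
    return pd.Series(keep, index=records.index)


def sieve_snps(counts: AlleleCountMatrix,
               config: SieveConfig | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Full sieve pipeline; returns (kept positional index, annotated records)."""
    config = config or SieveConfig()
    records = compute_rpmm(counts, weighted=config.weighted)
    keep = rescue_skewed_snps(records, config)
    records = records.assign(kept=keep.to_numpy())
    kept_idx = np.flatnonzero(keep.to_numpy())
    log.info("sieve: %d of %d SNPs kept", len(kept_idx), len(records))
    return kept_idx, records
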