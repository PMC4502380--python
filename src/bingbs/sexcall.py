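"""Call F2 sex from relative sex-chromosome sequencing depth.

In an XX/XY system the hemizygous sex carries one sex-chromosome copy,
so its sex-chromosome depth is about half its autosomal depth.  The
statistic is the per-fish ratio of reads per SNP on the sex scaffold to
reads per SNP on the autosomes, which cancels overall library depth.
Fish inside a dead zone between the thresholds, or with too few
sex-chromosome reads, are left unknown rather than guessed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import A, B, MISSING, AlleleCountMatrix
from .binning import GenoConfig


def call_sex(
    counts: AlleleCountMatrix,
    sex_chromosome: str,
    thresholds: tuple[float, float] = (0.65, 0.85),
    min_reads: int = 200,
) -> pd.DataFrame:
    """Depth-ratio sex calls; returns DataFrame(f2, depth_ratio, call).

    ratio < thresholds[0] -> XY; ratio > thresholds[1] -> XX; otherwise,
    or when the fish has fewer than ``min_reads`` sex-chromosome reads
    (ratio too noisy), the call is unknown.
    """
    on_sex = (counts.snps["scaffold"] == sex_chromosome).to_numpy()
    if not on_sex.any():
        raise ValueError(f"no SNPs on sex chromosome {sex_chromosome!r}")
    n_sex = int(on_sex.sum())
    n_auto = int((~on_sex).sum())
    if n_auto == 0:
        raise ValueError("no autosomal SNPs to normalize against")
    reads = counts.m + counts.f
    sex_reads = reads[on_sex].sum(axis=0)
    auto_reads = reads[~on_sex].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (sex_reads / n_sex) / (auto_reads / n_auto)
    lo, hi = thresholds
    call = np.where(ratio < lo, "XY", np.where(ratio > hi, "XX", "unknown"))
    call = np.where((sex_reads < min_reads) | (auto_reads == 0), "unknown", call)
    return pd.DataFrame(
        {"f2": counts.f2_ids, "depth_ratio": ratio, "call": call}
    )


def sex_aware_genotypes(
    codes: np.ndarray,
    M: np.ndarray,
    F: np.ndarray,
    markers: pd.DataFrame,
    sex_calls: pd.DataFrame,
    sex_chromosome: str,
    config: GenoConfig | None = None,
) -> np.ndarray:
    """Re-call sex-scaffold markers of XY fish under a haploid model.

    XY fish carry a single X haplotype, so sex-chromosome markers are
    either hemizygous-marine (coded A) or hemizygous-freshwater (B); a
    heterozygous-looking read mix is inconsistent with haploidy and
    becomes missing.  XX fish keep their diploid calls; fish of unknown
    sex get missing sex-chromosome genotypes.
    """
    config = config or GenoConfig()
    out = codes.copy()
    on_sex = (markers["scaffold"] == sex_chromosome).to_numpy()
    if not on_sex.any():
        return out
    call = sex_calls["call"].to_numpy()
    xy = call == "XY"
    unknown = call == "unknown"
    out[np.ix_(on_sex, unknown)] = MISSING
    if not xy.any():
        return out

    eps = config.error_rate
    ps = np.array([eps, 1.0 - eps])  # hemizygous M, hemizygous F
    m = M[np.ix_(on_sex, xy)].astype(float)
    f = F[np.ix_(on_sex, xy)].astype(float)
    loglik = f[..., None] * np.log(ps) + m[..., None] * np.log(1.0 - ps)
    logpost = loglik - logsumexp(loglik, axis=-1, keepdims=True)
    post = np.exp(logpost)
    hap = np.full(m.shape, MISSING, dtype=np.int8)
    hap[post[..., 0] >= config.call_posterior] = A
    hap[post[..., 1] >= config.call_posterior] = B
    hap[(m + f) < config.min_reads] = MISSING
    out[np.ix_(on_sex, xy)] = hap
    return out
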