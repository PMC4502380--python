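"""Synthetic F2 intercross generator with recorded truth.

Emulates the data a binned-GBS experiment produces: two divergent
grandparental populations (marine M, freshwater F), F1 hybrids
intercrossed to F2s, and shallow sequencing of ~10^5 phased homozygous-
difference SNPs at ~1.5x per sample.  Meioses follow a Haldane
(no-interference) model: crossovers per gamete per chromosome are
Poisson with mean equal to the genetic length in Morgans, placed
uniformly.  Reads at a SNP are Poisson(mean_coverage x per-fish depth
factor), each read drawn from one of the fish's two allele copies and
flipped with probability ``error_rate``.

Optional features mirror the quirks of real crosses: segregation-
distorted regions (gametes carry the freshwater allele at a stated
frequency across a span), an X-hemizygous sex scaffold (XY fish carry a
single haplotype at half depth), and QTL effects feeding a phenotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import AlleleCountMatrix


@dataclass(frozen=True)
class DistortedRegion:
    scaffold: str
    start: int
    end: int
    freshwater_freq: float  # gamete-level frequency of the F allele in the span


@dataclass(frozen=True)
class QtlEffect:
    scaffold: str
    pos: int
    additive: float  # half the MM-FF difference, sign = effect of the F allele
    dominance: float  # deviation of MF from the MM/FF midpoint
    residual_sd: float


@dataclass
class SimConfig:
    n_f2: int = 350
    n_chromosomes: int = 21
    scaffold_lengths: tuple[int, ...] = ()
    snp_density: float = 100.0  # SNPs per Mb
    mean_coverage: float = 1.5  # reads per SNP per F2
    error_rate: float = 0.01  # per-read wrong-allele probability
    recomb_rate: float = 4.0  # cM per Mb (stickleback-like: ~1600-2000 cM / 436 Mb)
    distorted_regions: tuple[DistortedRegion, ...] = ()
    male_fraction: float = 0.5
    sex_chromosome: str | None = None
    qtl_spec: tuple[QtlEffect, ...] = ()
    trait_mean: float = 0.0
    coverage_cv: float = 0.3  # per-fish depth factor coefficient of variation
    chromosome_assignment: tuple[int, ...] | None = None  # scaffold -> chromosome (1-based)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if not self.scaffold_lengths or any(L <= 0 for L in self.scaffold_lengths):
            raise ValueError("scaffold_lengths must be a non-empty list of positive bp")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if any(not 0.0 < dr.freshwater_freq < 1.0 for dr in self.distorted_regions):
            raise ValueError("distorted frequencies must lie in (0, 1)")
        if self.chromosome_assignment is not None and len(
            self.chromosome_assignment
        ) != len(self.scaffold_lengths):
            raise ValueError("chromosome_assignment length must match scaffold_lengths")


@dataclass
class TruthSet:
    """Everything the simulator knows that the pipeline must re-infer."""

    snps: pd.DataFrame  # scaffold, pos, chromosome, chrom_pos
    genotype: np.ndarray  # (n_snp, n_f2) int8, freshwater-allele dosage 0/1/2
    breakpoints: dict  # (f2_id, chromosome) -> sorted list of chrom-coordinate bp
    sex: np.ndarray  # "XX"/"XY" per F2
    placement: pd.DataFrame  # scaffold, chromosome, rank, orientation, length
    phenotype: pd.DataFrame  # f2, value, standard_length, sex
    f2_ids: list[str]
    config: SimConfig


def _assign_chromosomes(config: SimConfig) -> np.ndarray:
    if config.chromosome_assignment is not None:
        return np.asarray(config.chromosome_assignment, dtype=int)
    n = len(config.scaffold_lengths)
    chunks = np.array_split(np.arange(n), config.n_chromosomes)
    assignment = np.empty(n, dtype=int)
    for c, idx in enumerate(chunks, start=1):
        assignment[idx] = c
    return assignment


def _snp_positions(length: int, density: float) -> np.ndarray:
    """Evenly spaced SNPs at the requested density (deterministic layout)."""
    spacing = 1e6 / density
    pos = np.arange(spacing / 2.0, length, spacing)
    pos = np.unique(np.clip(np.round(pos).astype(np.int64), 1, length))
    return pos


def simulate_cross(config: SimConfig) -> tuple[AlleleCountMatrix, TruthSet]:
    """Simulate an F2 intercross; return observed counts and the truth."""
    rng = np.random.default_rng(config.seed)
    n_f2 = config.n_f2
    f2_ids = [f"F2_{i:04d}" for i in range(n_f2)]

    scaffolds = [str(i) for i in range(len(config.scaffold_lengths))]
    lengths = dict(zip(scaffolds, config.scaffold_lengths))
    chrom_of = dict(zip(scaffolds, _assign_chromosomes(config)))

    # truth placement: scaffolds in input order along each chromosome, all '+'
    placement_rows = []
    offsets: dict[str, int] = {}
    chrom_len: dict[int, int] = {}
    for s in scaffolds:
        c = chrom_of[s]
        rank = sum(1 for r in placement_rows if r["chromosome"] == c)
        offsets[s] = chrom_len.get(c, 0)
        chrom_len[c] = chrom_len.get(c, 0) + lengths[s]
        placement_rows.append(
            {"scaffold": s, "chromosome": c, "rank": rank, "orientation": "+",
             "length": lengths[s]}
        )
    placement = pd.DataFrame(placement_rows)

    # SNP table
    snp_frames = []
    for s in scaffolds:
        pos = _snp_positions(lengths[s], config.snp_density)
        snp_frames.append(
            pd.DataFrame(
                {"scaffold": s, "pos": pos, "chromosome": chrom_of[s],
                 "chrom_pos": pos + offsets[s]}
            )
        )
    snps = pd.concat(snp_frames, ignore_index=True)
    n_snp = len(snps)

    sex = np.where(rng.random(n_f2) < config.male_fraction, "XY", "XX")

    # meiosis: two independent gametes per F2 per chromosome
    genotype = np.zeros((n_snp, n_f2), dtype=np.int8)
    gametes = np.zeros((2, n_snp, n_f2), dtype=np.int8)  # freshwater allele 0/1
    breakpoints: dict = {}
    for c in sorted(chrom_len):
        in_c = snps["chromosome"].to_numpy() == c
        cpos = snps.loc[in_c, "chrom_pos"].to_numpy(dtype=float)
        L = chrom_len[c]
        morgans = config.recomb_rate * (L / 1e6) / 100.0
        for i in range(n_f2):
            bps: list[float] = []
            for g in range(2):
                n_xo = rng.poisson(morgans)
                xo = np.sort(rng.uniform(0, L, size=n_xo))
                start = rng.integers(0, 2)
                hap = (start + np.searchsorted(xo, cpos)) % 2
                gametes[g, in_c, i] = hap
                bps.extend(xo.tolist())
            breakpoints[(f2_ids[i], int(c))] = sorted(bps)

    # segregation distortion: per-gamete block redraw of the founder allele
    for dr in config.distorted_regions:
        s = dr.scaffold
        mask = (
            (snps["scaffold"].to_numpy() == s)
            & (snps["pos"].to_numpy() >= dr.start)
            & (snps["pos"].to_numpy() <= dr.end)
        )
        if not mask.any():
            continue
        for g in range(2):
            block = (rng.random(n_f2) < dr.freshwater_freq).astype(np.int8)
            gametes[g][np.ix_(mask, np.arange(n_f2))] = block[None, :]

    genotype = gametes[0] + gametes[1]

    # sex scaffold: XY fish are hemizygous (single maternal haplotype, doubled dosage)
    hemi = np.zeros((n_snp, n_f2), dtype=bool)
    if config.sex_chromosome is not None:
        sex_mask = snps["scaffold"].to_numpy() == config.sex_chromosome
        if not sex_mask.any():
            raise ValueError(f"sex_chromosome {config.sex_chromosome!r} has no SNPs")
        xy = sex == "XY"
        hemi[np.ix_(sex_mask, xy)] = True
        genotype[np.ix_(sex_mask, xy)] = 2 * gametes[0][np.ix_(sex_mask, xy)]

    # reads
    cv = config.coverage_cv
    if cv > 0:
        shape = 1.0 / cv**2
        depth_factor = rng.gamma(shape, 1.0 / shape, size=n_f2)
    else:
        depth_factor = np.ones(n_f2)
    lam = config.mean_coverage * depth_factor[None, :] * np.where(hemi, 0.5, 1.0)
    n_reads = rng.poisson(lam)
    p_f = genotype / 2.0
    p_f = p_f * (1 - config.error_rate) + (1 - p_f) * config.error_rate
    f_reads = rng.binomial(n_reads, p_f).astype(np.int32)
    m_reads = (n_reads - f_reads).astype(np.int32)
    total_reads = np.round(1e6 * depth_factor).astype(np.int64)

    # phenotype
    value = np.full(n_f2, config.trait_mean, dtype=float)
    res_var = 0.0
    for q in config.qtl_spec:
        d2 = (snps["scaffold"] == q.scaffold).to_numpy()
        if not d2.any():
            raise ValueError(f"QTL scaffold {q.scaffold!r} has no SNPs")
        idx = np.flatnonzero(d2)
        nearest = idx[np.argmin(np.abs(snps.loc[d2, "pos"].to_numpy() - q.pos))]
        dos = genotype[nearest]
        value += q.additive * (dos - 1) + q.dominance * (dos == 1)
        res_var += q.residual_sd**2
    if res_var > 0:
        value += rng.normal(0.0, np.sqrt(res_var), size=n_f2)
    phenotype = pd.DataFrame(
        {"f2": f2_ids, "value": value,
         "standard_length": rng.normal(45.0, 3.0, size=n_f2), "sex": sex}
    )

    counts = AlleleCountMatrix(
        snps[["scaffold", "pos"]].copy(), f2_ids, m_reads, f_reads, total_reads
    )
    truth = TruthSet(snps, genotype, breakpoints, sex, placement, phenotype,
                     f2_ids, config)
    return counts, truth


def scramble_assembly(
    truth: TruthSet, n_unanchor: int, n_flip: int, n_move: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive a degraded "prior" placement table from the truth.

    Chosen scaffolds are unplaced, orientation-flipped, or moved to a
    different chromosome; the edit log allows recovery scoring.  The
    three edit sets are disjoint.
    """
    rng = np.random.default_rng(seed)
    placement = truth.placement.copy()
    n_edit = n_unanchor + n_flip + n_move
    if n_edit > len(placement):
        raise ValueError("more edits requested than scaffolds available")
    chosen = rng.choice(placement["scaffold"].to_numpy(), size=n_edit, replace=False)
    un = set(chosen[:n_unanchor])
    fl = set(chosen[n_unanchor:n_unanchor + n_flip])
    mv = set(chosen[n_unanchor + n_flip:])

    chroms = sorted(placement["chromosome"].unique())
    log_rows = []
    prior = placement.set_index("scaffold").astype(
        {"rank": float, "chromosome": object}
    )
    for s in chosen:
        old = prior.loc[s]
        if s in un:
            log_rows.append({"scaffold": s, "edit": "unanchor",
                             "old_chromosome": old["chromosome"],
                             "old_rank": old["rank"],
                             "old_orientation": old["orientation"],
                             "new_chromosome": None, "new_rank": None,
                             "new_orientation": "?"})
            prior.loc[s, ["chromosome", "orientation"]] = [pd.NA, "?"]
            prior.loc[s, "rank"] = pd.NA
        elif s in fl:
            flipped = "-" if old["orientation"] == "+" else "+"
            log_rows.append({"scaffold": s, "edit": "flip",
                             "old_chromosome": old["chromosome"],
                             "old_rank": old["rank"],
                             "old_orientation": old["orientation"],
                             "new_chromosome": old["chromosome"],
                             "new_rank": old["rank"], "new_orientation": flipped})
            prior.loc[s, "orientation"] = flipped
        else:
            other = [c for c in chroms if c != old["chromosome"]]
            new_c = other[rng.integers(len(other))] if other else old["chromosome"]
            n_in = int((prior["chromosome"] == new_c).sum())
            new_rank = float(rng.integers(n_in + 1)) - 0.5  # insert between ranks
            log_rows.append({"scaffold": s, "edit": "move",
                             "old_chromosome": old["chromosome"],
                             "old_rank": old["rank"],
                             "old_orientation": old["orientation"],
                             "new_chromosome": new_c, "new_rank": new_rank,
                             "new_orientation": old["orientation"]})
            prior.loc[s, "chromosome"] = new_c
            prior.loc[s, "rank"] = new_rank

    prior = prior.reset_index()
    # densify ranks per chromosome
    placed = prior["chromosome"].notna()
    prior.loc[placed, "rank"] = (
        prior[placed].groupby("chromosome")["rank"].rank(method="first") - 1
    )
    log = pd.DataFrame(
        log_rows,
        columns=["scaffold", "edit", "old_chromosome", "old_rank",
                 "old_orientation", "new_chromosome", "new_rank",
                 "new_orientation"],
    )
    return prior, log


def truth_to_json(truth: TruthSet, path) -> None:
    """Persist the JSON-serializable parts of a TruthSet (no genotype matrix)."""
    payload = {
        "f2_ids": truth.f2_ids,
        "sex": truth.sex.tolist(),
        "breakpoints": {f"{f2}:{c}": v for (f2, c), v in truth.breakpoints.items()},
        "placement": truth.placement.to_dict(orient="records"),
        "phenotype": truth.phenotype.to_dict(orient="records"),
        "config": {
            k: v for k, v in asdict(truth.config).items()
            if k not in ("distorted_regions", "qtl_spec")
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
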