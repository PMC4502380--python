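# bingbs — binned genotyping-by-sequencing for F2 intercrosses

`bingbs` implements a *binned* GBS genotyping pipeline for large F2
intercrosses between two divergent founder populations (the motivating
system is marine × freshwater threespine stickleback crosses of ~350
fish).  Shallow sequencing (~1.5× per fish) of ~10⁵ phased
homozygous-difference SNPs is far too noisy to genotype site by site;
instead, SNPs are pooled into scaffold bins of at most 500 kb, turning
many unreliable observations into one ~150× binned marker per fish.
From those markers the package builds dense linkage maps, revises a
draft assembly's scaffold order and orientation, fine-maps individual
recombination breakpoints, and runs QTL genome scans.

It is aimed at researchers running cross-based genetic mapping in
organisms with fragmented draft assemblies, and ships a synthetic-cross
simulator with recorded truth so the entire pipeline is testable
without sequencing data.

## Method sketch

* **Sieve.** For each SNP, pooled allele counts across all F2s are
  normalized to reads per million mapped, RPMM(a) = 10⁶ Σᵢcₐᵢ / ΣᵢTᵢ.
  Kept SNPs have freshwater allele fraction in [0.2, 0.8] and total
  RPMM in [0.2, 3.0]; significantly skewed SNPs survive only inside
  runs of same-direction skew (genuine segregation distortion),
  isolated ones are removed.
* **Binned genotypes.** Pooled bin reads are binomial with freshwater-
  read probability ε, ½, or 1−ε under genotypes MM/MF/FF; a 1:2:1-prior
  posterior calls a state at ≥0.95, an adjacent pair (MM/MF or MF/FF)
  as an uncertain composite call, otherwise missing.
* **Sex calling.** XY fish have ~half sex-chromosome depth; the per-
  fish ratio of sex-chromosome to autosome reads per SNP separates XX
  (≈1.0) from XY (≈0.5), and XY sex-chromosome bins are re-called
  under a haploid model.
* **Linkage maps.** Two-point recombination fractions by maximum
  likelihood over the 9 joint F2 genotype classes (composite calls
  enter as partial observations); LOD ≥ 6 single-linkage grouping;
  seriation ordering; Haldane d = −50 ln(1−2r) (or Kosambi) distances.
* **Assembly revision.** Scaffolds are anchored to the chromosome of
  their linkage group, ranked by median marker cM, and oriented by the
  rank correlation of bp vs cM; two crosses merge into a consensus,
  leftover scaffolds are placed by genotype-dosage correlation, and a
  strand-aware liftover maps coordinates into the revised chromosomes.
* **Breakpoint HMM.** Per fish and chromosome, a three-state HMM on raw
  per-SNP counts — transitions from the Haldane map expansion of two
  meioses, binomial emissions — is decoded by forward–backward and
  Viterbi to bracket each crossover, and recombinant fish intersect
  into minimal QTL intervals.
* **QTL scans.** Haley–Knott regression of (covariate-adjusted)
  phenotypes on expected additive/dominance dosages,
  LOD = (n/2)·log₁₀(RSS₀/RSS₁), α = 0.05 thresholds from 1000
  permutations of the genome-wide maximum, PVE = 100·(1−10^(−2·LOD/n)),
  plus scans conditioned on a genotype class at a major locus.

## Worked example

Simulate a 350-fish cross with a recessive large-effect locus
(freshwater allele lowers the trait; MF near MM — the lateral-plate
architecture), bin the reads, and scan:

```python
import numpy as np
from bingbs.simulate import SimConfig, QtlEffect, simulate_cross
from bingbs import binning, qtl

cfg = SimConfig(
    n_f2=350, n_chromosomes=3, scaffold_lengths=(5_000_000,) * 3,
    snp_density=150, mean_coverage=1.5,
    qtl_spec=(QtlEffect("1", 2_500_000, -13.0, 11.0, 2.0),),
    trait_mean=19.7, seed=5,
)
counts, truth = simulate_cross(cfg)
lengths = dict(zip(truth.placement["scaffold"], truth.placement["length"].astype(int)))
markers, snp_to_bin = binning.assign_bins(counts.snps, lengths)
M, F = binning.pool_counts(counts, snp_to_bin, len(markers))
codes, posteriors = binning.call_genotypes(M, F)

probs = qtl.genotype_probabilities(posteriors, codes)
y = truth.phenotype["value"].to_numpy()
lods = qtl.scanone_hk(probs, y)
threshold = qtl.permutation_threshold(probs, y, n_perm=1000, seed=0)
peak = int(np.argmax(lods))
print(f"markers: {len(markers)}  mean binned coverage: {(M + F).mean():.0f}x")
print(f"peak marker: {markers['marker'].iloc[peak]}  LOD: {lods[peak]:.1f}")
print(f"alpha=0.05 threshold: {threshold:.2f}  PVE: {qtl.pve(lods[peak], cfg.n_f2):.1f}%")
```

prints

```
markers: 33  mean binned coverage: 103x
peak marker: 1_5  LOD: 232.3
alpha=0.05 threshold: 2.50  PVE: 95.3%
```

Each 5-Mb scaffold splits into 11 bins of ~455 kb that pool ~68 SNPs
each into ~100× markers; the scan peaks exactly at bin `1_5` — the bin
containing the
simulated causal position — far above the genome-wide threshold, and
the locus explains ~95% of the trait variance, as expected for a
near-Mendelian trait.

The same stages are scriptable from the shell via `bingbs
simulate|sieve|bin|sex|map|anchor|finemap|scan|liftover`; each
subcommand reads and writes plain TSV/CSV/JSON/AGP files (see
`bingbs --help`).

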