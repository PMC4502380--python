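# Methods

## The problem and the model

An F2 intercross between two divergent, inbred-enough founder
populations segregates two phased alleles at every informative SNP:
each fish carries 0, 1, or 2 copies of the "freshwater" allele with
prior 1:2:1.  At ~1.5× coverage a single SNP yields 0–3 reads — useless
for genotyping — but hundreds of neighbouring SNPs on a scaffold almost
always share one genotype, because crossovers are rare at the sub-Mb
scale.  Pooling reads within a bin therefore yields an effectively
high-coverage pseudo-marker whose error rate is governed by the pooled
binomial, not the per-SNP Poisson.  Everything in this package follows
from that observation.

## Simulator (`bingbs.simulate`)

The generator emulates the study design the pipeline targets: ~350 F2s,
~10⁵ phased SNPs, ~1.5× per-fish coverage, a 21-chromosome genome.

* **Meiosis.** Haldane model: per gamete and chromosome, crossover
  count ~ Poisson(genetic length in Morgans), positions uniform, no
  interference.  This matches the Haldane mapping function used
  downstream and gives closed-form oracles (e.g. a 1-Mb chromosome at
  1 cM/Mb yields 2 × 0.01 = 0.02 expected crossovers per F2 across its
  two meioses — asserted in the tests).
* **Rates and units.** `recomb_rate` defaults to 4 cM/Mb, the
  genome-wide average implied by stickleback-scale maps (~1600–2000 cM
  over ~436 Mb).  `snp_density` is SNPs per Mb on a deterministic even
  grid (random placement would only add noise orthogonal to everything
  tested).  `mean_coverage` is reads per SNP per fish; per-fish depth
  factors are Gamma with CV `coverage_cv` (default 0.3, echoing the
  large library-to-library depth variation of multiplexed GBS), and
  per-fish total mapped reads are 10⁶ × depth factor so that a SNP's
  total RPMM ≈ its mean coverage.
* **Reads.** Read count ~ Poisson; each read reports the wrong parental
  allele with probability `error_rate` (default 0.01; sequencing +
  mapping + phasing error combined).  Reads are abstract allele
  observations — no sequence emission, since alignment is out of scope
  and counts are the pipeline's native input.
* **Distortion.** A distorted region redraws each gamete's founder
  allele across the span as a block with the stated freshwater
  frequency, so neighbouring SNPs are skewed coherently — the situation
  the sieve's adjacency rescue must keep.
* **Sex.** The sex scaffold is X-hemizygous in XY fish: one maternal
  haplotype at doubled dosage, read depth halved; Y reads are not
  modelled.
* **Phenotype.** One trait: sum over QTL entries of a·(dosage−1) +
  d·[het], plus Gaussian noise whose sd combines the per-entry residual
  sds in quadrature, plus `trait_mean`; standard length ~ N(45, 3) mm
  and sex are independent covariates.
* **Assembly scrambling.** `scramble_assembly` degrades the truth
  placement by unanchoring, flipping, or moving disjoint scaffold sets
  and logs every edit for recovery scoring.

What the simulator does **not** emulate: reference bias, repeat-driven
coverage spikes (the >3 RPMM tail that the sieve's upper coverage bound
exists for), allele-specific mapping artifacts, genotyping batch
effects, or crossover interference.  Tests passing on this generator
show the pipeline's inference is correct under its stated model, not
that the sieve thresholds are optimal for any particular real library.

## Sieve (`bingbs.sieve`)

RPMM is implemented as the pooled ratio 10⁶ Σᵢcᵢ/ΣᵢTᵢ (the total-reads-
weighted mean of per-fish normalized counts); an unweighted per-fish
mean is available as a config switch.  Bounds (fraction 0.2–0.8, total
RPMM 0.2–3.0) are inclusive — "between x and y" is read inclusively,
and the boundary mass is zero in practice.  The skew test is a
two-sided binomial test of pooled counts against ½ (doubled smaller
tail) at α = 0.001; a skewed SNP survives iff a nearest flanking
coverage-passing SNP on the same scaffold within 1 Mb is skewed the
same direction.  Among coverage-passing SNPs the adjacency rule is the
only criterion applied to skewed SNPs, so a coherent distorted region
is kept even where its fraction leaves the 0.2–0.8 band; the coverage
band is never widened.  The α, window, and this composition are design
decisions — they reproduce the intended keep/remove behaviour with an
explicit, testable rule.

## Binning and genotype calls (`bingbs.binning`)

Bin counts follow the published series: 1 bin below 100 kb, 2 bins to
1 Mb, then ⌊L/500 kb⌋+1 equal bins (3 for 1–1.5 Mb, 4 for 1.5–2 Mb,
…), which caps bin length at 500 kb for scaffolds ≥ 1 Mb.  Bin spans
are computed with integer edges ⌊kL/n⌋ so they partition the scaffold
exactly with widths equal ±1 bp.

The caller uses binomial likelihoods with freshwater-read probability
ε (MM), ½ (MF), 1−ε (FF), ε defaulting to 0.02 at the bin level (a bin
pools SNPs of heterogeneous quality, so it is set above the simulator's
per-read 0.01), a 1:2:1 prior, a 0.95 call threshold, and a 3-read
floor.  When no single state reaches 0.95 but an adjacent pair does,
the composite calls D (= MM/MF, "not FF") and C (= MF/FF, "not MM") are
emitted — these arise almost exclusively in bins containing a
recombination breakpoint, where the read mixture genuinely supports two
states.  QC order is fixed: fish with >50% missing first (fish-level
missingness inflates marker missingness), then markers missing in ≥20%
of fish, then markers failing a χ² test against 1:2:1 at α = 0.001
unless rescued by a same-direction-skewed adjacent marker on the same
scaffold.  Zero-SNP bins emit all-missing genotypes and fall to the
missingness rule naturally.

## Sex calling (`bingbs.sexcall`)

The statistic is (sex-chromosome reads per SNP)/(autosome reads per
SNP) per fish, which cancels library depth.  Thresholds (0.65, 0.85)
leave an unknown dead zone between the XY (~0.5) and XX (~1.0) modes;
fish with fewer than 200 sex-chromosome reads are unknown regardless,
since the ratio's sampling error at lower counts spans the dead zone.
XY fish are re-called on the sex scaffold under a two-state haploid
model; balanced read mixtures are inconsistent with haploidy and become
missing.

## Linkage maps (`bingbs.linkage`)

The two-locus F2 likelihood comes from gamete phase probabilities
((1−r)/2 parental, r/2 recombinant per parent), giving a 3×3 joint
genotype table in r; observable codes (including composites) sum the
table over their compatible states, and missing pairs drop out.  The
MLE is found by bounded scalar maximization (single pairs) or an r-grid
with parabolic refinement (all-pairs, vectorized through indicator-
matrix products — ~10⁵ pairs in under a second).  Grouping is
single-linkage at LOD ≥ 6 and r ≤ 0.35; with ~350 fish, truly linked
markers exceed LOD 6 by orders of magnitude, so the exact threshold is
uncritical.  Ordering is greedy nearest-neighbour chain growth plus
2-opt reversals on Σ adjacent r̂ — adequate because binned markers are
dense and near-collinear; multipoint ML ordering is out of scope.  Map
distances default to Haldane (consistent with the simulator; Kosambi
available).  A map's overall orientation per group is arbitrary and is
normalized against physical marker keys when available.

## Assembly revision (`bingbs.assembly`)

Chromosome labels attach to linkage groups by a global greedy
assignment of prior-placed scaffold votes (scaffold count, then marker
count), so one misplaced scaffold cannot steal a chromosome's name from
its resident group.  Scaffold rank is median marker cM with ties broken
by prior rank then id; orientation is the sign of the Spearman
correlation of bp vs cM (unknown with <2 distinct cM values — in
practice the single-marker scaffolds).  Within-chromosome
rearrangements are scaffolds outside the longest increasing subsequence
of prior ranks in map order — the minimal set of moves explaining the
difference.  The consensus keeps agreements, accepts single-cross
placements with their evidence label, and excludes chromosome conflicts
with an explicit report.  Residual bins are placed by Pearson
correlation of genotype dosage (posterior mean, 0–1 freshwater scale)
against placed markers, with a 0.5 acceptance threshold and a 0.1
margin over the best other-chromosome competitor; missing dosages are
mean-imputed, which biases correlations mildly toward zero
(conservative).  The revised sequence uses fixed 1000-bp inter-scaffold
N gaps, recorded in AGP v2.0 so the liftover is exact and bijective
over covered coordinates.

## Breakpoint HMM (`bingbs.hmm`)

States MM/MF/FF; between SNPs d bp apart, r = (1−e^(−2ρd))/2 with ρ the
chromosome-wide rate (e.g. map cM / physical Mb — estimating ρ per fish
at 1.5× would be hopelessly unstable), and the transition matrix is the
tensor square of one meiosis reduced to dosage space.  Emissions drop
the binomial coefficient (constant across states); zero-read SNPs are
exactly flat.  Decoding is log-space forward–backward plus Viterbi;
posteriors are renormalized per SNP.  Breakpoint bounds use the
τ = 0.95 posterior convention: last confident SNP of the departing
state to first confident SNP of the arriving state.  Two breakpoints
closer than 1 Mb are flagged rather than suppressed — close doubles at
low coverage are real but unreliable.  Minimal QTL intervals intersect
half-line constraints under maximal consistency: positions inside a
fish's uncertainty interval are consistent with either phenotype class,
which guarantees the true locus is never excluded; contradictions
return an explicit result naming the offending fish.

## QTL scans (`bingbs.qtl`)

Haley–Knott regression on expected additive (P(FF)−P(MM)) and dominance
(P(MF)) dosages from the call posteriors; missing calls fall back to
the 1:2:1 prior.  No pseudomarker interpolation — binned markers sit
roughly every 1–2 cM, so between-marker positions add nothing.
Permutation thresholds permute the trait, re-projecting all
permutations through each marker's precomputed orthonormal basis (one
matrix product genome-wide), and take the (1−α) quantile of the max
LOD; fewer than 20 permutations are refused.  PVE = 100·(1−10^(−2LOD/n))
— exact for a single-QTL fit; values adjusted for other QTL in a
multi-QTL model do not satisfy this identity, which is why class means
and PVE are reported per single scan only.  Class means use hard calls
only; composites contribute to scans via their posteriors but not to
means.  Conditioned scans subset to one hard genotype class at a
conditioning marker (refusing <10 fish, warning <30) and rerun scan +
permutations within the subset.  Multiple-QTL model selection is
deliberately out of scope.

## Problem sizes and numerical choices

The test and acceptance workloads are scaled to run a full suite in
about a minute of simulation-heavy work: genotype recovery uses 350
F2s × 6 one-Mb scaffolds at 250 SNPs/Mb (≥75 SNPs/bin, the regime where
binned calls are ≥99% concordant with truth); assembly recovery uses 21
chromosomes × 3 scaffolds with 10 unanchored + 10 flipped + 2 moved;
scan calibration uses a 21-group, ~1030-marker map with 200 null traits
at 100 permutations each (the α = 0.05 threshold median lands at ~3.9,
where ~300 effective tests put it).  Tolerances follow the underlying
sampling error: pooled allele-ratio checks use the fact that the
founder-haplotype draw (~2 quasi-independent draws per fish per
chromosome), not read sampling, dominates the ratio's variance.
Likelihood grids use float32 with parabolic refinement (r̂ precision
~10⁻³, i.e. ~0.1 cM); HMM and posterior computations are float64 in log
space and match exhaustive enumeration to 10⁻⁹.

## Known limitations

* Two-point + seriation ordering can locally misorder markers separated
  by < 1 recombinant in the cross; the 2-opt polish does not guarantee
  a global optimum.
* The read-correlation placement assumes missingness is uninformative;
  systematic missingness correlated with genotype would bias it.
* The sieve's skew test uses pooled counts and therefore cannot
  distinguish distortion from allele-specific mapping bias; only the
  adjacency structure separates them.
* Sex calling assumes a single X-hemizygous sex chromosome and no
  pseudo-autosomal recombination modelling.
* The HMM treats ρ as constant per chromosome; strong local rate
  variation (e.g. inversions) widens breakpoint intervals there rather
  than biasing them.
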