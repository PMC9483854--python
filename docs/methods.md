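# Methods

## Scope and data model

The package evaluates individual-identification SNP (II-SNP) panels: a
marker panel (`FrequencyPanel`: identifier, autosome, 1-based position,
ordered allele list, frequency vector per locus), unordered diploid
genotypes (`GenotypeMatrix`, allele indices with −1 for missing calls;
phase is discarded on input because no statistic here uses it), and
long-format per-allele amplicon read counts (`ReadCountTable`, with the
reserved symbol `*` for off-target reads). Missing calls are excluded
per locus from every statistic (pairwise deletion).

## Synthetic cohorts

The generator produces every input the pipeline consumes, under the
conditions of the evaluated study design: 111 loci (89 bi-allelic, 22
multi-allelic) across the 22 autosomes, 187 diploid individuals, ~5000×
mean depth, mean heterozygote allele balance ~0.87 and noise ~0.004.

* **Frequencies.** Bi-allelic major-allele frequency uniform on
  [0.4, 0.6] (the forensic screening window). Multi-allelic spectra are
  symmetric Dirichlet(α = 2), rejected until every allele is ≥ 0.01.
  The default allele-count range for multi-allelic loci is {3, 4}: a SNP
  has at most four bases, and with Dirichlet(2) spectra this sets the
  panel mean heterozygosity to ≈ 0.52, the study condition. Loci are
  placed round-robin on 22 simulated 250 Mb autosomes with gaps strictly
  greater than 10 Mb, so a fresh panel satisfies the spacing criterion by
  construction; requesting more loci than placeable raises a sizing
  error.
* **Genotypes.** Two independent draws from the locus frequency vector
  (Hardy–Weinberg), no missingness.
* **Relative pairs.** Per pair and locus, an IBD state is drawn from the
  relationship's (k0, k1, k2); state 2 copies the genotype, state 1
  copies a uniformly chosen allele and draws the other from the
  population, state 0 draws independently. The latent states are
  returned for recovery checks.
* **Structured populations.** Balding–Nichols: per population and locus,
  frequencies are Dirichlet-drawn with parameters pₐ(1−F)/F around the
  ancestral vector (Beta for bi-allelic); F = 0 copies the ancestral
  frequencies exactly, avoiding the division by zero.
* **Read counts.** Total depth per call is negative binomial with mean
  5000 and dispersion (size) 10 — a mid-range overdispersion for
  amplicon MPS, chosen once since only summary moments are published.
  Heterozygote reads split binomially with proportion
  logistic(N(0, σ)); σ defaults to 0.186, solving
  E[min/max] = 2·e^{σ²/2}·Φ(−σ) = 0.867 for the target mean allele
  balance. Each read is independently misassigned with probability
  `noise_rate` to a uniformly chosen non-genotype allele of the locus or
  to the off-target bucket, so the pipeline's NL estimator recovers the
  rate directly. Zero-depth calls are permitted and flagged downstream.

All randomness flows from one integer seed through `SeedSequence`
spawning: identical configurations give bit-identical outputs.

What the generator does *not* emulate: linkage between loci, genotyping
error and allele dropout in the genotype matrix itself, locus-specific
amplification efficiency (every locus shares one depth distribution,
unlike the ~780×–12000× per-locus spread seen in real runs), mutation in
pedigrees, and admixed or continuously structured populations. Passing
tests therefore demonstrate correctness of the estimators under their
own model assumptions, not robustness to real-data artefacts.

## Forensic parameters

Per locus with n typed individuals: Ho is the heterozygote fraction;
He = 2n/(2n−1)·(1−Σpᵢ²) (Nei's unbiased gene diversity — the correction
is what reproduces the printed He→PIC pairing at n = 187);
PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein); PM is the sum of squared
*observed* genotype-class frequencies (the forensic-tool convention,
which keeps PM + PD = 1 exactly); PE = h²(1 − 2h(1−h)²) with h = Ho
(single-parent exclusion; this form reproduces both published PE
extremes from their Ho values). Monomorphic loci report He = PIC = 0.
Report tables round half-up to 4 decimals.

Panel cumulatives multiply in log10 space (CPM = Π PM, CPE complement
Π(1−PE)) and are displayed as `m.mmmE±ee` / `1-m.mmmE±ee`, since the
headline numbers (~10⁻⁵⁰) are far beyond float-decimal display defaults.

## Exact tests

**HWE.** Bi-allelic: full enumeration of the conditional distribution of
genotype tables given the allele counts (Levene/Haldane); the two-sided
p-value sums the probabilities of all tables no more probable than the
observed one, ties included (probability-ordering convention). Computed
with log-gamma factorials; a tie tolerance of 1e−9 on log-probabilities
absorbs rounding. Multi-allelic: Monte-Carlo version that shuffles the
observed gene-copy vector, re-pairs it into diploids and compares
conditional table probabilities, with the (x+1)/(N+1) estimator; the
default is 10⁵ replicates and fewer than 10³ is rejected. An exact
conditional test at these sample sizes is conservative — its p-values
are discrete and stochastically dominate U(0,1) — so calibration is
asserted as validity (P(p < t) ≤ t), not uniformity.

**Linkage disequilibrium.** Genotypic G (log-likelihood-ratio) statistic
on the two-locus genotype contingency table; the null distribution comes
from permuting one locus's genotype column (default 10⁴ permutations).
Monomorphic partners return p = 1 with a warning. During panel
screening, permutation stops early once enough exceedances have
accumulated that the pair can no longer be significant at the Bonferroni
threshold — a decision-exact shortcut that leaves every reject/accept
outcome identical to the full run.

## Screening pipeline

Filters run cheapest-first: exclusion list (the disease-association
criterion is a database curation step, so it enters as a user-supplied
list), frequency window / MAF floor, Ho floor, HWE, pairwise LD, then
spacing. The Bonferroni m for each test stage is the number of loci (or
pairs) actually entering that stage. LD conflicts drop the lower-Ho
locus of the significant pair, and the spacing filter resolves
conflicts greedily left-to-right per chromosome in favour of higher Ho
(ties keep the earlier position) — both choices preserve identification
power. Permutation seeds derive from the run seed and locus identifiers
(CRC-32), so p-values are independent of panel composition and the
filter is idempotent.

## Sequencing QC

DoC is the per-call total (genotype alleles plus off-target), summarised
as mean ± population SD (divisor N, fixed for determinism) per locus.
ACR is defined over heterozygous calls with both allele counts positive
as min/max of the two genotype-allele counts, averaged per locus;
zero-count alleles are excluded and reported as dropouts. NL is the
per-call off-genotype read fraction (including off-target), averaged
over calls with positive depth; NL plus the genotype-read fraction is
exactly 1 per call. Casework flags: calls below 20× and loci with mean
ACR below 0.66.

## Kinship likelihood ratios

P(pair) = P(g₁)·[k0·P(g₂) + k1·P(g₂ | one IBD allele) + k2·1(g₂ = g₁)],
with the one-IBD transition summing over which allele of g₁ is shared
(weight ½ each). No mutation, silent alleles or coancestry correction
(θ = 0). Multi-locus LRs multiply; log10 LR is additive. The simulation
experiment draws pairs under the true relationship and under
unrelatedness, scores both with the test-vs-unrelated LR, and summarises
separation with a decision-threshold overlap: the mean of the related
fraction with log10 LR ≤ 0 and the unrelated fraction ≥ 0. The published
comparison is qualitative ("a small proportion of LRs overlapped" for
half siblings), so this precise surrogate is what the tests assert:
full-sibling overlap < 0.01 and half-sibling overlap strictly greater on
the same panel and seed.

## Population comparison

DA = 1 − (1/L)·Σ_loci Σ_alleles √(xₐyₐ) over the union of allele lists,
averaged over all shared loci including monomorphic ones (Nei's
definition, fixed for determinism). FST is the genotype-based
Weir–Cockerham θ with variance components summed over loci and alleles
before the ratio (ratio-of-sums); negative estimates are reported as
computed; the genotype-based estimator was chosen over a haplotypic
AMOVA formulation because the data are unphased. Neighbor joining
(Saitou–Nei) breaks Q-matrix ties deterministically by the
lexicographically smallest leaf-label pair; negative branch lengths are
clamped to zero with the deficit moved to the sibling edge (preserving
the pair distance); the final three clusters join at one node via the
three-point formulas, which writes the unrooted tree as a rooted
trifurcation — exact on additive matrices. PCA encodes each individual
as dosages of all-but-one allele per locus (dropping one removes the
frequency-closure collinearity), mean-imputes missing dosages, drops
constant columns, centres, and decomposes by full SVD.

## Problem sizes and tolerances

Simulation-backed tests use the study-scale cohort (111 loci × 187
individuals) where the claim concerns that design (sibling separation,
QC recovery) and smaller panels (5–500 bi-allelic loci, 50–200
individuals) for estimator-recovery checks, with tolerances set from
the corresponding sampling error (binomial or 3-standard-error bounds).
Monte-Carlo agreement between the HWE enumeration and shuffling paths is
asserted at ±0.01 with 10⁵ replicates. The LR-distribution experiments
use 10⁴ pairs.

## Known limitations

Exact multi-allelic HWE enumeration is not implemented (Monte-Carlo
only). Haplotype-level LD with EM phasing, θ-corrected match
probabilities, pedigrees beyond pairs, mutation models, bootstrap
support on trees and admixture inference are out of scope. FST values
from different estimator families (haplotypic AMOVA vs genotype-based θ)
are not numerically interchangeable, which matters when comparing
against published matrices computed with other tools.
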