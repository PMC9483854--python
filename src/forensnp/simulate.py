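"""Synthetic genotype, pedigree-pair, population and read-count simulator.

Generates every input the evaluation pipeline needs with the statistical
structure the downstream analyses assume:

* marker panels with forensically screened frequency spectra (bi-allelic
  major-allele frequencies in [0.4, 0.6]; multi-allelic Dirichlet spectra
  with every allele above a minor-allele-frequency floor),
* Hardy–Weinberg genotypes,
* relative pairs under arbitrary IBD-coefficient models (k0, k1, k2),
* structured subpopulations under the Balding–Nichols model at a target F,
* amplicon MPS read counts with negative-binomial depth, logistic-normal
  heterozygote allele imbalance and a uniform misassignment noise rate.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so identical configurations
yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    OFFTARGET,
    FrequencyPanel,
    GenotypeMatrix,
    Locus,
    ReadCountTable,
    ValidationError,
)

N_AUTOSOMES = 22
CHROM_LENGTH = 250_000_000  # simulated autosome length, bp
MIN_SPACING = 10_000_000  # bp between loci sharing a chromosome

#: Allele symbols in panel order.  Up to four alleles a locus is an ordinary
#: SNP; five- and six-allele loci (allowed but not default) get two-base
#: symbols so the panel still serialises to valid VCF.
ALLELE_SYMBOLS = ("A", "C", "G", "T", "AA", "AC")


class SizingError(ValidationError):
    """More loci requested than can be placed at the minimum spacing."""


@dataclass
class SimulationConfig:
    """Study-design constants for one synthetic cohort.

    Defaults reproduce the evaluated study design: a 111-locus
    individual-identification panel (89 bi-allelic + 22 multi-allelic SNPs)
    typed in 187 diploid individuals at a mean amplicon depth of 5000x with
    mean heterozygote allele-balance ~0.87 and noise level ~0.004.
    """

    n_loci: int = 111
    n_biallelic: int = 89
    n_multiallelic: int = 22
    allele_count_range: tuple[int, int] = (2, 4)
    n_individuals: int = 187
    mean_depth: float = 5000.0
    depth_dispersion: float = 10.0
    allele_imbalance_sd: float = 0.186
    noise_rate: float = 0.004
    fst: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_biallelic + self.n_multiallelic != self.n_loci:
            raise ValidationError(
                "n_biallelic + n_multiallelic must equal n_loci "
                f"({self.n_biallelic}+{self.n_multiallelic} != {self.n_loci})"
            )
        lo, hi = self.allele_count_range
        if not (2 <= lo <= hi <= len(ALLELE_SYMBOLS)):
            raise ValidationError(
                f"allele_count_range {self.allele_count_range} outside "
                f"(2..{len(ALLELE_SYMBOLS)})"
            )
        if not 0 <= self.noise_rate < 1:
            raise ValidationError("noise_rate must be in [0, 1)")
        if not 0 <= self.fst < 1:
            raise ValidationError("fst must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValidationError("depth_dispersion must be positive")
        if self.allele_imbalance_sd < 0:
            raise ValidationError("allele_imbalance_sd must be non-negative")


@dataclass
class RelatedPairs:
    """Paired genotype matrices with the latent per-locus IBD states."""

    a: GenotypeMatrix
    b: GenotypeMatrix
    ibd_states: np.ndarray = field(repr=False)  # (n_pairs, n_loci) in {0,1,2}


def _rng(seed_seq: np.random.SeedSequence | int) -> np.random.Generator:
    return np.random.default_rng(seed_seq)


def gen_locus_frequencies(config: SimulationConfig) -> FrequencyPanel:
    """Draw a marker panel satisfying the forensic screening frequency rules.

    Bi-allelic loci get a major-allele frequency uniform on [0.4, 0.6];
    multi-allelic loci draw symmetric Dirichlet(2) spectra, rejected until
    every allele frequency is at least 0.01.  Loci are spread over the 22
    autosomes with at least 10 Mb between neighbours on a chromosome.
    """
    per_chrom = int(np.ceil(config.n_loci / N_AUTOSOMES))
    capacity = (CHROM_LENGTH - 1) // (MIN_SPACING + 1) + 1
    if per_chrom > capacity:
        raise SizingError(
            f"{config.n_loci} loci cannot be placed on {N_AUTOSOMES} "
            f"chromosomes of {CHROM_LENGTH} bp at {MIN_SPACING} bp spacing"
        )
    ss = np.random.SeedSequence([config.seed, 0x66726571])
    rng = _rng(ss)

    lo, hi = config.allele_count_range
    multi_lo = max(3, lo)
    n_alleles = np.concatenate(
        [
            np.full(config.n_biallelic, 2, dtype=int),
            rng.integers(multi_lo, hi + 1, size=config.n_multiallelic)
            if config.n_multiallelic
            else np.empty(0, dtype=int),
        ]
    )
    rng.shuffle(n_alleles)

    # chromosome assignment round-robin, then per-chromosome positions with
    # gaps strictly greater than the minimum spacing
    chroms = [str(i % N_AUTOSOMES + 1) for i in range(config.n_loci)]
    positions = np.zeros(config.n_loci, dtype=np.int64)
    for c in range(1, N_AUTOSOMES + 1):
        idx = [i for i, ch in enumerate(chroms) if ch == str(c)]
        k = len(idx)
        if k == 0:
            continue
        slack = CHROM_LENGTH - 1 - (k - 1) * (MIN_SPACING + 1)
        offsets = np.sort(rng.uniform(0, slack, size=k)).astype(np.int64)
        for rank, i in enumerate(idx):
            positions[i] = 1 + offsets[rank] + rank * (MIN_SPACING + 1)

    loci: list[Locus] = []
    for i in range(config.n_loci):
        k = int(n_alleles[i])
        if k == 2:
            p = rng.uniform(0.4, 0.6)
            freqs = np.array([p, 1.0 - p])
        else:
            while True:
                freqs = rng.dirichlet(np.full(k, 2.0))
                if freqs.min() >= 0.01:
                    break
        freqs = freqs / freqs.sum()
        loci.append(
            Locus(
                id=f"sim{i + 1:04d}",
                chrom=chroms[i],
                pos=int(positions[i]),
                alleles=ALLELE_SYMBOLS[:k],
                freqs=freqs,
            )
        )
    return FrequencyPanel(loci).sorted_by_position()


def gen_genotypes(
    panel: FrequencyPanel,
    n: int,
    seed: int,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Draw *n* diploid individuals under Hardy–Weinberg equilibrium.

    Each genotype is two independent draws from the locus frequency vector;
    no missing data are produced.
    """
    if len(panel) == 0:
        raise ValidationError("empty panel")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(np.random.SeedSequence([seed, 0x67656E6F]))
    calls = np.empty((n, len(panel), 2), dtype=np.int16)
    for j, locus in enumerate(panel):
        calls[:, j, :] = rng.choice(
            locus.n_alleles, size=(n, 2), p=locus.freqs
        )
    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples, panel, calls)


def gen_related_pairs(
    panel: FrequencyPanel,
    model,
    n_pairs: int,
    seed: int,
) -> RelatedPairs:
    """Simulate genotype pairs under an IBD-coefficient relationship model.

    Per pair and locus an IBD state is drawn from (k0, k1, k2); shared
    alleles are copied from the first individual (a uniformly chosen allele
    for state 1) and the remaining alleles are independent draws from the
    population frequencies.
    """
    k = np.array([model.k0, model.k1, model.k2], dtype=float)
    if np.any(k < 0) or abs(k.sum() - 1.0) > 1e-9:
        raise ValidationError(f"invalid IBD coefficients {tuple(k)}")
    k = k / k.sum()
    rng = _rng(np.random.SeedSequence([seed, 0x70616972]))
    L = len(panel)
    states = rng.choice(3, size=(n_pairs, L), p=k)
    calls_a = np.empty((n_pairs, L, 2), dtype=np.int16)
    calls_b = np.empty((n_pairs, L, 2), dtype=np.int16)
    for j, locus in enumerate(panel):
        a = rng.choice(locus.n_alleles, size=(n_pairs, 2), p=locus.freqs)
        b = rng.choice(locus.n_alleles, size=(n_pairs, 2), p=locus.freqs)
        st = states[:, j]
        # state 1: one allele of b replaced by a random allele of a
        share_from = rng.integers(0, 2, size=n_pairs)
        ibd1 = st == 1
        b[ibd1, 0] = a[ibd1, share_from[ibd1]]
        # state 2: whole genotype copied
        b[st == 2] = a[st == 2]
        calls_a[:, j, :] = a
        calls_b[:, j, :] = b
    names_a = [f"P{i + 1:05d}a" for i in range(n_pairs)]
    names_b = [f"P{i + 1:05d}b" for i in range(n_pairs)]
    return RelatedPairs(
        GenotypeMatrix(names_a, panel, calls_a),
        GenotypeMatrix(names_b, panel, calls_b),
        states,
    )


def gen_subpopulations(
    panel: FrequencyPanel,
    fst: float,
    n_pops: int,
    n_per_pop: int,
    seed: int,
) -> list[GenotypeMatrix]:
    """Simulate structured populations under the Balding–Nichols model.

    Per population and locus, allele frequencies are Dirichlet-drawn with
    parameters ``p_a (1-F)/F`` around the ancestral vector ``p`` (the Beta
    special case for bi-allelic loci), then genotypes are drawn under HWE.
    ``fst=0`` copies the ancestral frequencies exactly.
    """
    if not 0 <= fst < 1:
        raise ValidationError("fst must be in [0, 1)")
    ss = np.random.SeedSequence([seed, 0x73756270])
    child_seeds = ss.spawn(n_pops)
    pops = []
    for p_idx in range(n_pops):
        rng = _rng(child_seeds[p_idx])
        loci = []
        for locus in panel:
            if fst == 0:
                freqs = locus.freqs.copy()
            else:
                alpha = locus.freqs * (1.0 - fst) / fst
                freqs = rng.dirichlet(np.maximum(alpha, 1e-9))
                freqs = freqs / freqs.sum()
            loci.append(
                Locus(locus.id, locus.chrom, locus.pos, locus.alleles, freqs)
            )
        pop_panel = FrequencyPanel(loci)
        gm = gen_genotypes(
            pop_panel,
            n_per_pop,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_prefix=f"pop{p_idx + 1}_",
        )
        # report genotypes against the ancestral panel (shared allele lists)
        pops.append(GenotypeMatrix(gm.samples, panel, gm.calls))
    return pops


def gen_read_counts(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> ReadCountTable:
    """Simulate per-allele amplicon read counts for every call.

    Total depth per call is negative binomial with the configured mean and
    dispersion; heterozygote reads split by a binomial whose proportion is
    logistic(Normal(0, allele_imbalance_sd)); each read is independently
    misassigned with probability ``noise_rate`` to a uniformly chosen
    non-genotype allele of the locus or to the off-target bucket ``*``.
    """
    rng = _rng(np.random.SeedSequence([config.seed, 0x72656164]))
    n, L = genotypes.n_samples, genotypes.n_loci
    r = config.depth_dispersion
    p_nb = r / (r + config.mean_depth)

    frames = []
    for j, locus in enumerate(genotypes.panel):
        k = locus.n_alleles
        col = genotypes.calls[:, j, :]
        missing = np.any(col == -1, axis=1)
        depth = rng.negative_binomial(r, p_nb, size=n)
        het = (col[:, 0] != col[:, 1]) & ~missing

        # source reads per panel allele, before noise
        reads = np.zeros((n, k + 1), dtype=np.int64)  # last column: off-target
        imbalance = rng.normal(0.0, config.allele_imbalance_sd, size=n)
        pi = 1.0 / (1.0 + np.exp(-imbalance))
        first = np.where(het, rng.binomial(depth, pi), depth)
        rows = np.arange(n)
        a0 = np.where(missing, 0, col[:, 0])
        a1 = np.where(missing, 0, col[:, 1])
        np.add.at(reads, (rows[~missing], a0[~missing]), first[~missing])
        np.add.at(
            reads,
            (rows[het], a1[het]),
            (depth - first)[het],
        )

        if config.noise_rate > 0:
            # misassign a binomial share of each source allele's reads
            noise = rng.binomial(reads[:, :k], config.noise_rate)
            reads[:, :k] -= noise
            total_noise = noise.sum(axis=1)
            # targets: non-genotype panel alleles plus the off-target bucket
            allowed = np.ones((n, k + 1), dtype=bool)
            allowed[rows, a0] = False
            allowed[rows, a1] = False
            allowed[missing, :] = False
            allowed[:, k] = ~missing
            pvals = allowed / np.maximum(
                allowed.sum(axis=1, keepdims=True), 1
            )
            reads += rng.multinomial(total_noise, pvals)

        reads[missing, :] = 0
        frames.append(
            pd.DataFrame(
                {
                    "sample": np.repeat(genotypes.samples, k + 1),
                    "locus": locus.id,
                    "allele": np.tile(
                        list(locus.alleles) + [OFFTARGET], n
                    ),
                    "reads": reads.reshape(-1),
                }
            )
        )
    return ReadCountTable(pd.concat(frames, ignore_index=True))
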