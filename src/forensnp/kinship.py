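"""IBD-coefficient kinship likelihood-ratio engine.

A pairwise relationship is summarised by the prior probabilities
(k0, k1, k2) that the pair shares 0, 1 or 2 alleles identical by descent at
an autosomal locus (unrelated: (1,0,0); half siblings: (0.5,0.5,0); full
siblings: (0.25,0.5,0.25)).  The joint probability of an unordered genotype
pair is

    P(g1) * [ k0 P(g2) + k1 P(g2 | 1 IBD allele with g1) + k2 1(g2 == g1) ]

with the one-IBD-allele transition summing over which allele of g1 is
shared (each with weight 1/2 for heterozygotes).  Likelihood ratios of two
relationship hypotheses multiply over independent loci; log10 LR is
additive.  No mutation, silent alleles or coancestry correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import simulate
from .types import FrequencyPanel, ValidationError


@dataclass(frozen=True)
class KinshipModel:
    """Relationship hypothesis as IBD-state priors (k0, k1, k2)."""

    label: str
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        k = (self.k0, self.k1, self.k2)
        if any(x < 0 for x in k) or abs(sum(k) - 1.0) > 1e-9:
            raise ValidationError(f"invalid IBD coefficients {k}")


UNRELATED = KinshipModel("unrelated", 1.0, 0.0, 0.0)
HALF_SIBLING = KinshipModel("half-sibling", 0.5, 0.5, 0.0)
FULL_SIBLING = KinshipModel("full-sibling", 0.25, 0.5, 0.25)

MODELS = {m.label: m for m in (UNRELATED, HALF_SIBLING, FULL_SIBLING)}


def _genotype_prob(g: tuple[int, int], freqs: np.ndarray) -> float:
    a, b = g
    if a == b:
        return float(freqs[a] ** 2)
    return float(2.0 * freqs[a] * freqs[b])


def _ibd1_conditional(g1: tuple[int, int], g2: tuple[int, int], freqs: np.ndarray) -> float:
    """P(g2 | g1, exactly one allele IBD), unordered genotypes."""
    total = 0.0
    for shared in g1:
        # weight 1/2 for the choice of which g1 allele is transmitted IBD
        if g2[0] == g2[1]:
            p = freqs[g2[0]] if shared == g2[0] else 0.0
        else:
            if shared == g2[0]:
                p = float(freqs[g2[1]])
            elif shared == g2[1]:
                p = float(freqs[g2[0]])
            else:
                p = 0.0
        total += 0.5 * p
    return total


def pair_likelihood(
    g1: tuple[int, int],
    g2: tuple[int, int],
    freqs: np.ndarray,
    model: KinshipModel,
) -> float:
    """Joint probability of an unordered genotype pair under the model."""
    freqs = np.asarray(freqs, dtype=float)
    for g in (g1, g2):
        for a in g:
            if not 0 <= a < freqs.size:
                raise ValidationError(f"allele index {a} outside frequency vector")
            if freqs[a] == 0:
                raise ValidationError(f"allele index {a} has zero frequency")
    g1 = tuple(sorted(g1))
    g2 = tuple(sorted(g2))
    cond = (
        model.k0 * _genotype_prob(g2, freqs)
        + model.k1 * _ibd1_conditional(g1, g2, freqs)
        + model.k2 * (1.0 if g1 == g2 else 0.0)
    )
    return _genotype_prob(g1, freqs) * cond


def lr(
    g1: tuple[int, int],
    g2: tuple[int, int],
    freqs: np.ndarray,
    numerator: KinshipModel,
    denominator: KinshipModel,
) -> float:
    """Single-locus likelihood ratio of two relationship hypotheses."""
    num = pair_likelihood(g1, g2, freqs, numerator)
    den = pair_likelihood(g1, g2, freqs, denominator)
    if den == 0.0:
        return np.inf
    return num / den


def _panel_log10_lr(
    pairs: simulate.RelatedPairs,
    panel: FrequencyPanel,
    numerator: KinshipModel,
    denominator: KinshipModel,
) -> np.ndarray:
    """Vectorised multi-locus log10 LR for every simulated pair."""
    n_pairs = pairs.a.n_samples
    total = np.zeros(n_pairs)
    for j, locus in enumerate(panel):
        f = locus.freqs
        a = pairs.a.calls[:, j, :]
        b = pairs.b.calls[:, j, :]
        pb0, pb1 = f[b[:, 0]], f[b[:, 1]]
        het_b = b[:, 0] != b[:, 1]
        p_g2 = np.where(het_b, 2 * pb0 * pb1, pb0 * pb1)
        same = (a[:, 0] == b[:, 0]) & (a[:, 1] == b[:, 1])
        # IBD1 transition: sum over the shared allele of a
        cond1 = np.zeros(n_pairs)
        for s_col in (0, 1):
            s = a[:, s_col]
            term = np.where(
                het_b,
                np.where(
                    s == b[:, 0],
                    pb1,
                    np.where(s == b[:, 1], pb0, 0.0),
                ),
                np.where(s == b[:, 0], pb0, 0.0),
            )
            cond1 += 0.5 * term
        ratio_terms = []
        for model in (numerator, denominator):
            cond = model.k0 * p_g2 + model.k1 * cond1 + model.k2 * same
            ratio_terms.append(cond)
        with np.errstate(divide="ignore"):
            total += np.log10(ratio_terms[0]) - np.log10(ratio_terms[1])
    return total


@dataclass
class LRSimulationResult:
    """Log10 LR samples for related and unrelated pairs plus their overlap."""

    log10_lr_related: np.ndarray = field(repr=False)
    log10_lr_unrelated: np.ndarray = field(repr=False)
    n_pairs: int = 0
    seed: int = 0

    @property
    def overlap(self) -> float:
        """Decision-threshold overlap at LR = 1: the mean of the related
        fraction with log10 LR <= 0 and the unrelated fraction >= 0."""
        rel = float(np.mean(self.log10_lr_related <= 0.0))
        unrel = float(np.mean(self.log10_lr_unrelated >= 0.0))
        return 0.5 * (rel + unrel)


def simulate_lr_distributions(
    panel: FrequencyPanel,
    true_model: KinshipModel,
    test_model: KinshipModel,
    n_pairs: int,
    seed: int,
) -> LRSimulationResult:
    """Simulate log10 LR distributions for related and unrelated pairs.

    Pairs are generated under ``true_model`` and under the unrelated model;
    both sets are scored with the LR of ``test_model`` against unrelated.
    """
    if n_pairs < 100:
        raise ValidationError("n_pairs must be >= 100")
    related = simulate.gen_related_pairs(panel, true_model, n_pairs, seed)
    unrelated = simulate.gen_related_pairs(panel, UNRELATED, n_pairs, seed + 1)
    lr_rel = _panel_log10_lr(related, panel, test_model, UNRELATED)
    lr_unrel = _panel_log10_lr(unrelated, panel, test_model, UNRELATED)
    return LRSimulationResult(lr_rel, lr_unrel, n_pairs, seed)
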