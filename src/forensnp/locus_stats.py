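"""Per-locus forensic and population-genetic statistics.

Implements the per-marker quantities a forensic panel evaluation reports —
allele frequencies, observed and unbiased expected heterozygosity,
polymorphism information content, match probability / power of
discrimination, power of exclusion — together with Hardy–Weinberg and
genotypic linkage-(dis)equilibrium exact tests:

* HWE, bi-allelic: full enumeration of the conditional distribution of
  genotype tables given the allele counts (Levene/Haldane), two-sided by
  probability ordering with ties included in the rejection set.
* HWE, multi-allelic: Monte-Carlo version of the same test obtained by
  shuffling the observed gene-copy vector and re-pairing it into diploid
  genotypes, with the (x+1)/(N+1) estimator.
* LD: genotypic log-likelihood-ratio (G) statistic on the two-locus
  genotype contingency table, null distribution by permutation of one
  locus's genotype column.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import GenotypeMatrix, ValidationError

LOG2 = np.log(2.0)
_TIE_TOL = 1e-9  # log-probability tie tolerance for the rejection set


class UndefinedStatisticError(ValidationError):
    """A statistic was requested for data that cannot define it."""


@dataclass
class LocusForensicStats:
    """Forensic summary of one marker in one population sample."""

    locus: str
    n_typed: int
    ho: float
    he: float
    pic: float
    pm: float
    pd: float
    pe: float
    hwe_p: float
    maf: float


def round_report(x: float, ndigits: int = 4) -> float:
    """Half-up rounding used for report tables (4 decimals by default)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def _check_calls(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    if calls.ndim != 2 or calls.shape[1] != 2:
        raise ValidationError("calls must have shape (n, 2)")
    calls = calls[~np.any(calls < 0, axis=1)]
    if calls.shape[0] == 0:
        raise UndefinedStatisticError("no non-missing calls at locus")
    return calls


def allele_frequencies(calls: np.ndarray, n_alleles: int | None = None) -> np.ndarray:
    """Sample allele frequencies over the 2n gene copies of non-missing calls."""
    calls = _check_calls(calls)
    if n_alleles is None:
        n_alleles = int(calls.max()) + 1
    counts = np.bincount(calls.reshape(-1), minlength=n_alleles)
    return counts / counts.sum()


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Fraction of typed individuals carrying two different alleles."""
    calls = _check_calls(calls)
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def expected_heterozygosity_unbiased(freqs: np.ndarray, n_typed: int) -> float:
    """Nei's unbiased gene diversity, He = 2n/(2n-1) * (1 - sum p_i^2)."""
    if n_typed < 2:
        raise UndefinedStatisticError("He requires at least 2 typed individuals")
    freqs = np.asarray(freqs, dtype=float)
    return float(2 * n_typed / (2 * n_typed - 1) * (1.0 - np.sum(freqs**2)))


def pic(freqs: np.ndarray) -> float:
    """Polymorphism information content (Botstein):
    1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(freqs, dtype=float)
    sq = p**2
    cross = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - 2.0 * cross)


def genotype_counts(calls: np.ndarray) -> dict[tuple[int, int], int]:
    """Counts of each observed unordered genotype class."""
    calls = _check_calls(calls)
    lo = np.minimum(calls[:, 0], calls[:, 1])
    hi = np.maximum(calls[:, 0], calls[:, 1])
    out: dict[tuple[int, int], int] = {}
    for a, b in zip(lo.tolist(), hi.tolist()):
        out[(a, b)] = out.get((a, b), 0) + 1
    return out


def match_probability(calls: np.ndarray) -> float:
    """PM = sum over observed genotype classes of (class frequency)^2."""
    counts = genotype_counts(calls)
    n = sum(counts.values())
    return float(sum((c / n) ** 2 for c in counts.values()))


def power_of_discrimination(pm: float) -> float:
    """PD = 1 - PM."""
    return 1.0 - pm


def power_of_exclusion(ho: float) -> float:
    """Single-parent power of exclusion, PE = h^2 (1 - 2 h (1-h)^2)."""
    if not 0 <= ho <= 1:
        raise ValidationError("Ho must lie in [0, 1]")
    return float(ho**2 * (1.0 - 2.0 * ho * (1.0 - ho) ** 2))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests


def _biallelic_log_probs(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of all genotype tables given allele counts (nA, nB).

    Returns (het_counts, log_probs) over every heterozygote count compatible
    with the allele counts (same parity as nA, non-negative homozygotes).
    """
    n = (n_a + n_b) // 2
    h = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    naa = (n_a - h) // 2
    nbb = (n_b - h) // 2
    lp = (
        gammaln(n + 1)
        - gammaln(naa + 1)
        - gammaln(h + 1)
        - gammaln(nbb + 1)
        + h * LOG2
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    return h, lp


def hwe_exact_biallelic(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Exact HWE p-value for a bi-allelic locus by full enumeration.

    Conditions on the allele counts; two-sided p is the total probability of
    tables no more probable than the observed one (ties included).
    """
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    h, lp = _biallelic_log_probs(n_a, n_b)
    lp_obs = lp[np.searchsorted(h, n_het)]
    probs = np.exp(lp)
    p = float(probs[lp <= lp_obs + _TIE_TOL].sum())
    return min(p, 1.0)


def _mc_hwe_biallelic(
    n_het: int, n_a: int, n_b: int, mc_reps: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo twin of the bi-allelic enumeration (used for cross-checks)."""
    h_all, lp_all = _biallelic_log_probs(n_a, n_b)
    lp_obs = lp_all[np.searchsorted(h_all, n_het)]
    n = (n_a + n_b) // 2
    copies = np.concatenate([np.zeros(n_a, np.int8), np.ones(n_b, np.int8)])
    order = np.argsort(rng.random((mc_reps, 2 * n)), axis=1)
    shuffled = copies[order]
    h_rep = np.sum(shuffled[:, ::2] != shuffled[:, 1::2], axis=1)
    lp_rep = lp_all[np.searchsorted(h_all, h_rep)]
    hits = int(np.sum(lp_rep <= lp_obs + _TIE_TOL))
    return (hits + 1) / (mc_reps + 1)


def _table_log_stat(counts: np.ndarray, k: int, lgamma_tab: np.ndarray) -> float:
    """Table-ordering statistic: h*log2 - sum log(n_g!) (constants dropped)."""
    het = 0
    s = 0.0
    for a in range(k):
        for b in range(a, k):
            c = counts[a * k + b]
            if c:
                s -= lgamma_tab[c]
                if a != b:
                    het += c
    return s + het * LOG2


def hwe_exact_test(
    calls: np.ndarray,
    mc_reps: int = 100_000,
    seed: int = 0,
    force_mc: bool = False,
) -> float:
    """HWE exact test p-value for one locus.

    Bi-allelic loci are tested by full enumeration; loci with three or more
    alleles by Monte-Carlo re-pairing of the gene-copy vector with
    ``(hits + 1)/(mc_reps + 1)``.  Monomorphic loci return 1.0.
    """
    calls = _check_calls(calls)
    copies = calls.reshape(-1)
    alleles, copies = np.unique(copies, return_inverse=True)
    k = alleles.size
    if k < 2:
        return 1.0
    if k == 2 and not force_mc:
        pairs = copies.reshape(-1, 2)
        n_het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
        n_b = int(np.sum(copies == 1))
        n_hom_b = (n_b - n_het) // 2
        n_hom_a = pairs.shape[0] - n_het - n_hom_b
        return hwe_exact_biallelic(n_het, n_hom_a, n_hom_b)
    if mc_reps < 1000:
        raise ValidationError("mc_reps must be >= 1000 for the Monte-Carlo test")
    rng = np.random.default_rng(seed)
    if k == 2:
        pairs = copies.reshape(-1, 2)
        n_het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
        n_b = int(np.sum(copies == 1))
        n_a = copies.size - n_b
        return _mc_hwe_biallelic(n_het, n_a, n_b, mc_reps, rng)

    n = copies.size // 2
    lgamma_tab = gammaln(np.arange(n + 2))
    pairs = np.sort(copies.reshape(-1, 2), axis=1)
    obs_codes = pairs[:, 0] * k + pairs[:, 1]
    obs_counts = np.bincount(obs_codes, minlength=k * k)
    stat_obs = _table_log_stat(obs_counts, k, lgamma_tab)

    hits = 0
    batch = 2000
    done = 0
    while done < mc_reps:
        b = min(batch, mc_reps - done)
        order = np.argsort(rng.random((b, 2 * n)), axis=1)
        shuffled = copies[order]
        g1 = shuffled[:, ::2]
        g2 = shuffled[:, 1::2]
        lo = np.minimum(g1, g2)
        hi = np.maximum(g1, g2)
        codes = lo * k + hi
        for row in codes:
            counts = np.bincount(row, minlength=k * k)
            if _table_log_stat(counts, k, lgamma_tab) <= stat_obs + _TIE_TOL:
                hits += 1
        done += b
    return (hits + 1) / (mc_reps + 1)


# ---------------------------------------------------------------------------
# Genotypic linkage-disequilibrium permutation test


def _g_statistic(joint: np.ndarray, m1: int, m2: int) -> float:
    table = joint.reshape(m1, m2)
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / n
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_exact_test(
    calls1: np.ndarray,
    calls2: np.ndarray,
    mc_reps: int = 10_000,
    seed: int = 0,
    early_stop_hits: int | None = None,
) -> float:
    """Genotypic LD permutation test between two loci.

    Uses the log-likelihood-ratio (G) statistic on the two-locus genotype
    contingency table; the null distribution comes from permuting one
    locus's genotype column across individuals typed at both loci.

    ``early_stop_hits`` stops permuting once that many null statistics have
    reached the observed one; the returned (x+1)/(N+1) estimate then lower-
    bounds the full-run p-value, which is exact for screening against
    thresholds below (early_stop_hits+1)/(mc_reps+1).
    """
    calls1 = np.asarray(calls1)
    calls2 = np.asarray(calls2)
    ok = ~(np.any(calls1 < 0, axis=1) | np.any(calls2 < 0, axis=1))
    calls1, calls2 = calls1[ok], calls2[ok]
    if calls1.shape[0] < 2:
        raise UndefinedStatisticError("need >= 2 individuals typed at both loci")

    def codes(c: np.ndarray) -> np.ndarray:
        lo = np.minimum(c[:, 0], c[:, 1])
        hi = np.maximum(c[:, 0], c[:, 1])
        _, inv = np.unique(lo * 1000 + hi, return_inverse=True)
        return inv

    g1, g2 = codes(calls1), codes(calls2)
    m1, m2 = g1.max() + 1, g2.max() + 1
    if m1 < 2 or m2 < 2:
        warnings.warn("monomorphic locus in LD test; p = 1.0", stacklevel=2)
        return 1.0
    joint = np.bincount(g1 * m2 + g2, minlength=m1 * m2)
    stat_obs = _g_statistic(joint, m1, m2)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    for done in range(1, mc_reps + 1):
        perm = rng.permutation(g2)
        joint = np.bincount(g1 * m2 + perm, minlength=m1 * m2)
        if _g_statistic(joint, m1, m2) >= stat_obs - _TIE_TOL:
            hits += 1
            if early_stop_hits is not None and hits >= early_stop_hits:
                break
    return (hits + 1) / (done + 1)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Per-panel driver


def compute_locus_stats(
    gm: GenotypeMatrix,
    hwe_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """All per-locus forensic statistics for a genotype matrix.

    Returns one row per locus with n_typed, Ho, He, PIC, PM, PD, PE, the
    HWE exact-test p-value and the minor-allele frequency.  Per-locus HWE
    Monte-Carlo seeds are derived deterministically from ``seed`` and the
    locus identifier, so results do not depend on panel composition.
    """
    import zlib

    rows = []
    for j, locus in enumerate(gm.panel):
        calls = gm.locus_calls(j)
        n_typed = calls.shape[0]
        freqs = allele_frequencies(calls, locus.n_alleles)
        ho = observed_heterozygosity(calls)
        observed = freqs[freqs > 0]
        monomorphic = observed.size < 2
        he = 0.0 if monomorphic else expected_heterozygosity_unbiased(freqs, n_typed)
        pic_v = 0.0 if monomorphic else pic(freqs)
        pm = match_probability(calls)
        locus_seed = zlib.crc32(locus.id.encode()) ^ (seed & 0x7FFFFFFF)
        hwe_p = hwe_exact_test(calls, mc_reps=hwe_reps, seed=locus_seed)
        rows.append(
            LocusForensicStats(
                locus=locus.id,
                n_typed=n_typed,
                ho=ho,
                he=he,
                pic=pic_v,
                pm=pm,
                pd=power_of_discrimination(pm),
                pe=power_of_exclusion(ho),
                hwe_p=hwe_p,
                maf=float(observed.min()) if observed.size > 1 else 0.0,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
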