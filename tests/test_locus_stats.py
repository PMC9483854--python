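"""Forensic parameters and HWE/LD exact tests against independent oracles."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as st

from forensnp import locus_stats as ls
from forensnp import simulate
from forensnp.types import FrequencyPanel, Locus, ValidationError

from conftest import make_biallelic_panel


def hwe_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> Fraction:
    """Exact-rational HWE p-value by brute enumeration of genotype tables.

    Enumerates every table compatible with the observed allele counts and
    sums the conditional probabilities (Levene) of tables no more probable
    than the observed one.  Entirely independent of the log-gamma
    implementation path.
    """
    from math import factorial

    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het

    def prob(h: int) -> Fraction:
        aa, bb = (n_a - h) // 2, (n_b - h) // 2
        num = Fraction(
            factorial(n) * 2**h * factorial(n_a) * factorial(n_b),
            factorial(aa) * factorial(h) * factorial(bb) * factorial(2 * n),
        )
        return num

    hs = [h for h in range(n_a % 2, min(n_a, n_b) + 1, 2)]
    p_obs = prob(n_het)
    return sum(prob(h) for h in hs if prob(h) <= p_obs)


class TestAlleleFrequencies:
    def test_simple_counts(self):
        calls = np.array([[0, 0], [0, 1], [1, 1]])
        np.testing.assert_allclose(ls.allele_frequencies(calls), [0.5, 0.5])

    def test_printed_frequency_from_copy_counts(self):
        # 110 copies of the minor allele among 187 diploids: 110/374
        calls = np.array([[0, 1]] * 110 + [[0, 0]] * 77)
        f = ls.allele_frequencies(calls)
        assert ls.round_report(f[1]) == 0.2941

    def test_reordering_invariance(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(50, 2))
        perm = rng.permutation(50)
        np.testing.assert_array_equal(
            ls.allele_frequencies(calls, 3), ls.allele_frequencies(calls[perm], 3)
        )

    def test_all_missing_rejected(self):
        with pytest.raises(ls.UndefinedStatisticError):
            ls.allele_frequencies(np.full((4, 2), -1))


class TestHeterozygosityAndPic:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            (np.array([[0, 0], [1, 1]]), 0.0),
            (np.array([[0, 1], [0, 1]]), 1.0),
            (np.array([[0, 1]] * 75 + [[0, 0]] * 112), 75 / 187),
        ],
    )
    def test_observed_heterozygosity(self, calls, expected):
        assert ls.observed_heterozygosity(calls) == pytest.approx(expected)

    def test_minimum_printed_ho_rounds_to_4011(self):
        calls = np.array([[0, 1]] * 75 + [[0, 0]] * 112)
        assert ls.round_report(ls.observed_heterozygosity(calls)) == 0.4011

    def test_unbiased_he_direct_formula(self):
        assert ls.expected_heterozygosity_unbiased([0.5, 0.5], 100) == pytest.approx(
            200 / 199 * 0.5
        )

    def test_he_monomorphic_zero(self):
        assert ls.expected_heterozygosity_unbiased([1.0], 50) == 0.0

    def test_he_at_printed_study_frequency(self):
        p = 110 / 374
        he = ls.expected_heterozygosity_unbiased([p, 1 - p], 187)
        assert ls.round_report(he) == 0.4163

    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([0.5, 0.5], 0.375),
            ([0.25, 0.25, 0.25, 0.25], 0.703125),
        ],
    )
    def test_pic_hand_values(self, freqs, expected):
        assert ls.pic(freqs) == pytest.approx(expected)

    def test_pic_at_printed_study_frequency(self):
        p = 110 / 374
        assert ls.round_report(ls.pic([p, 1 - p])) == 0.3290

    def test_biallelic_ordering_pic_below_gene_diversity_below_he(self):
        for p in (0.3, 0.5, 0.45):
            d = 2 * p * (1 - p)
            assert ls.pic([p, 1 - p]) < d < ls.expected_heterozygosity_unbiased(
                [p, 1 - p], 100
            )


class TestMatchAndExclusion:
    def test_pm_pd_from_genotype_classes(self):
        calls = np.array([[0, 0]] * 40 + [[0, 1]] * 40 + [[1, 1]] * 20)
        pm = ls.match_probability(calls)
        assert pm == pytest.approx(0.36)
        assert ls.power_of_discrimination(pm) == pytest.approx(0.64)

    def test_single_class_pm_one(self):
        assert ls.match_probability(np.array([[0, 1]] * 9)) == 1.0

    def test_pd_pm_identity(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, size=(187, 2))
        pm = ls.match_probability(calls)
        assert pm + ls.power_of_discrimination(pm) == 1.0

    @pytest.mark.parametrize(
        "h, expected",
        [(0.0, 0.0), (1.0, 1.0), (0.5, 0.1875), (0.4011, 0.1146), (0.7005, 0.4290)],
    )
    def test_pe_formula(self, h, expected):
        assert ls.round_report(ls.power_of_exclusion(h)) == pytest.approx(expected)


class TestHweExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((1, 0, 1), 1 / 3),  # tables given 2+2 copies: P(h=0)=1/3, P(h=2)=2/3
            ((0, 2, 0), 1.0),
            ((5, 0, 0), 1.0),  # monomorphic
        ],
    )
    def test_small_tables_by_hand(self, table, expected):
        aa, het, bb = table
        assert ls.hwe_exact_biallelic(het, aa, bb) == pytest.approx(expected)

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            het = int(rng.integers(0, n + 1))
            aa = int(rng.integers(0, n - het + 1))
            bb = n - het - aa
            got = ls.hwe_exact_biallelic(het, aa, bb)
            want = float(hwe_oracle(aa, het, bb))
            assert got == pytest.approx(want, abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self):
        calls = np.array([[0, 0]] * 30 + [[0, 1]] * 40 + [[1, 1]] * 30)
        exact = ls.hwe_exact_test(calls)
        mc = ls.hwe_exact_test(calls, mc_reps=100_000, seed=3, force_mc=True)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_multiallelic_mc_reps_floor(self):
        calls = np.array([[0, 1], [1, 2], [0, 2], [2, 2]])
        with pytest.raises(ValidationError):
            ls.hwe_exact_test(calls, mc_reps=500)

    def test_multiallelic_mc_detects_excess_heterozygosity(self):
        calls = np.array([[0, 1], [0, 2], [1, 2]] * 30)  # no homozygotes at all
        p = ls.hwe_exact_test(calls, mc_reps=5000, seed=4)
        assert p < 0.01

    def test_multiallelic_mc_null_is_large_for_hwe_data(self):
        panel = FrequencyPanel(
            [Locus("x", "1", 100, ("A", "C", "G"), np.array([0.5, 0.3, 0.2]))]
        )
        gm = simulate.gen_genotypes(panel, 187, seed=5)
        p = ls.hwe_exact_test(gm.locus_calls(0), mc_reps=5000, seed=6)
        assert p > 0.01


class TestLdExact:
    def test_locus_against_its_copy_is_significant(self):
        panel = make_biallelic_panel(1, seed=6)
        gm = simulate.gen_genotypes(panel, 187, seed=7)
        calls = gm.locus_calls(0)
        p = ls.ld_exact_test(calls, calls, mc_reps=2000, seed=8)
        assert p <= 0.001

    def test_monomorphic_partner_returns_one(self):
        calls1 = np.array([[0, 1]] * 10 + [[0, 0]] * 10)
        calls2 = np.zeros((20, 2), dtype=int)
        with pytest.warns(UserWarning):
            assert ls.ld_exact_test(calls1, calls2) == 1.0

    def test_null_pvalues_approximately_uniform(self):
        panel = make_biallelic_panel(200, seed=9)
        gm = simulate.gen_genotypes(panel, 187, seed=10)
        ps = [
            ls.ld_exact_test(
                gm.locus_calls(2 * i), gm.locus_calls(2 * i + 1),
                mc_reps=400, seed=i,
            )
            for i in range(100)
        ]
        assert st.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 111, 0.05 / 111), (0.05, 6105, 0.05 / 6105), (0.05, 1, 0.05)],
    )
    def test_threshold(self, alpha, m, expected):
        assert ls.bonferroni_threshold(alpha, m) == pytest.approx(expected)


class TestComputeLocusStats:
    def test_table_shape_and_invariants(self, study_cohort):
        df = ls.compute_locus_stats(study_cohort, hwe_reps=2000, seed=1)
        assert len(df) == 111
        assert (df["n_typed"] == 187).all()
        np.testing.assert_allclose(df["pd"] + df["pm"], 1.0)
        assert ((df["pe"] <= df["ho"] ** 2 + 1e-12)).all()
        for col in ("ho", "he", "pic", "pm", "pd", "pe", "hwe_p"):
            assert df[col].between(0, 1).all()

    def test_hwe_conformance_of_simulated_panel(self, study_cohort):
        # on HWE data the expected count of Bonferroni-level failures is ~0
        df = ls.compute_locus_stats(study_cohort, hwe_reps=2000, seed=2)
        thr = ls.bonferroni_threshold(0.05, len(df))
        assert (df["hwe_p"] < thr).sum() == 0
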