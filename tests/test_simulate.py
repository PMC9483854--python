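"""Statistical behaviour of the synthetic-data generator."""

import numpy as np
import pytest
from scipy import stats as st

from forensnp import locus_stats as ls
from forensnp import popcomp, simulate
from forensnp.types import FrequencyPanel, Locus, ValidationError

from conftest import make_biallelic_panel


class TestLocusFrequencies:
    def test_study_panel_structure(self, study_panel):
        assert len(study_panel) == 111
        n_bi = sum(1 for l in study_panel if l.n_alleles == 2)
        assert n_bi == 89
        for locus in study_panel:
            assert abs(locus.freqs.sum() - 1.0) < 1e-12
            if locus.n_alleles == 2:
                assert 0.4 <= locus.freqs.max() <= 0.6
            else:
                assert locus.freqs.min() >= 0.01

    def test_single_locus_normalized(self):
        cfg = simulate.SimulationConfig(
            n_loci=1, n_biallelic=1, n_multiallelic=0, seed=7
        )
        panel = simulate.gen_locus_frequencies(cfg)
        assert len(panel) == 1
        assert abs(panel[0].freqs.sum() - 1.0) < 1e-12

    def test_expected_heterozygosity_of_frequency_prior(self):
        # E[2p(1-p)] for p ~ U[0.4, 0.6] is 0.49333...
        cfg = simulate.SimulationConfig(
            n_loci=550, n_biallelic=550, n_multiallelic=0, seed=3
        )
        vals = []
        for rep in range(19):
            cfg = simulate.SimulationConfig(
                n_loci=550, n_biallelic=550, n_multiallelic=0, seed=rep
            )
            panel = simulate.gen_locus_frequencies(cfg)
            vals.extend(2 * l.freqs[0] * l.freqs[1] for l in panel)
        assert len(vals) >= 10_000
        assert np.mean(vals) == pytest.approx(0.49333, abs=0.01)

    def test_spacing_at_least_10mb_on_shared_chromosomes(self, study_panel):
        by_chrom: dict[str, list[int]] = {}
        for locus in study_panel:
            by_chrom.setdefault(locus.chrom, []).append(locus.pos)
        assert set(by_chrom) == {str(c) for c in range(1, 23)}
        for positions in by_chrom.values():
            positions = sorted(positions)
            gaps = np.diff(positions)
            assert np.all(gaps > simulate.MIN_SPACING)

    def test_impossible_sizing_rejected(self):
        with pytest.raises(simulate.SizingError):
            simulate.gen_locus_frequencies(
                simulate.SimulationConfig(
                    n_loci=2000, n_biallelic=2000, n_multiallelic=0, seed=0
                )
            )

    def test_determinism(self, default_config, study_panel):
        again = simulate.gen_locus_frequencies(default_config)
        assert again.ids == study_panel.ids
        for a, b in zip(again, study_panel):
            assert a.chrom == b.chrom and a.pos == b.pos
            np.testing.assert_array_equal(a.freqs, b.freqs)


class TestGenotypes:
    def test_heterozygote_fraction_at_half(self):
        panel = FrequencyPanel(
            [Locus("x", "1", 100, ("A", "C"), np.array([0.5, 0.5]))]
        )
        gm = simulate.gen_genotypes(panel, 10_000, seed=5)
        assert gm.het_mask().mean() == pytest.approx(0.5, abs=0.015)

    def test_monomorphic_locus_all_homozygous(self):
        panel = FrequencyPanel([Locus("m", "1", 100, ("A",), np.array([1.0]))])
        gm = simulate.gen_genotypes(panel, 50, seed=1)
        assert not gm.het_mask().any()
        assert np.all(gm.calls == 0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            simulate.gen_genotypes(FrequencyPanel([]), 10, seed=0)

    def test_frequency_recovery(self):
        panel = make_biallelic_panel(20, seed=9)
        gm = simulate.gen_genotypes(panel, 100_000, seed=10)
        for j, locus in enumerate(panel):
            est = ls.allele_frequencies(gm.locus_calls(j), locus.n_alleles)
            np.testing.assert_allclose(est, locus.freqs, atol=0.005)

    def test_hwe_exact_pvalues_conservative_but_not_degenerate(self):
        # An exact conditional test has discrete p-value support, so its
        # null p-values stochastically dominate U(0,1): P(p < t) <= t.
        panel = make_biallelic_panel(550, seed=11)
        gm = simulate.gen_genotypes(panel, 187, seed=12)
        ps = np.array(
            [ls.hwe_exact_test(gm.locus_calls(j)) for j in range(len(panel))]
        )
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            # 3-sigma binomial slack on the validity bound
            assert (ps < t).mean() <= t + 3 * np.sqrt(t * (1 - t) / len(ps))
        assert (ps < 0.05).mean() >= 0.005
        assert (ps < 0.9).mean() <= 0.95


class TestRelatedPairs:
    def test_ibd2_everywhere_copies_genotypes(self):
        panel = make_biallelic_panel(5, seed=1)
        model = type("M", (), {"k0": 0.0, "k1": 0.0, "k2": 1.0})
        pairs = simulate.gen_related_pairs(panel, model, 200, seed=2)
        np.testing.assert_array_equal(pairs.a.calls, pairs.b.calls)

    def test_unrelated_pairs_independent(self):
        # genotype-pair table at one locus vs product of margins
        panel = FrequencyPanel(
            [Locus("x", "1", 100, ("A", "C"), np.array([0.5, 0.5]))]
        )
        model = type("M", (), {"k0": 1.0, "k1": 0.0, "k2": 0.0})
        pairs = simulate.gen_related_pairs(panel, model, 10_000, seed=3)
        code = (
            (pairs.a.calls[:, 0, 0] + pairs.a.calls[:, 0, 1]) * 3
            + pairs.b.calls[:, 0, 0]
            + pairs.b.calls[:, 0, 1]
        )
        observed = np.bincount(code, minlength=9).reshape(3, 3)
        marg = np.array([0.25, 0.5, 0.25])
        expected = np.outer(marg, marg) * 10_000
        p = st.chisquare(observed.ravel(), expected.ravel()).pvalue
        assert p > 0.001

    def test_full_sib_both_heterozygous_fraction(self):
        # sum over IBD states at p = q = 0.5: 0.25*0.25 + 0.5*0.25 + 0.25*0.5
        panel = FrequencyPanel(
            [Locus("x", "1", 100, ("A", "C"), np.array([0.5, 0.5]))]
        )
        from forensnp.kinship import FULL_SIBLING

        pairs = simulate.gen_related_pairs(panel, FULL_SIBLING, 10_000, seed=4)
        both_het = pairs.a.het_mask()[:, 0] & pairs.b.het_mask()[:, 0]
        assert both_het.mean() == pytest.approx(0.3125, abs=0.02)

    def test_invalid_k_vector_rejected(self):
        panel = make_biallelic_panel(2, seed=1)
        bad = type("M", (), {"k0": 0.5, "k1": 0.5, "k2": 0.5})
        with pytest.raises(ValidationError):
            simulate.gen_related_pairs(panel, bad, 10, seed=0)

    def test_ibd_state_recovery(self):
        panel = make_biallelic_panel(1, seed=1)
        from forensnp.kinship import FULL_SIBLING

        pairs = simulate.gen_related_pairs(panel, FULL_SIBLING, 100_000, seed=5)
        props = np.bincount(pairs.ibd_states.ravel(), minlength=3) / 100_000
        np.testing.assert_allclose(props, [0.25, 0.5, 0.25], atol=0.01)


class TestSubpopulations:
    def test_fst_zero_copies_ancestral_frequencies(self):
        panel = make_biallelic_panel(10, seed=2)
        pops = simulate.gen_subpopulations(panel, 0.0, 3, 20, seed=6)
        assert len(pops) == 3
        for gm in pops:
            assert gm.panel.ids == panel.ids

    def test_balding_nichols_parameter_recovery(self):
        panel = make_biallelic_panel(500, seed=13)
        pops = simulate.gen_subpopulations(panel, 0.1, 2, 100, seed=14)
        theta = popcomp.pairwise_fst(pops[0], pops[1])
        assert 0.08 <= theta <= 0.12

    def test_high_fst_drives_fixation(self):
        panel = make_biallelic_panel(500, seed=15, freq_range=(0.5, 0.5))
        pops = simulate.gen_subpopulations(panel, 0.9, 2, 50, seed=16)
        hets = [
            np.mean(
                [
                    ls.expected_heterozygosity_unbiased(
                        ls.allele_frequencies(gm.locus_calls(j), 2), gm.n_samples
                    )
                    for j in range(len(panel))
                ]
            )
            for gm in pops
        ]
        assert np.mean(hets) < 0.2


class TestReadCounts:
    def test_clean_run_has_zero_noise_level(self, study_panel):
        cfg = simulate.SimulationConfig(
            noise_rate=0.0, allele_imbalance_sd=0.0, seed=8, n_individuals=30
        )
        gm = simulate.gen_genotypes(study_panel, 30, seed=8)
        counts = simulate.gen_read_counts(gm, cfg)
        from forensnp import qc

        nl = qc.nl_per_locus(counts, gm)
        assert np.allclose(nl["nl_mean"], 0.0)

    def test_mean_depth_recovery(self, study_read_counts):
        totals = study_read_counts.totals()
        assert totals["reads"].mean() == pytest.approx(5000, rel=0.02)

    def test_noise_rate_recovery(self, study_read_counts, study_cohort):
        from forensnp import qc

        nl = qc.nl_per_locus(study_read_counts, study_cohort)
        assert np.average(nl["nl_mean"], weights=nl["n_calls"]) == pytest.approx(
            0.004, abs=0.001
        )

    def test_determinism(self, study_cohort, default_config, study_read_counts):
        again = simulate.gen_read_counts(study_cohort, default_config)
        assert again.table.equals(study_read_counts.table)
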