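import numpy as np
import pytest

from forensnp import simulate
from forensnp.types import FrequencyPanel, Locus


def make_biallelic_panel(n_loci: int, seed: int, freq_range=(0.4, 0.6)) -> FrequencyPanel:
    """Bi-allelic panel with HWE-screening frequencies, spaced >= 10 Mb."""
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        p = rng.uniform(*freq_range)
        loci.append(
            Locus(
                id=f"L{i + 1:04d}",
                chrom=str(i % 22 + 1),
                pos=10_000_001 * (i // 22 + 1) + i,
                alleles=("A", "C"),
                freqs=np.array([p, 1 - p]),
            )
        )
    return FrequencyPanel(loci)


@pytest.fixture(scope="session")
def default_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def study_panel(default_config) -> FrequencyPanel:
    """111-locus panel under the study design (89 bi- + 22 multi-allelic)."""
    return simulate.gen_locus_frequencies(default_config)


@pytest.fixture(scope="session")
def study_cohort(study_panel, default_config):
    """187 HWE individuals typed on the study panel."""
    return simulate.gen_genotypes(study_panel, default_config.n_individuals, seed=7)


@pytest.fixture(scope="session")
def study_read_counts(study_cohort, default_config):
    return simulate.gen_read_counts(study_cohort, default_config)
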