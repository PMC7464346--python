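import pytest

from seropeak import SimulationConfig, generate_cohort_matrix


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-sized cohort: 29 vs 17 sera, 160 peaks of which 110
    discriminative, log2 fold change 2, fixed seed."""
    return generate_cohort_matrix(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast per-module tests."""
    cfg = SimulationConfig(
        n_group1=10, n_group2=8, n_peaks=48, n_discriminative=30, seed=11
    )
    return generate_cohort_matrix(cfg)
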