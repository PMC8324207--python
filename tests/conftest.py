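import numpy as np
import pytest

from crcrisk import CohortConfig, default_panel, simulate_subjects


@pytest.fixture(scope="session")
def panel():
    """24-SNP candidate panel, 5 variants forced out of HWE."""
    return default_panel(n_snps=24, n_out_of_hwe=5, seed=11)


@pytest.fixture(scope="session")
def clean_panel():
    """Panel with every variant at HWE."""
    return default_panel(n_snps=12, n_out_of_hwe=0, seed=12)


@pytest.fixture(scope="session")
def small_cohort(clean_panel):
    """A modest simulated cohort shared by read-only tests."""
    config = CohortConfig(n_subjects=1500, seed=42)
    return simulate_subjects(config, clean_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
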