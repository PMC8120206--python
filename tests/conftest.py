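import pytest

from neoscape import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (15 patients, ~50 mutations/sample) shared by tests
    that only need structural realism, not the full study-scale layout."""
    cfg = SyntheticCohortConfig(
        n_patients=15,
        n_mutations_mean=50,
        n_tcr_clones=60,
        n_background_genes=60,
        seed=11,
    )
    return simulate_cohort(cfg)
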