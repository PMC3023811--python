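import pytest
from hypothesis import HealthCheck, settings

from chprofile import SyntheticConfig, generate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """A 400-gene synthetic study with planted DE, shared across tests."""
    config = SyntheticConfig(
        n_genes=400,
        onset_fractions=(0.05, 0.03, 0.02),
        geneset_spec=((20, 0.8), (60, 0.2)),
        include_mutant=True,
        seed=11,
    )
    study, truth = generate_study(config)
    return config, study, truth
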