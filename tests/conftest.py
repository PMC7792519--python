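import pytest
from hypothesis import HealthCheck, settings

from paralog_epidiv.simulate import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


SMALL_PAIRS = {"WGD": 150, "tandem": 100, "proximal": 50, "transposed": 60}


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        genes_per_chromosome=400,
        n_pairs_by_mode=dict(SMALL_PAIRS),
        seed=20240917,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small but fully featured dataset shared across test modules."""
    return generate_dataset(small_config)
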