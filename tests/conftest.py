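import pytest
from hypothesis import HealthCheck, settings

from lncdissect.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL = dict(
    n_coding_genes=60, n_linc=30, n_antisense=8, n_pseudogene=4, n_small_rna=4,
    trans_pair_count=8, chrom_length=2_500_000,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate_dataset(SimulationConfig(seed=23, noise_sd=0.0, **SMALL))
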