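import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from rarecnv.cnv_data import bundled_sz_loci
from rarecnv.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sz_loci():
    return bundled_sz_loci()


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort shared by read-only tests."""
    cfg = SimConfig(
        n_cases=120,
        n_controls=280,
        background_rate=2.0,
        n_common_cnvs=1,
        common_freq=0.03,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20259)
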