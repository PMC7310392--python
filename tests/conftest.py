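import numpy as np
import pytest

from ordgrowth.model import ModelSpec, build_design
from ordgrowth.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject synthetic cohort under the default generating model."""
    cfg = SimConfig(n_subjects=40, visit_rate=1.0, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    spec = ModelSpec(shared=("time", "on_cart", "log_vl_c", "qol_phys_c"), npo=())
    return build_design(small_cohort, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
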