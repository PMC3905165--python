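import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gateworks import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return syn.BundleSpec()


@pytest.fixture(scope="session")
def occluded_bundle(default_spec):
    return syn.make_bundle(default_spec)


@pytest.fixture(scope="session")
def open_cyt_bundle():
    return syn.make_bundle(syn.BundleSpec(gate_cyt=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
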