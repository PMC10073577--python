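import pytest
from hypothesis import settings

from kampopreg import SimConfig, generate_bundle, run_pipeline

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition bundle with truth (fast, reused)."""
    return generate_bundle(SimConfig(n_mothers=400, seed=11))


@pytest.fixture(scope="session")
def calib_sim():
    """A 10k-mother default bundle for marginal-calibration checks."""
    return generate_bundle(SimConfig(n_mothers=10_000, seed=7))


@pytest.fixture(scope="session")
def calib_result(calib_sim):
    bundle, _ = calib_sim
    return run_pipeline(bundle)
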