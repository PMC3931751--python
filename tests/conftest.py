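import pytest

from cisqpcr.simulate import SimConfig
from cisqpcr.standards import default_catalog, default_esm_mixes


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def esm_mixes():
    return default_esm_mixes()


@pytest.fixture()
def clean_cfg():
    """Default mechanism, all measurement noise off."""
    return SimConfig(cq_noise_sd=0.0, fluor_run_sd=0.0)


@pytest.fixture()
def ideal_cfg():
    """Exact per-cycle doubling with the threshold far below saturation.

    Used for identities that hold only under ideal amplification (e.g. exact
    log2 Cq shifts); the threshold crossing then sits in a purely exponential
    region and log-linear interpolation is exact.
    """
    return SimConfig(
        e0=1.0,
        capacity=1e16,
        threshold_fraction=1e-8,
        cq_noise_sd=0.0,
        fluor_run_sd=0.0,
    )
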