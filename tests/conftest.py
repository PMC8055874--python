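import numpy as np
import pytest

from glioforecast.forward import SimulationSettings
from glioforecast.phantom import PhantomConfig, synthesize_visits


def small_phantom_config(**overrides) -> PhantomConfig:
    """A 32x32x4 virtual patient small enough for per-test simulation."""
    defaults = dict(
        grid_shape=(32, 32, 4),
        grid_spacing=(1.0, 1.0, 5.0),
        brain_semiaxes_mm=(14.0, 14.0, 8.75),
        csf_semiaxes_mm=(4.0, 4.0, 3.0),
        gray_shell_mm=2.0,
        tumor_center_offset_mm=(5.0, 0.0, 0.0),
        enhancing_radius_mm=4.0,
        rim_width_mm=3.0,
        adc_noise_sd=0.0,
        intensity_noise_sd=0.0,
        settings=SimulationSettings(dt=2.0, mechanics_stride=5),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return small_phantom_config()


@pytest.fixture(scope="session")
def small_patient(small_config):
    """Noiseless small dataset plus its generating truth (shared, read-only)."""
    return synthesize_visits(small_config)


@pytest.fixture(scope="session")
def noisy_small_patient():
    return synthesize_visits(small_phantom_config(adc_noise_sd=0.03, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
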