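import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import timewrap as tw

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """8 macro-pixels x 4 lines, instrument delay timing (270 samples/4.5 ps)."""
    return tw.AcquisitionConfig(n_macro_x=8, n_lines_y=4)


@pytest.fixture(scope="session")
def bgo_raw(small_config):
    """Zero-noise, zero-jitter calibration-crystal acquisition."""
    phantom = tw.bgo_phantom(small_config)
    return tw.simulate_acquisition(phantom, small_config)


@pytest.fixture(scope="session")
def bgo_cubes(bgo_raw):
    return tw.reshape_to_cubes(bgo_raw)


@pytest.fixture(scope="session")
def single_pixel_config():
    return tw.AcquisitionConfig(n_macro_x=1, n_lines_y=1)


def single_line_raw(config, center=90.0, t2=100.0, with_spike=True, phase=0.0):
    """One-pixel acquisition of a single vibrational line."""
    phantom = tw.Phantom(
        label_map=np.zeros((config.n_lines_y, config.n_macro_x), dtype=int),
        species_table={0: [tw.VibrationalLine(center, 1.0, t2, phase)]},
    )
    amp = None if with_spike else 0.0
    return tw.simulate_acquisition(phantom, config, overlap_amplitude=amp)


@pytest.fixture(scope="session")
def two_species_small():
    config = tw.AcquisitionConfig(n_macro_x=24, n_lines_y=12)
    phantom = tw.two_species_phantom(config)
    raw = tw.simulate_acquisition(phantom, config)
    hcube = tw.process_acquisition(raw)
    return config, phantom, hcube
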