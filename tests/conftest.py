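import numpy as np
import pytest

from synovaquant.phantom import (
    CompartmentSpec,
    PhantomConfig,
    generate_dce_phantom,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless phantom with a washing-out synovium compartment."""
    compartments = [
        CompartmentSpec(1, "synovium", s0=100.0, arrival_time=19.6,
                        uptake_slope=4.0, peak_time=39.2, late_slope=-0.1),
        CompartmentSpec(2, "artery", s0=100.0, arrival_time=9.8,
                        uptake_slope=12.0, peak_time=29.4, late_slope=-0.6),
        CompartmentSpec(3, "muscle", s0=80.0, arrival_time=19.6,
                        uptake_slope=0.4, peak_time=117.6, late_slope=0.1),
        CompartmentSpec(4, "effusion", s0=120.0),
        CompartmentSpec(5, "background", s0=20.0),
    ]
    config = PhantomConfig(grid_shape=(15, 8, 4), noise_sd=0.0,
                           compartments=compartments)
    signal, labels, truth = generate_dce_phantom(config)
    return config, signal, labels, truth


@pytest.fixture(scope="session")
def study_table():
    from synovaquant.study import load_fixture

    return load_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
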