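import pytest

import gelfront as gf

GRID = (128, 128)


@pytest.fixture(scope="session")
def spec_1h():
    return gf.build_phantom_spec(1.0, "HPMC400", grid_shape=GRID)


@pytest.fixture(scope="session")
def gt_maps_1h(spec_1h):
    return gf.render_parameter_maps(spec_1h)


@pytest.fixture(scope="session")
def spec_half_h():
    return gf.build_phantom_spec(0.5, "HPMC400", grid_shape=GRID)


@pytest.fixture(scope="session")
def gt_maps_half_h(spec_half_h):
    return gf.render_parameter_maps(spec_half_h)


@pytest.fixture(scope="session")
def study_1h_low_noise():
    """Simulated + fitted 1 h phantom at low noise (shared: fitting is the slow part)."""
    return gf.simulate_hydration_study(1.0, "HPMC400", seed=11, grid_shape=(96, 96), sigma=0.1)
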