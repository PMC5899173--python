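import numpy as np
import pytest
from hypothesis import settings

import episcade as ep

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from episcade.cascade import FULL_WINDOW, RESTRICTED_WINDOW


@pytest.fixture(scope="session")
def gauss0():
    return ep.make_rotated_gaussian(ep.GaussianParams(0.0))


@pytest.fixture(scope="session")
def gauss12():
    return ep.make_rotated_gaussian(ep.GaussianParams(np.pi / 12))


@pytest.fixture(scope="session")
def gauss4():
    return ep.make_rotated_gaussian(ep.GaussianParams(np.pi / 4))


@pytest.fixture(scope="session")
def plane_full():
    """Default (K_TetR, K_LacI) response-range landscape, full input window."""
    return ep.default_plane(w=FULL_WINDOW)


@pytest.fixture(scope="session")
def plane_restricted():
    return ep.default_plane(w=RESTRICTED_WINDOW)


@pytest.fixture(scope="session")
def map_full(plane_full):
    return ep.epistasis_map(plane_full, grid=201)


@pytest.fixture(scope="session")
def map_restricted(plane_restricted):
    return ep.epistasis_map(plane_restricted, grid=201)


@pytest.fixture(scope="session")
def small_panel():
    """A 3x3 variant panel with moderate noise, fitted once per session."""
    variants, truth = ep.sample_variant_panel(
        ep.VariantPanelSpec(n_upstream=3, n_downstream=3), seed=7)
    data, curves = ep.simulate_panel_measurements(
        variants, ep.default_cascade(), ep.MeasurementSpec(noise_sigma=0.5, seed=7))
    return dict(variants=variants, truth=truth, data=data, curves=curves)
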