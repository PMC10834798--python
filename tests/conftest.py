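import numpy as np
import pytest

import slamrecon as sr
from slamrecon.acquisition import Protocol, build_aw_scheme, simulate_acquisition
from slamrecon.phantom import build_default_phantom, rasterize_masks


@pytest.fixture(scope="session")
def default_geometry():
    return sr.AcquisitionGeometry()


@pytest.fixture(scope="session")
def clean_phantom():
    """Static, blood-free, unsaturated phantom: exactly compartment-constant."""
    return build_default_phantom(
        motion_amplitude_mm=0.0, blood_fraction=0.0, with_saturation_slabs=False
    )


@pytest.fixture(scope="session")
def clean_kspace(clean_phantom):
    return simulate_acquisition(
        clean_phantom, build_aw_scheme(), Protocol(gated=True, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def clean_mask(clean_phantom):
    return rasterize_masks(clean_phantom)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-featured phantom: blood pool, saturation slabs, motion."""
    return build_default_phantom()


@pytest.fixture(scope="session")
def small_geometry():
    return sr.AcquisitionGeometry((80.0, 80.0, 50.0), (4, 4, 2))


@pytest.fixture(scope="session")
def empty_phantom(small_geometry):
    """Zero-signal phantom on a tiny grid, for noise-only simulations."""
    from slamrecon.phantom import Box, CompartmentSpec, PhantomDefinition, SpectralComponent

    comp = CompartmentSpec(
        "other",
        shapes=(Box((0.0, 0.0, 0.0), (80.0, 80.0, 50.0)),),
        components=(SpectralComponent("null", 0.0, 0.0, 10.0),),
    )
    return PhantomDefinition(geometry=small_geometry, compartments=(comp,))


def time_axis(n=512, dwell=1.0 / 4000.0):
    return np.arange(n) * dwell
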