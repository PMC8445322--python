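"""Shared fixtures: small seeded geometries and noiseless synthetic stacks."""

import math

import numpy as np
import pytest

from retroquant.kinetics import KineticParams
from retroquant.synthetic import (
    AcquisitionParams,
    generate_geometry,
    generate_timelapse,
)


@pytest.fixture(scope="session")
def small_geometry():
    """Two cells with punctate endolysosomes in a 128x128 field."""
    return generate_geometry(
        2,
        seed=3,
        image_shape=(128, 128),
        cell_radius_range=(24.0, 30.0),
        n_el_range=(5, 8),
        el_radius_range=(2.0, 4.0),
    )


@pytest.fixture(scope="session")
def plateau_params():
    """Zero-retrofusion, pure-cleavage regime at the measured 2:1 ILV:LM ratio."""
    return KineticParams(
        rho=2.0, phi_dynamic=0.0, k_cleave=0.1, k_retro=0.0,
        half_life_h=math.inf, k_sec=0.0,
    )


@pytest.fixture(scope="session")
def plateau_stack(plateau_params):
    """Noiseless 3-cell movie over the full 6-h protocol (frames every 180 s).

    121 frames cover t = 0..360 min inclusive so the 6-h remaining fraction
    is sampled exactly.
    """
    geom = generate_geometry(
        3,
        seed=11,
        image_shape=(256, 256),
        cell_radius_range=(30.0, 40.0),
        n_el_range=(6, 10),
        el_radius_range=(2.0, 4.0),
    )
    acq = AcquisitionParams(n_frames=121)
    stack, truth = generate_timelapse(geom, plateau_params, acq)
    return stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
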