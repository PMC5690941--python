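import numpy as np
import pytest

from odmsim.attenuation import MATERIALS
from odmsim.beam import Spectrum
from odmsim.config import RunConfig
from odmsim.experiments import make_beam
from odmsim.phantoms import VoxelPhantom, build_ctdi_phantom
from odmsim.transport import BeamGeometry


@pytest.fixture(scope="session")
def config():
    return RunConfig(seed=1234)


@pytest.fixture(scope="session")
def beam(config):
    """(spectrum, subfields) for the large filter via the full beam chain."""
    return make_beam(config)


@pytest.fixture(scope="session")
def geometry():
    return BeamGeometry()


@pytest.fixture(scope="session")
def ctdi_phantom_coarse():
    """4 mm voxel CTDI phantom: fast enough for per-test MC runs."""
    return build_ctdi_phantom(voxel_mm=4.0)


@pytest.fixture(scope="session")
def water_box():
    """100 mm water cube centered on the isocenter with one tally region."""
    n = 25
    vox = 4.0
    material = np.ones((n, n, n), dtype=np.int8)
    organ = np.ones((n, n, n), dtype=np.int16)
    return VoxelPhantom(
        voxel_mm=np.array([vox] * 3),
        material_grid=material,
        organ_grid=organ,
        material_names=["air", "water"],
        densities=np.array([MATERIALS["air"].density, MATERIALS["water"].density]),
        origin_mm=np.array([-50.0, -50.0, -50.0]),
        organ_names={1: "block"},
    )


@pytest.fixture(scope="session")
def mono_60kev():
    """Spectrum whose only support is the 60 keV grid point."""
    return Spectrum(np.array([59.0, 60.0]), np.array([0.0, 1.0]))
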