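"""Shared fixtures: small specimens and instrument settings sized for tests."""
from __future__ import annotations

import numpy as np
import pytest

import coccomap as cm


@pytest.fixture(scope="session")
def library():
    return cm.load_line_library()


@pytest.fixture(scope="session")
def inst_small():
    """Default instrument with 20 eV bins (800 bins), fast to render and fit."""
    return cm.InstrumentConfig(energy_step_keV=0.02)


@pytest.fixture(scope="session")
def small_geometry():
    """A 3 um placolith at 100 nm pixels (~1.2k pixel grid)."""
    return cm.GeometryConfig(length_um=3.0, width_um=2.4, pixel_size_nm=100.0, seed=0)


@pytest.fixture(scope="session")
def small_models():
    return {
        "Sr": cm.IncorporationModel(mode="lattice", base_ratio_mmol_per_mol=3.0,
                                    radial_gradient=1.0),
        "Cl": cm.IncorporationModel(mode="surface", coat_field_scale=1.5e4),
        "Fe": cm.IncorporationModel(mode="surface", coat_field_scale=500.0),
    }


@pytest.fixture(scope="session")
def small_specimen(small_geometry, small_models):
    thickness = cm.make_geometry(small_geometry)
    return cm.make_element_fields(thickness, small_models, seed=0)


@pytest.fixture(scope="session")
def standard_calibration(inst_small, library):
    """Noiseless synthetic standard measurement and the calibration from it."""
    certified = {"Ca": 116.0, "Fe": 184.0, "Cu": 160.0, "Zn": 127.0, "Sr": 100.0}
    std = cm.synthetic_standard(certified, inst_small)
    cal = cm.calibrate(std, library, inst_small.dwell_s)
    return std, cal


#: Candidate set used for fits of the small specimen (absent elements included
#: on purpose so the inclusion rule has something to reject).
CANDIDATES = ["Ca", "Sr", "Se", "Cl", "Fe", "Ni", "Zn", "V",
              "Ar", "Si", "Cu", "Kr"]


@pytest.fixture(scope="session")
def candidates():
    return list(CANDIDATES)
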