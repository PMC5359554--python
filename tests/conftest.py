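"""Shared fixtures: a self-contained voxel/plate model built entirely from
the package's synthetic generators (yield table, water stopping-power curve,
two-component electron spectrum)."""

import numpy as np
import pytest

import tlksim as t
from tlksim.calibration import SimConfig


@pytest.fixture(scope="session")
def nucleus():
    return t.NucleusModel(diameter_um=10.0, density_g_cm3=1.0)


@pytest.fixture(scope="session")
def let_model():
    return t.water_let_fixture()


@pytest.fixture(scope="session")
def zbar_fn(let_model, nucleus):
    return t.make_zbar_fn(let_model, nucleus)


@pytest.fixture(scope="session")
def table():
    return t.generate_fixture_table()


@pytest.fixture(scope="session")
def spectrum20():
    """Voxel-like spectrum with a 20% low-energy (<100 keV) traversal share."""
    return t.make_spectrum(t.SpectrumGeneratorConfig(low_energy_fraction=0.20, seed=3))


@pytest.fixture(scope="session")
def truth_params():
    """The calibrated repair/mis-repair parameter set used as ground truth."""
    return t.TLKParams()


@pytest.fixture(scope="session")
def cal_config(spectrum20, zbar_fn, table):
    """Scaled-down calibration plate model (deterministic)."""
    pop = t.build_population(spectrum20, zbar_fn, table, 21.0, n=100, seed=7)
    return SimConfig(pop, t_end_h=96.0, dt_h=0.1)


@pytest.fixture(scope="session")
def doses6():
    return np.array([0.1, 1.0, 2.0, 3.0, 4.0, 5.0])
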