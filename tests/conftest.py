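import numpy as np
import pytest

from hucorr import (
    BeamModelParams,
    MaterialTable,
    ScannerCalibration,
    build_phantom_spec,
    load_packaged_table,
)
from hucorr.xsection import RAYLEIGH_FIT_TABLE


@pytest.fixture(scope="session")
def wide_table():
    """Packaged 10-150 keV water table (mass attenuation, cm^2/g)."""
    return load_packaged_table()


@pytest.fixture(scope="session")
def fit_table():
    """Packaged 50-100 keV Rayleigh table in the power-law fit's units."""
    return load_packaged_table(RAYLEIGH_FIT_TABLE)


@pytest.fixture(scope="session")
def params():
    return BeamModelParams()


@pytest.fixture(scope="session")
def calib():
    """Default scanner calibration: 30 cm / 110 kVp, epsilon 0.045."""
    return ScannerCalibration()


@pytest.fixture(scope="session")
def zero_calib():
    """Zero-sized-phantom calibration: corrections enter unreferenced."""
    return ScannerCalibration(cal_diameter=0.0)


@pytest.fixture(scope="session")
def materials():
    return MaterialTable()


@pytest.fixture(scope="session")
def head_spec():
    return build_phantom_spec("head")


@pytest.fixture(scope="session")
def abdomen_spec():
    return build_phantom_spec("abdomen")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
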