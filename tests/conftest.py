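import numpy as np
import pytest

from duospect.geometry import AcquisitionGeometry
from duospect.physics import DetectorModel, standard_windows
from duospect.psf import generate_psf_table


@pytest.fixture(scope="session")
def windows():
    return standard_windows()


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def psf_tables(windows, detector):
    """PSF tables for the three windows the pipeline actually uses."""
    return {lab: generate_psf_table(det=detector, window=windows[lab])
            for lab in ("ho81", "tc140", "sc170")}


@pytest.fixture(scope="session")
def small_geom(windows):
    """A light acquisition geometry for fast simulator tests."""
    return AcquisitionGeometry(n_angles=8, nu=48, nv=32,
                               windows=tuple(windows.values()),
                               time_per_angle_s=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
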