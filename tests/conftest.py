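"""Shared fixtures: optical train, default sheets, camera and PSF models.

The lattice and Gaussian sheet volumes are session-scoped because they
are the expensive inputs reused across the metric, scattering and
acceptance tests.
"""

import numpy as np
import pytest

from solls import (MaskSpec, OpticalTrain, SheetSpec, make_gaussian_sheet,
                   make_lattice_sheet)
from solls.beams import gaussian_focal_field, lattice_focal_field
from solls.smlm import CameraModel, PSFModel


@pytest.fixture(scope="session")
def train():
    return OpticalTrain()


@pytest.fixture(scope="session")
def sheet_spec():
    return SheetSpec(family="lattice")


@pytest.fixture(scope="session")
def gaussian_spec():
    return SheetSpec(family="gaussian")


@pytest.fixture(scope="session")
def lattice_sheet(train, sheet_spec):
    """Default dithered lattice sheet, ±60 µm, 121 planes."""
    return make_lattice_sheet(MaskSpec(), train, sheet_spec)


@pytest.fixture(scope="session")
def gaussian_sheet(train, gaussian_spec):
    """Matched-waist Gaussian sheet, ±60 µm, 121 planes."""
    return make_gaussian_sheet(gaussian_spec, train)


@pytest.fixture(scope="session")
def lattice_focal(train, sheet_spec):
    field, _ = lattice_focal_field(MaskSpec(), train, sheet_spec)
    return field


@pytest.fixture(scope="session")
def gaussian_focal(train, gaussian_spec):
    return gaussian_focal_field(gaussian_spec, train)


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def psf():
    return PSFModel()


@pytest.fixture(scope="session")
def dh_psf():
    return PSFModel.short_range()


def gaussian_beam_field(w0, dx, n_grid, wavelength=0.56, index=1.0):
    """Round Gaussian beam at its waist, for propagation oracles."""
    from solls import ScalarField
    c = (np.arange(n_grid) - n_grid // 2) * dx
    r2 = c[:, None] ** 2 + c[None, :] ** 2
    return ScalarField(np.exp(-r2 / w0**2), dx, dx, wavelength, index)
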