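import numpy as np
import pytest

from nirtrs.design import ExperimentDesign
from nirtrs.optics import (
    TPSF,
    OpticalProperties,
    ProbeGeometry,
    TimeGrid,
    convolve_irf,
    gaussian_irf,
    reflectance,
)


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def geometry() -> ProbeGeometry:
    return ProbeGeometry()


def make_tpsf(
    mua: float = 0.015,
    musp: float = 1.2,
    total_photons: float | None = None,
    seed: int | None = None,
    grid: TimeGrid | None = None,
    geometry: ProbeGeometry | None = None,
    wavelength: float = 763.0,
) -> TPSF:
    """Forward-model a TPSF; noiseless float expectation counts unless a
    photon budget + seed are given."""
    from nirtrs.optics import sample_counts

    grid = grid or TimeGrid()
    geometry = geometry or ProbeGeometry()
    irf = gaussian_irf(grid)
    props = OpticalProperties(mua=mua, musp=musp, wavelength=wavelength)
    expected = convolve_irf(reflectance(geometry, props, grid), irf)
    if total_photons is None:
        # noiseless: float expectation counts and the exact (unrounded) IRF
        counts = expected / expected.sum() * 1e7
        irf_counts = irf * 1e6
    else:
        counts = sample_counts(expected, int(total_photons), seed)
        irf_counts = np.round(irf * 1e6).astype(np.int64)
    return TPSF(
        grid=grid,
        counts=counts,
        irf_counts=irf_counts,
        wavelength=wavelength,
        geometry=geometry,
    )


@pytest.fixture(scope="session")
def noiseless_tpsf() -> TPSF:
    return make_tpsf()
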