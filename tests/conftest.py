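import numpy as np
import pytest

from qobm import (
    ARM_LABELS,
    FrequencyGrid,
    OpticalSystem,
    PhantomSpec,
    compute_wotf,
    make_pupil,
    make_source,
)


@pytest.fixture(scope="session")
def osys32():
    return OpticalSystem(wavelength_um=0.72, na_objective=0.6, pixel_um=0.25,
                         shape=(32, 32))


@pytest.fixture(scope="session")
def grid32(osys32):
    return FrequencyGrid.from_system(osys32)


@pytest.fixture(scope="session")
def pupil32(osys32, grid32):
    return make_pupil(osys32, grid32)


@pytest.fixture(scope="session")
def tfs32(osys32, grid32, pupil32):
    return {
        arm: compute_wotf(osys32, grid32, pupil32, make_source(osys32, grid32, arm))
        for arm in ARM_LABELS
    }


def _system_with_tfs(shape, pixel_um):
    osys = OpticalSystem(wavelength_um=0.72, na_objective=0.6, pixel_um=pixel_um,
                         shape=shape)
    grid = FrequencyGrid.from_system(osys)
    pupil = make_pupil(osys, grid)
    tfs = {
        arm: compute_wotf(osys, grid, pupil, make_source(osys, grid, arm))
        for arm in ARM_LABELS
    }
    return osys, grid, pupil, tfs


@pytest.fixture(scope="session")
def field_system():
    """Moderate-size imaging setup for group simulations: 128x128 at
    0.5 um/pixel (64 um field of view)."""
    return _system_with_tfs((128, 128), 0.5)


@pytest.fixture(scope="session")
def field_spec():
    """Phantom geometry scaled to the 64-um field: default phase levels,
    fewer/smaller nuclei so the packing stays feasible."""
    return PhantomSpec(
        n_nuclei=8,
        nucleus_radius_um=(2.5, 4.5),
        n_inclusions=2,
        inclusion_radius_um=(0.8, 1.4),
    )


@pytest.fixture(scope="session")
def small_system():
    """Small setup for replicate-heavy statistics: 64x64 at 0.5 um/pixel."""
    return _system_with_tfs((64, 64), 0.5)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        n_nuclei=3,
        nucleus_radius_um=(2.0, 3.5),
        n_inclusions=1,
        inclusion_radius_um=(0.8, 1.2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
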