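import numpy as np
import pytest

from chromstim import (
    LightSource,
    Photoreceptor,
    ReceptorSet,
    SensitivityCurve,
    Spectrum,
    StimulationSystem,
    WavelengthGrid,
)
from chromstim.fixtures import (
    artificial_spectrum,
    dichromat_receptors,
    gaussian_led_bank,
)


@pytest.fixture(scope="session")
def grid1nm():
    return WavelengthGrid.regular(300.0, 700.0, 1.0)


@pytest.fixture(scope="session")
def dichromat():
    """Gaussian S(440/50) + L(520/80) dichromat, log transform, eps=1e-3."""
    return dichromat_receptors()


@pytest.fixture(scope="session")
def led3():
    """Three Gaussian LEDs at 400/480/580 nm, unit-flux, bounds [0, 1]."""
    return gaussian_led_bank((400.0, 480.0, 580.0), (20.0, 25.0, 30.0))


@pytest.fixture(scope="session")
def led2():
    """Two broadband Gaussian LEDs for 2x2 fixtures."""
    return gaussian_led_bank((430.0, 550.0), (35.0, 45.0))


@pytest.fixture(scope="session")
def system32(dichromat, led3):
    """Underdetermined 2-receptor / 3-source system on a mid-grey background."""
    return StimulationSystem(led3, dichromat, background=np.array([0.5, 0.5, 0.5]))


@pytest.fixture(scope="session")
def system22(dichromat, led2):
    """Determined 2-receptor / 2-source system on a mid-grey background."""
    return StimulationSystem(led2, dichromat, background=np.array([0.5, 0.5]))


def random_square_system(rng, n=3, transform="log"):
    """Random full-rank n-receptor / n-source system for consistency tests."""
    grid = WavelengthGrid.regular(300.0, 700.0, 1.0)
    wl = grid.wavelengths
    receptors = []
    for i in range(n):
        mu = rng.uniform(380, 620)
        sd = rng.uniform(30, 80)
        vals = np.exp(-0.5 * ((wl - mu) / sd) ** 2)
        receptors.append(Photoreceptor(f"r{i}", SensitivityCurve(grid, vals),
                                       epsilon=1e-3))
    rset = ReceptorSet(receptors, transform=transform, grid=grid)
    sources = []
    for j in range(n):
        mu = rng.uniform(360, 640)
        sd = rng.uniform(15, 40)
        vals = np.exp(-0.5 * ((wl - mu) / sd) ** 2)
        sources.append(LightSource(f"s{j}", Spectrum(grid, vals), upper=10.0))
    sys_ = StimulationSystem(sources, rset,
                             background=np.full(n, 0.5))
    if np.linalg.matrix_rank(sys_.A) < n or np.linalg.cond(sys_.A) > 1e6:
        return None
    return sys_


@pytest.fixture(scope="session")
def fine_oracle():
    """Independent 0.1 nm trapezoid quadrature oracle for capture integrals.

    Works from closed-form curve definitions, not package signal objects.
    """

    def oracle(sens_fn, spec_fn, lo=300.0, hi=700.0, step=0.1):
        wl = np.arange(lo, hi + step / 2, step)
        return np.trapezoid(sens_fn(wl) * spec_fn(wl), wl)

    return oracle
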