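"""Synthetic fixtures and colour-space sampling strategies.

Provides the artificial dichromat used throughout the examples (Gaussian
sensitivities peaking at 440 and 520 nm with widths 50 and 80 nm), the
artificial test spectra exp(sin(2*pi*(lambda-300)/400)) and the cosine
analogue, Gaussian LED banks, Gaussian-parameter sensitivity prior grids,
and seeded low-rank hyperspectral cubes.  Also implements grid sampling in
source-intensity-log or excitation space and in-gamut random sampling.
Everything is deterministic given a seed and needs no external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fitting import FitProblem, fit, in_gamut
from .patterned import HyperspectralImage
from .receptors import Photoreceptor, ReceptorSet
from .spectral import SensitivityCurve, Spectrum, WavelengthGrid, integrate
from .system import LightSource, StimulationSystem

__all__ = [
    "DEFAULT_GRID",
    "gaussian_sensitivity",
    "dichromat_receptors",
    "artificial_spectrum",
    "gaussian_led",
    "gaussian_led_bank",
    "prior_grid",
    "synthetic_cube",
    "make_fixtures",
    "sample_grid",
    "sample_in_gamut",
    "FixtureBundle",
]

DEFAULT_GRID = WavelengthGrid.regular(300.0, 700.0, 1.0)


def gaussian_sensitivity(mean: float, sd: float, name: str = "",
                         grid: WavelengthGrid = DEFAULT_GRID) -> SensitivityCurve:
    """Peak-normalized Gaussian sensitivity curve."""
    if sd <= 0:
        raise ValueError("standard deviation must be > 0")
    wl = grid.wavelengths
    vals = np.exp(-0.5 * ((wl - mean) / sd) ** 2)
    return SensitivityCurve(grid, vals, name=name, normalization="peak")


def dichromat_receptors(means=(440.0, 520.0), sds=(50.0, 80.0),
                        epsilon: float = 1e-3, transform: str = "log",
                        grid: WavelengthGrid = DEFAULT_GRID) -> ReceptorSet:
    """The artificial S/L dichromat (Gaussians 440/50 nm and 520/80 nm)."""
    names = ["S", "L"] if len(means) == 2 else [f"R{i}" for i in range(len(means))]
    receptors = [
        Photoreceptor(name, gaussian_sensitivity(mu, sd, name=name, grid=grid),
                      epsilon=epsilon)
        for name, mu, sd in zip(names, means, sds)
    ]
    return ReceptorSet(receptors, transform=transform, grid=grid)


def artificial_spectrum(kind: str = "sin",
                        grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """The artificial broadband spectra exp(sin(.)) / exp(cos(.)).

    Phase argument is 2*pi*(lambda - 300 nm) / 400 nm.
    """
    wl = grid.wavelengths
    phase = 2 * np.pi * (wl - 300.0) / 400.0
    if kind == "sin":
        vals = np.exp(np.sin(phase))
    elif kind == "cos":
        vals = np.exp(np.cos(phase))
    else:
        raise ValueError("kind must be 'sin' or 'cos'")
    return Spectrum(grid, vals, name=f"exp_{kind}")


def gaussian_led(peak: float, sd: float, name: str = "", lower: float = 0.0,
                 upper: float = 1.0,
                 grid: WavelengthGrid = DEFAULT_GRID) -> LightSource:
    """Gaussian LED emission, normalized to unit photon flux by LightSource."""
    wl = grid.wavelengths
    name = name or f"led{int(peak)}"
    vals = np.exp(-0.5 * ((wl - peak) / sd) ** 2)
    return LightSource(name, Spectrum(grid, vals, name=name),
                       lower=lower, upper=upper)


def gaussian_led_bank(peaks, sds=None, lower: float = 0.0, upper: float = 1.0,
                      grid: WavelengthGrid = DEFAULT_GRID) -> list[LightSource]:
    sds = [15.0] * len(peaks) if sds is None else sds
    return [gaussian_led(p, s, name=f"led{int(p)}", lower=lower, upper=upper,
                         grid=grid) for p, s in zip(peaks, sds)]


def prior_grid(mean_ranges=((420.0, 460.0), (500.0, 540.0)),
               sd_ranges=((30.0, 70.0), (60.0, 100.0)), step: float = 10.0,
               epsilon: float = 1e-3, transform: str = "log",
               grid: WavelengthGrid = DEFAULT_GRID) -> list[ReceptorSet]:
    """Grid of Gaussian-sensitivity receptor sets over mean/sd ranges.

    The default ranges give 5 values per parameter and 5**4 = 625 dichromat
    samples (two receptors, mean and sd each varied independently).
    """
    axes = []
    for (lo, hi) in mean_ranges:
        axes.append(np.arange(lo, hi + step / 2, step))
    for (lo, hi) in sd_ranges:
        axes.append(np.arange(lo, hi + step / 2, step))
    n_rec = len(mean_ranges)
    samples = []
    for combo in itertools.product(*axes):
        means = combo[:n_rec]
        sds = combo[n_rec:]
        samples.append(dichromat_receptors(means, sds, epsilon=epsilon,
                                           transform=transform, grid=grid))
    return samples


def synthetic_cube(height: int = 32, width: int = 32, rank: int = 2,
                   noise: float = 0.0, seed: int = 0,
                   grid: WavelengthGrid | None = None,
                   step: float = 5.0) -> HyperspectralImage:
    """Seeded low-rank hyperspectral cube with smooth spatial/spectral factors.

    cube = sum_r map_r (pixels) x profile_r (wavelengths) + noise, clipped at
    zero; mimics the strong spatial-spectral correlation of natural scenes.
    """
    rng = np.random.default_rng(seed)
    grid = grid or WavelengthGrid.regular(300.0, 700.0, step)
    wl = grid.wavelengths
    p = height * width
    yy, xx = np.mgrid[0:height, 0:width]
    maps = np.empty((rank, p))
    profiles = np.empty((rank, wl.size))
    for r in range(rank):
        cy, cx = rng.uniform(0, height), rng.uniform(0, width)
        s = rng.uniform(0.2, 0.5) * max(height, width)
        maps[r] = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s ** 2))).ravel()
        mu = rng.uniform(350, 650)
        sd = rng.uniform(40, 120)
        profiles[r] = np.exp(-0.5 * ((wl - mu) / sd) ** 2)
    cube = maps.T @ profiles
    if noise > 0:
        cube = cube + noise * rng.standard_normal(cube.shape)
    cube = np.clip(cube, 0.0, None)
    return HyperspectralImage(height, width, grid, cube)


@dataclass
class FixtureBundle:
    """The synthetic test-bed: a dichromat, an LED bank, spectra and a cube."""

    receptors: ReceptorSet
    sources: list[LightSource]
    spectra: list[Spectrum]
    cube: HyperspectralImage


def make_fixtures(means=(440.0, 520.0), sds=(50.0, 80.0),
                  led_peaks=(400.0, 480.0, 580.0), led_sds=(20.0, 25.0, 30.0),
                  led_upper: float = 1.0, epsilon: float = 1e-3,
                  transform: str = "log", cube_size: int = 32,
                  cube_rank: int = 2, cube_noise: float = 0.0,
                  seed: int = 0) -> FixtureBundle:
    """Assemble the default synthetic fixture set on a 1 nm [300, 700] grid."""
    receptors = dichromat_receptors(means, sds, epsilon=epsilon,
                                    transform=transform)
    sources = gaussian_led_bank(led_peaks, led_sds, upper=led_upper)
    spectra = [artificial_spectrum("sin"), artificial_spectrum("cos")]
    cube = synthetic_cube(cube_size, cube_size, rank=cube_rank,
                          noise=cube_noise, seed=seed)
    return FixtureBundle(receptors, sources, spectra, cube)


# ---------------------------------------------------------------------------
# Sampling strategies.


@dataclass
class GridSpec:
    """An axis-aligned sampling grid in one of two spaces.

    ``source-intensity-log``: coordinates are log(i / i_b) per source, so
    (0, ..., 0) maps to the background intensities exactly and no fitting is
    needed.  ``excitation``: coordinates are target excitations, fitted (and
    hence clipped to the gamut) through the standard solver.
    """

    low: np.ndarray
    high: np.ndarray
    count: np.ndarray
    space: str = "excitation"

    def __post_init__(self) -> None:
        self.low = np.atleast_1d(np.asarray(self.low, dtype=float))
        self.high = np.atleast_1d(np.asarray(self.high, dtype=float))
        self.count = np.atleast_1d(np.asarray(self.count, dtype=int))
        if not (self.low.shape == self.high.shape == self.count.shape):
            raise ValueError("low/high/count must have matching shapes")
        if np.any(self.count < 2):
            raise ValueError("need at least 2 points per dimension")
        if np.any(self.low >= self.high):
            raise ValueError("low must be < high per dimension")
        if self.space not in ("source-intensity-log", "excitation"):
            raise ValueError(f"unknown sampling space {self.space!r}")

    def points(self) -> np.ndarray:
        axes = [np.linspace(lo, hi, c)
                for lo, hi, c in zip(self.low, self.high, self.count)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


def sample_grid(spec: GridSpec, system: StimulationSystem,
                background_intensity: np.ndarray | None = None):
    """Evaluate a sampling grid on a system.

    Returns ``(intensities, excitations)`` with one row per grid point.  In
    source space intensities are i_b * exp(g) (clipped to bounds); in
    excitation space each grid point is fitted, clipping out-of-gamut
    targets as per the fitting procedure.
    """
    pts = spec.points()
    if spec.space == "source-intensity-log":
        if pts.shape[1] != system.m:
            raise ValueError(
                f"source-space grid dimension {pts.shape[1]} != m={system.m}"
            )
        if background_intensity is None:
            if not (system.background is not None
                    and not isinstance(system.background, Spectrum)):
                raise ValueError(
                    "source-space sampling needs background intensities; pass "
                    "background_intensity or build the system with an "
                    "intensity-vector background"
                )
            background_intensity = np.asarray(system.background, dtype=float)
        xs = background_intensity[None, :] * np.exp(pts)
        xs = np.clip(xs, system.lower, system.upper)
        es = np.stack([system.excitations(x) for x in xs])
        return xs, es
    if pts.shape[1] != system.n:
        raise ValueError(
            f"excitation-space grid dimension {pts.shape[1]} != n={system.n}"
        )
    xs, es = [], []
    for target in pts:
        r = fit(FitProblem(system, target))
        xs.append(r.x)
        es.append(r.excitations)
    return np.stack(xs), np.stack(es)


def _gamut_vertices(system: StimulationSystem) -> np.ndarray:
    """Total relative captures at all bound-vertex intensity vectors."""
    combos = itertools.product(*[(lo, hi) for lo, hi in
                                 zip(system.lower, system.upper)])
    X = np.array(list(combos))
    return X @ system.A.T + system.eta


def sample_in_gamut(system: StimulationSystem, count: int, seed: int = 0,
                    method: str = "hull-interior") -> np.ndarray:
    """Random excitation targets guaranteed inside the system's gamut.

    ``hull-interior`` draws Dirichlet-weighted mixtures of the gamut's
    capture-space vertices (the image of the intensity box is convex, so
    every mixture is reachable); ``rejection`` samples the capture-space
    bounding box and keeps reachable points.  Deterministic per seed.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    verts = _gamut_vertices(system)
    if np.allclose(verts, verts[0]):
        raise ValueError("degenerate gamut: all vertices coincide")
    rng = np.random.default_rng(seed)
    if method == "hull-interior":
        # sparse Dirichlet (alpha < 1) spreads mass toward the gamut
        # boundary so the sample hull covers the polytope quickly
        wts = rng.dirichlet(np.full(len(verts), 0.2), size=count)
        caps = wts @ verts
        return system.transform(caps)
    if method == "rejection":
        lo = verts.min(axis=0)
        hi = verts.max(axis=0)
        out = []
        attempts = 0
        while len(out) < count:
            cand = rng.uniform(lo, hi, size=system.n)
            if in_gamut(system, cand):
                out.append(cand)
            attempts += 1
            if attempts > 100000 * count:
                raise RuntimeError("rejection sampling failed to converge")
        return system.transform(np.array(out))
    raise ValueError(f"unknown sampling method {method!r}")
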