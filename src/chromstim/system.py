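"""Stimulation-system model: the normalized capture matrix, chromaticity
projection, and gamut geometry/metric.

The gamut metric is the ratio of the (n-1)-dimensional hull measure of a
system's reachable chromaticities to the hull measure of the 'perfect'
system whose chromaticities trace the single-wavelength locus.  Hull
measures are computed after projecting the (n-1)-simplex onto its first
n-1 coordinates; the ratio is invariant to that affine projection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .receptors import ReceptorSet, capture, relative_capture
from .spectral import Spectrum, SpectralError, integrate, resample

__all__ = [
    "LightSource",
    "StimulationSystem",
    "build_capture_matrix",
    "chromaticity",
    "spectral_locus",
    "gamut_metric",
    "rank_source_sets",
]


@dataclass(frozen=True)
class LightSource:
    """A light source with a unit-photon-flux spectrum and intensity bounds.

    The stored spectrum integrates to one uE; ``lower``/``upper`` are the
    admissible intensities (uE) scaling that spectrum.  The lower bound can
    never be negative: a light source cannot emit negative intensity.
    """

    name: str
    spectrum: Spectrum
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        flux = integrate(self.spectrum)
        if flux <= 0:
            raise SpectralError(f"source {self.name!r} has zero photon flux")
        if abs(flux - 1.0) > 1e-9:
            object.__setattr__(self, "spectrum", self.spectrum.scaled(1.0 / flux))
        if self.lower < 0:
            raise ValueError("lower intensity bound must be >= 0")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")

    @classmethod
    def from_spectrum(cls, name: str, spectrum: Spectrum,
                      lower: float = 0.0, upper: float = 1.0) -> "LightSource":
        return cls(name, spectrum, lower, upper)


def build_capture_matrix(receptors: ReceptorSet, sources: Sequence[LightSource],
                         background: Spectrum | np.ndarray | None,
                         return_denominator: bool = False):
    """Normalized capture matrix A and baseline vector eta.

    A[i, j] is the relative light-induced capture of receptor i for source j
    at one unit photon flux: capture_i(source_j) / (Q_background_i + eps_i).
    eta[i] = eps_i / (Q_background_i + eps_i).
    """
    raw = np.stack([capture(receptors, s.spectrum) for s in sources], axis=1)
    if background is None:
        Qb = np.zeros(receptors.n)
    elif isinstance(background, Spectrum):
        Qb = capture(receptors, background)
    else:
        x_b = np.asarray(background, dtype=float)
        if x_b.shape != (len(sources),):
            raise ValueError(
                f"background intensity vector length {x_b.shape} does not match "
                f"{len(sources)} sources"
            )
        Qb = raw @ x_b
    denom = Qb + receptors.epsilon
    if np.any(denom <= 0):
        raise ValueError(
            "background capture + epsilon must be positive; give a brighter "
            "background or epsilon > 0"
        )
    A = raw / denom[:, None]
    eta = receptors.epsilon / denom
    if return_denominator:
        return A, eta, denom
    return A, eta


class StimulationSystem:
    """m bounded light sources viewed through an animal's receptor set."""

    def __init__(self, sources: Sequence[LightSource], receptors: ReceptorSet,
                 background: Spectrum | np.ndarray | None = None):
        sources = list(sources)
        if not sources:
            raise ValueError("need at least one light source")
        names = [s.name for s in sources]
        if len(set(names)) != len(names):
            raise ValueError(f"source names must be unique, got {names}")
        self.sources = tuple(sources)
        self.receptors = receptors
        self.background = background
        self.A, self.eta, self.vk_denominator = build_capture_matrix(
            receptors, sources, background, return_denominator=True)

    @property
    def n(self) -> int:
        return self.receptors.n

    @property
    def m(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]

    @property
    def lower(self) -> np.ndarray:
        return np.array([s.lower for s in self.sources])

    @property
    def upper(self) -> np.ndarray:
        return np.array([s.upper for s in self.sources])

    @property
    def transform(self):
        return self.receptors.transform

    def relative_captures(self, x: np.ndarray) -> np.ndarray:
        """Total relative capture q_t = A x + eta for intensities x."""
        return self.A @ np.asarray(x, dtype=float) + self.eta

    def excitations(self, x: np.ndarray) -> np.ndarray:
        return self.transform(self.relative_captures(x))

    def subsystem(self, names: Iterable[str]) -> "StimulationSystem":
        wanted = list(names)
        by_name = {s.name: s for s in self.sources}
        return StimulationSystem([by_name[n] for n in wanted], self.receptors,
                                 self.background)

    def __repr__(self) -> str:
        return (f"StimulationSystem(sources={self.source_names}, "
                f"receptors={self.receptors.names})")


def chromaticity(values: np.ndarray) -> np.ndarray:
    """Project capture vectors onto the (n-1)-simplex: v / sum(v).

    Accepts a single vector or an array of row vectors; intensity-free.
    """
    v = np.asarray(values, dtype=float)
    s = v.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("chromaticity undefined for all-zero capture vectors")
    return v / s


def spectral_locus(receptors: ReceptorSet, start: float | None = None,
                   stop: float | None = None, step: float = 1.0,
                   adaptation: np.ndarray | None = None):
    """Chromaticities of monochromatic lights across the visible range.

    Returns ``(wavelengths, points)`` where points[k] is the chromaticity at
    wavelengths[k]; wavelengths where every receptor is insensitive are
    skipped.  ``adaptation`` divides each receptor's sensitivity by a von
    Kries denominator so the locus lives in relative-capture space; the
    rescaling is monotone per coordinate, so extreme wavelengths coincide
    with the unadapted locus.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    lo, hi = receptors.grid.span
    lo = lo if start is None else start
    hi = hi if stop is None else stop
    wls = np.arange(lo, hi + step / 2, step)
    S = receptors.sensitivity_matrix()
    if adaptation is not None:
        adaptation = np.asarray(adaptation, dtype=float)
        if adaptation.shape != (receptors.n,) or np.any(adaptation <= 0):
            raise ValueError("adaptation must be a positive length-n vector")
        S = S / adaptation[:, None]
    vals = np.stack([
        np.interp(wls, receptors.grid.wavelengths, S[i], left=0.0, right=0.0)
        for i in range(receptors.n)
    ], axis=1)
    mask = vals.sum(axis=1) > 0
    return wls[mask], chromaticity(vals[mask])


def _hull_measure(points: np.ndarray) -> float:
    """(d)-dimensional hull measure of simplex points projected to their
    first n-1 coordinates; degenerate hulls have measure 0."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("expected an array of chromaticity points")
    proj = pts[:, :-1]
    d = proj.shape[1]
    if d == 0:
        return 0.0
    if d == 1:
        return float(proj.max() - proj.min())
    if len(pts) <= d:
        return 0.0
    try:
        return float(ConvexHull(proj).volume)
    except QhullError:
        return 0.0  # degenerate (flat) point set


def _box_hyperplane_vertices(a: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                             level: float) -> np.ndarray:
    """Vertices of {lo <= x <= hi, a.x = level} by fixing all but one
    coordinate at bounds and solving for the free one (small m only)."""
    m = a.size
    verts = []
    for free in range(m):
        if a[free] == 0:
            continue
        others = [j for j in range(m) if j != free]
        for combo in itertools.product(*[(lo[j], hi[j]) for j in others]):
            x = np.empty(m)
            x[others] = combo
            x[free] = (level - a[others] @ x[others]) / a[free]
            if lo[free] - 1e-12 <= x[free] <= hi[free] + 1e-12:
                x[free] = np.clip(x[free], lo[free], hi[free])
                verts.append(x)
    return np.array(verts) if verts else np.empty((0, m))


def _reachable_chromaticities(system: StimulationSystem,
                              intensity_level: float | None,
                              rng: np.random.Generator | None = None,
                              mc_samples: int = 4096) -> np.ndarray:
    A, eta = system.A, system.eta
    lo, hi = system.lower, system.upper
    if intensity_level is None:
        # Uncapped: the closure of reachable chromaticities at unbounded
        # intensity is the hull of the source chromaticities (the baseline
        # eta only matters near darkness and would give a single source a
        # spurious nonzero gamut).
        pts = [chromaticity(A[:, j]) for j in range(system.m) if A[:, j].sum() > 0]
        return np.array(pts)
    a = A.sum(axis=0)  # total relative capture contributed per unit intensity
    if system.m <= 8:
        verts = _box_hyperplane_vertices(a, lo, hi, intensity_level)
    else:  # Monte-Carlo hull for wide banks
        rng = rng or np.random.default_rng(0)
        x = rng.uniform(lo, hi, size=(mc_samples, system.m))
        tot = x @ a
        ok = tot > 0
        x = x[ok] * (intensity_level / tot[ok])[:, None]
        inside = np.all((x >= lo - 1e-12) & (x <= hi + 1e-12), axis=1)
        verts = x[inside]
    if len(verts) == 0:
        return np.empty((0, system.n))
    caps = verts @ A.T + eta
    return chromaticity(caps)


def gamut_metric(system: StimulationSystem, intensity_level: float | None = None,
                 locus_step: float = 1.0) -> float:
    """Fraction of the animal's chromaticity diagram reachable by the system.

    Ratio of hull measures: reachable chromaticities over the hull of the
    single-wavelength locus (the perfect system).  With ``intensity_level``
    the reachable set is restricted to intensities x with sum(A x) equal to
    that total relative capture, so the metric shrinks near the system's
    intensity ceiling.
    """
    if system.n < 2:
        raise ValueError("gamut metric requires at least 2 receptors")
    # Locus and system chromaticities must live in the same (von Kries
    # adapted) space for the ratio to be meaningful.
    _, locus = spectral_locus(system.receptors, step=locus_step,
                              adaptation=system.vk_denominator)
    perfect = _hull_measure(locus)
    if perfect <= 0:
        raise ValueError("degenerate spectral locus: receptors indistinguishable")
    pts = _reachable_chromaticities(system, intensity_level)
    if len(pts) == 0:
        return 0.0
    return min(_hull_measure(pts) / perfect, 1.0)


def rank_source_sets(receptors: ReceptorSet, candidates: Sequence[LightSource],
                     k: int, background: Spectrum | np.ndarray | None = None,
                     intensity_level: float | None = None):
    """All k-subsets of a candidate bank ranked by gamut metric (descending).

    Exhaustive enumeration; ties broken lexicographically by source names.
    Returns a list of ``(names_tuple, metric)`` pairs.
    """
    candidates = list(candidates)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds bank size {len(candidates)}")
    if background is not None and not isinstance(background, Spectrum):
        # an intensity vector over the full bank cannot be subset; convert
        # it to the equivalent background spectrum once
        x_b = np.asarray(background, dtype=float)
        if x_b.shape != (len(candidates),):
            raise ValueError("background intensities must match the bank size")
        mix = candidates[0].spectrum.scaled(x_b[0])
        for src, xb in zip(candidates[1:], x_b[1:]):
            mix = mix + src.spectrum.scaled(xb)
        background = mix
    results = []
    for combo in itertools.combinations(sorted(candidates, key=lambda s: s.name), k):
        sys_k = StimulationSystem(list(combo), receptors, background)
        names = tuple(s.name for s in combo)
        results.append((names, gamut_metric(sys_k, intensity_level)))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results
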