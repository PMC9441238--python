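"""Hyperspectral-image reconstruction with fewer projector subframes than
light sources.

The capture image Q (receptors x pixels) is factorized with non-negative
matrix factorization to initialize per-subframe source intensities X
(sources x subframes) and pixel masks P (subframes x pixels, in [0, 1]).
X and P are then refined by alternating bounded least squares on the
excitation-space residual E - f(A X P + eta); each half-step starts from
the current value, so the objective never increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .fitting import FitProblem, fit
from .receptors import ReceptorSet, capture, relative_capture
from .spectral import Spectrum, SpectralError, WavelengthGrid, trapezoid_weights
from .system import StimulationSystem

__all__ = [
    "HyperspectralImage",
    "CaptureImage",
    "image_captures",
    "fit_subframes",
    "export_subframes",
    "SubframeDecomposition",
]


@dataclass(frozen=True)
class HyperspectralImage:
    """A per-pixel spectral cube: (height*width, wavelengths) photon flux."""

    height: int
    width: int
    grid: WavelengthGrid
    cube: np.ndarray  # (pixels, len(grid)), row-major pixels, origin top-left

    def __post_init__(self) -> None:
        cube = np.asarray(self.cube, dtype=float)
        if cube.shape != (self.height * self.width, len(self.grid)):
            raise SpectralError(
                f"cube shape {cube.shape} does not match "
                f"{self.height * self.width} pixels x {len(self.grid)} bands"
            )
        if np.any(cube < 0) or not np.all(np.isfinite(cube)):
            raise SpectralError("cube must be non-negative and finite")
        object.__setattr__(self, "cube", cube)

    @property
    def pixels(self) -> int:
        return self.height * self.width

    def pixel_spectrum(self, idx: int) -> Spectrum:
        return Spectrum(self.grid, self.cube[idx])


@dataclass
class CaptureImage:
    """Relative captures and target excitations of an image."""

    Q: np.ndarray          # (n receptors, pixels) total relative captures
    E: np.ndarray          # (n receptors, pixels) target excitations f(Q)
    height: int
    width: int


def _interp_matrix(src: WavelengthGrid, dst: WavelengthGrid) -> np.ndarray:
    """W with W @ values == np.interp(dst, src, values, left=0, right=0)."""
    s, d = src.wavelengths, dst.wavelengths
    W = np.zeros((d.size, s.size))
    idx = np.searchsorted(s, d, side="right") - 1
    inside = (d >= s[0]) & (d <= s[-1])
    idx = np.clip(idx, 0, s.size - 2)
    frac = (d - s[idx]) / (s[idx + 1] - s[idx])
    rows = np.arange(d.size)[inside]
    W[rows, idx[inside]] = 1 - frac[inside]
    W[rows, idx[inside] + 1] = frac[inside]
    return W


def image_captures(image: HyperspectralImage, receptors: ReceptorSet,
                   background: Spectrum | np.ndarray) -> CaptureImage:
    """Per-pixel von Kries relative captures and excitations of a cube.

    Each pixel spectrum is resampled onto the receptor grid and integrated
    there — the same convention as :func:`chromstim.capture` — but through a
    single interpolation matrix instead of a per-pixel loop.
    """
    S = receptors.sensitivity_matrix()
    w = trapezoid_weights(receptors.grid)
    if image.grid == receptors.grid:
        cube_on_grid = image.cube
    else:
        W = _interp_matrix(image.grid, receptors.grid)
        cube_on_grid = image.cube @ W.T
    raw = (S * w) @ cube_on_grid.T  # (n, pixels) light-induced captures
    if isinstance(background, Spectrum):
        Qb = capture(receptors, background)
    else:
        Qb = np.asarray(background, dtype=float)
    denom = Qb + receptors.epsilon
    if np.any(denom <= 0):
        raise ValueError("background capture + epsilon must be positive")
    Q = (raw + receptors.epsilon[:, None]) / denom[:, None]
    E = receptors.transform(Q)
    return CaptureImage(Q=Q, E=E, height=image.height, width=image.width)


@dataclass
class SubframeDecomposition:
    """Source intensities X and pixel masks P reconstructing a capture image."""

    X: np.ndarray               # (sources, subframes), within [lower, upper]
    P: np.ndarray               # (subframes, pixels), within [0, 1]
    r2: np.ndarray              # per-receptor R^2 in excitation space
    iterations: int
    objective_trace: list[float] = field(default_factory=list)
    perfect_fit: bool = False   # set when residual ~ 0 with zero target variance

    def reconstruction(self, system: StimulationSystem) -> np.ndarray:
        """Excitation image f(A X P + eta) implied by the decomposition."""
        q = system.A @ self.X @ self.P + system.eta[:, None]
        return system.transform(q)


def _excitation_sse(system: StimulationSystem, X: np.ndarray, P: np.ndarray,
                    E: np.ndarray) -> float:
    q = system.A @ X @ P + system.eta[:, None]
    return float(np.sum((system.transform(q) - E) ** 2))


def _update_X(system: StimulationSystem, X: np.ndarray, P: np.ndarray,
              E: np.ndarray) -> np.ndarray:
    """Refit all source intensities with masks fixed (bounded trf)."""
    m, k = X.shape
    A, eta = system.A, system.eta
    transform = system.transform
    # bounds follow the row-major ravel of (m, k): repeat per source
    lo = np.repeat(system.lower, k)
    hi = np.repeat(system.upper, k)

    def resid(xflat: np.ndarray) -> np.ndarray:
        q = A @ xflat.reshape(m, k) @ P + eta[:, None]
        return (transform(q) - E).ravel()

    x0 = np.clip(X.ravel(order="C"), lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        ftol=1e-10, xtol=1e-10)
    X_new = sol.x.reshape(m, k)
    if _excitation_sse(system, X_new, P, E) > _excitation_sse(system, X, P, E):
        return X
    return X_new


def _update_P(system: StimulationSystem, X: np.ndarray, P: np.ndarray,
              E: np.ndarray) -> np.ndarray:
    """Refit every pixel's mask column with intensities fixed.

    Each pixel is an independent small bounded least-squares problem on
    B p + eta ~ finv-target, solved in excitation space starting from the
    pixel's current mask (monotone per pixel).
    """
    B = system.A @ X  # (n, k) effective capture matrix of the subframes
    eta = system.eta
    transform = system.transform
    k = X.shape[1]
    P_new = P.copy()
    for j in range(P.shape[1]):
        target = E[:, j]

        def resid(p: np.ndarray) -> np.ndarray:
            return transform(np.maximum(B @ p + eta, 1e-300)) - target

        p0 = np.clip(P[:, j], 0.0, 1.0)
        sol = least_squares(resid, p0, bounds=(np.zeros(k), np.ones(k)),
                            method="trf", ftol=1e-10, xtol=1e-10)
        if np.sum(resid(sol.x) ** 2) <= np.sum(resid(p0) ** 2):
            P_new[:, j] = sol.x
    return P_new


def fit_subframes(captures: CaptureImage, system: StimulationSystem,
                  k: int, max_iter: int = 50, tol: float = 1e-8,
                  fit_tol: float = 1e-6, nmf_seed: int = 0) -> SubframeDecomposition:
    """Decompose a capture image into k subframes of mixed sources.

    NMF of Q initializes masks (each subframe mask normalized so its
    maximum is 1, keeping the matching capture column reachable) and
    per-subframe intensities (each NMF capture column fitted through the
    standard excitation solver); alternating bounded least squares then
    refines X and P until the relative objective change drops below
    ``tol``.  The X*c / P/c scale ambiguity is canonicalized between
    iterations by renormalizing mask maxima to 1 where the intensity
    bounds allow.
    """
    if k <= 0:
        raise ValueError("number of subframes must be >= 1")
    Q, E = captures.Q, captures.E
    n, p = Q.shape
    if n != system.n:
        raise ValueError("capture image and system receptor counts differ")
    # --- initialization ------------------------------------------------
    nmf = NMF(n_components=k, init="nndsvda" if k > 1 else "random",
              random_state=nmf_seed, max_iter=5000, tol=1e-8)
    with warnings.catch_warnings():
        # the factorization is only an initialization; a slightly
        # unconverged NMF is refined by the alternation anyway
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = nmf.fit_transform(np.maximum(Q, 0))   # (n, k)
    H = nmf.components_                           # (k, p)
    scale = H.max(axis=1)
    dead = scale <= 0
    scale[dead] = 1.0
    H[dead] = 0.5
    P = np.clip(H / scale[:, None], 0.0, 1.0)
    Q0 = W * scale[None, :]
    X = np.zeros((system.m, k))
    for c in range(k):
        q_col = np.maximum(Q0[:, c], system.eta + 1e-12)
        target_e = system.transform(q_col)
        X[:, c] = fit(FitProblem(system, target_e)).x

    def rebalance(X, P):
        for c in range(k):
            mx = P[c].max()
            if mx > 0 and mx != 1.0 and np.all(
                    X[:, c] * mx <= system.upper + 1e-12) and np.all(
                    X[:, c] * mx >= system.lower - 1e-12):
                X[:, c] = np.clip(X[:, c] * mx, system.lower, system.upper)
                P[c] = P[c] / mx
        return X, P

    # --- alternating refinement ----------------------------------------
    # Stop on a good fit (residual a negligible fraction of the target
    # variance) or when the objective stalls; alternating least squares
    # zigzags forever at tiny amplitude otherwise.
    ss_total = float(np.sum((E - E.mean(axis=1, keepdims=True)) ** 2))
    trace = [_excitation_sse(system, X, P, E)]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        X = _update_X(system, X, P, E)
        P = _update_P(system, X, P, E)
        X, P = rebalance(X, P)
        trace.append(_excitation_sse(system, X, P, E))
        prev, cur = trace[-2], trace[-1]
        if cur <= fit_tol * max(ss_total, 1e-300):
            break
        if prev == 0 or abs(prev - cur) <= tol * max(prev, 1e-300):
            break
    # --- goodness of fit ------------------------------------------------
    recon = system.transform(system.A @ X @ P + system.eta[:, None])
    ss_res = np.sum((E - recon) ** 2, axis=1)
    ss_tot = np.sum((E - E.mean(axis=1, keepdims=True)) ** 2, axis=1)
    perfect = False
    r2 = np.empty(n)
    for i in range(n):
        if ss_tot[i] == 0:
            r2[i] = 1.0 if ss_res[i] <= 1e-12 else 0.0
            perfect = perfect or ss_res[i] <= 1e-12
        else:
            r2[i] = 1.0 - ss_res[i] / ss_tot[i]
    return SubframeDecomposition(X=X, P=P, r2=r2, iterations=iterations,
                                 objective_trace=trace, perfect_fit=perfect)


def export_subframes(decomposition: SubframeDecomposition, bit_depth: int = 8):
    """Quantized masks and the per-subframe intensity table.

    Masks are rounded half-up to ``2**bit_depth - 1`` levels, bounding the
    per-pixel quantization error by 1 / 2**(bit_depth+1) of full scale.
    Returns ``(masks, intensities)`` with masks as unsigned integers.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    levels = 2 ** bit_depth - 1
    # round-half-up, not banker's rounding
    masks = np.floor(decomposition.P * levels + 0.5).astype(
        np.uint8 if bit_depth == 8 else np.uint16)
    return masks, decomposition.X.copy()
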