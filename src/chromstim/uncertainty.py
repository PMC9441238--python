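"""Uncertainty in spectral sensitivities: capture-variance estimation,
first-order propagation to excitations, variance-minimizing refitting, and
fitting against a weighted set of sampled sensitivities."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .fitting import (
    DELTA_FIT,
    FitProblem,
    FitResult,
    IN_GAMUT_TOL,
    _solve_core,
    fit,
)
from .receptors import Photoreceptor, ReceptorSet, capture
from .spectral import SensitivityCurve, Spectrum
from .system import LightSource, StimulationSystem, build_capture_matrix

__all__ = [
    "SensitivityPrior",
    "build_variance_matrix",
    "propagate_variance",
    "fit_min_variance",
    "fit_with_sampled_sensitivities",
    "UncertainFitResult",
]


@dataclass
class SensitivityPrior:
    """A weighted sample of receptor sets representing sensitivity uncertainty."""

    samples: Sequence[ReceptorSet]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(self.samples) < 2:
            raise ValueError("a prior needs at least 2 sensitivity samples")
        names = self.samples[0].names
        for s in self.samples[1:]:
            if s.names != names:
                raise ValueError("all prior samples must share receptor names/order")
        k = len(self.samples)
        if self.weights is None:
            self.weights = np.full(k, 1.0 / k)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (k,) or np.any(self.weights < 0):
                raise ValueError("weights must be non-negative, one per sample")
            total = self.weights.sum()
            if abs(total - 1.0) > 1e-12:
                raise ValueError("prior weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.samples)

    def expected(self) -> ReceptorSet:
        """Mean receptor set: weighted average of sensitivity values."""
        ref = self.samples[0]
        mean_vals = np.zeros((ref.n, len(ref.grid)))
        for w, s in zip(self.weights, self.samples):
            grid_match = s.grid == ref.grid
            for i, r in enumerate(s.receptors):
                vals = r.sensitivity.values if grid_match else np.interp(
                    ref.grid.wavelengths, r.sensitivity.wavelengths,
                    r.sensitivity.values, left=0, right=0)
                mean_vals[i] += w * vals
        receptors = [
            Photoreceptor(r.name, SensitivityCurve(ref.grid, mean_vals[i],
                                                   name=r.name),
                          r.epsilon, r.abs_sensitivity)
            for i, r in enumerate(ref.receptors)
        ]
        return ReceptorSet(receptors, transform=ref.transform, grid=ref.grid)


def build_variance_matrix(prior: SensitivityPrior,
                          sources: Sequence[LightSource],
                          background: Spectrum | np.ndarray | None) -> np.ndarray:
    """Weighted empirical variance of unit-flux relative captures across the
    prior samples: Sigma[i, j] = Var_s(q_{i,j}).
    """
    mats = np.stack([
        build_capture_matrix(s, sources, background)[0] for s in prior.samples
    ])  # (k, n, m)
    w = prior.weights[:, None, None]
    mean = (w * mats).sum(axis=0)
    return (w * (mats - mean) ** 2).sum(axis=0)


def propagate_variance(system: StimulationSystem, sigma2: np.ndarray,
                       x: np.ndarray, transform=None) -> float:
    """First-order total excitation variance theta^2 = f'(Ax+eta)^2 . Sigma x^2."""
    transform = transform or system.transform
    x = np.asarray(x, dtype=float)
    q = system.relative_captures(x)
    if transform.kind == "log" and np.any(q <= 0):
        raise ValueError("log derivative undefined at non-positive capture")
    fp2 = transform.fprime(q) ** 2
    return float(fp2 @ (np.asarray(sigma2, dtype=float) @ (x ** 2)))


@dataclass
class UncertainFitResult:
    """Variance-minimized fit with its residual budget and provenance."""

    x: np.ndarray
    theta2: float
    delta: float
    base: FitResult
    fell_back: bool = False

    @property
    def residual(self) -> float:
        return self._residual

    def __post_init__(self) -> None:
        self._residual = self.base.residual


def fit_min_variance(problem: FitProblem, sigma2: np.ndarray,
                     delta_slack: float = DELTA_FIT) -> UncertainFitResult:
    """Minimize propagated variance subject to not degrading the fit.

    Runs the standard two-step fit, then minimizes theta^2 over the bounded
    set where the weighted excitation residual stays within the achieved
    residual plus ``delta_slack``.  Falls back to the standard fit when the
    variance step cannot improve feasibly.
    """
    base = fit(problem)
    sys = problem.system
    transform = sys.transform
    w = problem.weights
    delta = base.residual ** 2 + delta_slack
    sigma2 = np.asarray(sigma2, dtype=float)

    def theta2(x: np.ndarray) -> float:
        return propagate_variance(sys, sigma2, x, transform)

    def resid_sq(x: np.ndarray) -> float:
        e = transform(sys.relative_captures(x))
        return float(np.sum((w * (e - problem.target)) ** 2))

    base_theta2 = theta2(base.x)
    if np.all(sigma2 == 0):
        return UncertainFitResult(base.x, 0.0, delta, base)
    cons = [{"type": "ineq", "fun": lambda x: delta - resid_sq(x)}]
    sol = minimize(theta2, base.x, method="SLSQP",
                   bounds=list(zip(problem.lower, problem.upper)),
                   constraints=cons, options={"maxiter": 500, "ftol": 1e-14})
    x = np.clip(sol.x, problem.lower, problem.upper)
    if resid_sq(x) <= delta * (1 + 1e-9) + 1e-15 and theta2(x) <= base_theta2:
        return UncertainFitResult(x, theta2(x), delta, base)
    return UncertainFitResult(base.x, base_theta2, delta, base, fell_back=True)


def fit_with_sampled_sensitivities(prior: SensitivityPrior,
                                   system: StimulationSystem,
                                   target_spectrum: Spectrum,
                                   background: Spectrum | np.ndarray | None = None,
                                   weights: np.ndarray | None = None,
                                   min_variance: bool = False,
                                   delta_slack: float = DELTA_FIT) -> FitResult:
    """Fit a target spectrum while averaging over sensitivity samples.

    Each prior sample contributes its own block of n receptors: the capture
    matrix, baseline vector and per-sample target excitations are stacked
    into a (k*n)-row problem whose rows are weighted by the sample's prior
    probability.  Targets must be spectra — per-sample excitations of a bare
    excitation vector are undefined.

    With ``min_variance=True`` a variance-minimization step (using the
    variance matrix computed from the prior) follows the stacked fit.
    """
    if not isinstance(target_spectrum, Spectrum):
        raise TypeError(
            "fit_with_sampled_sensitivities needs a target Spectrum; per-sample "
            "target excitations are undefined for a bare excitation vector"
        )
    background = system.background if background is None else background
    transform = system.transform
    n = system.n
    blocks_A, blocks_eta, blocks_e, blocks_w = [], [], [], []
    base_w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    for pw, rset in zip(prior.weights, prior.samples):
        A_s, eta_s = build_capture_matrix(rset, system.sources, background)
        Q = capture(rset, target_spectrum)
        if isinstance(background, Spectrum):
            Qb = capture(rset, background)
        elif background is None:
            Qb = np.zeros(n)
        else:
            raw = np.stack([capture(rset, s.spectrum) for s in system.sources],
                           axis=1)
            Qb = raw @ np.asarray(background, dtype=float)
        q_t = (Q + rset.epsilon) / (Qb + rset.epsilon)
        blocks_A.append(A_s)
        blocks_eta.append(eta_s)
        blocks_e.append(transform(q_t))
        blocks_w.append(base_w * np.sqrt(pw))
    A = np.vstack(blocks_A)
    eta = np.concatenate(blocks_eta)
    e = np.concatenate(blocks_e)
    w = np.concatenate(blocks_w)
    x, nfev, stage, _ = _solve_core(A, eta, e, transform, w,
                                    system.lower, system.upper)
    resid = float(np.linalg.norm(w * (transform(A @ x + eta) - e)))
    result = FitResult(x=x, excitations=transform(system.relative_captures(x)),
                       residual=resid, in_gamut=resid <= IN_GAMUT_TOL,
                       stage="stacked:" + stage, iterations=nfev)
    if not min_variance:
        return result
    sigma2 = build_variance_matrix(prior, system.sources, background)
    if np.all(sigma2 == 0):
        return result
    delta = resid ** 2 + delta_slack

    def theta2(xv):
        return propagate_variance(system, sigma2, xv, transform)

    def resid_sq(xv):
        return float(np.sum((w * (transform(A @ xv + eta) - e)) ** 2))

    cons = [{"type": "ineq", "fun": lambda xv: delta - resid_sq(xv)}]
    sol = minimize(theta2, x, method="SLSQP",
                   bounds=list(zip(system.lower, system.upper)),
                   constraints=cons, options={"maxiter": 500, "ftol": 1e-14})
    xv = np.clip(sol.x, system.lower, system.upper)
    if resid_sq(xv) <= delta * (1 + 1e-9) + 1e-15 and theta2(xv) <= theta2(x):
        resid2 = np.sqrt(resid_sq(xv))
        return FitResult(x=xv,
                         excitations=transform(system.relative_captures(xv)),
                         residual=resid2, in_gamut=resid2 <= IN_GAMUT_TOL,
                         stage=result.stage + "+min-variance",
                         iterations=nfev + sol.nit)
    return result
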