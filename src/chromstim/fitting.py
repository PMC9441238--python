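"""Constrained fitting of source intensities to target excitations.

The solver is a deterministic two-step procedure.  Step one fits the
relative captures with bounded linear least squares (convex, unique
residual).  If the transform is the identity, or the step-one residual is
already below tolerance (the target is in gamut), the procedure stops
there.  Otherwise step two refines the solution with bounded nonlinear
least squares (trust-region reflective) on the excitation-space residual,
initialized at the step-one solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import least_squares, lsq_linear, minimize

from .receptors import Transform, get_transform
from .system import StimulationSystem

__all__ = [
    "FitProblem",
    "FitResult",
    "fit",
    "fit_batch",
    "resolve_underdetermined",
    "in_gamut",
    "gamut_correct",
    "silent_substitution",
    "metamers",
]

STEP1_TOL = 1e-10      # step-one residual below this: linear solution accepted
IN_GAMUT_TOL = 1e-8    # residual threshold of the in-gamut feasibility test
STEP2_FTOL = 1e-12
DELTA_FIT = 1e-9       # residual slack for secondary objectives


@dataclass
class FitProblem:
    """A target-excitation fitting problem on a stimulation system."""

    system: StimulationSystem
    target: np.ndarray                     # excitations e, shape (n,)
    weights: np.ndarray | None = None      # w >= 0, not all zero
    lower: np.ndarray | None = None        # default: system source bounds
    upper: np.ndarray | None = None
    objective: str = "min_norm"            # secondary objective selector

    def __post_init__(self) -> None:
        sys = self.system
        self.target = np.asarray(self.target, dtype=float)
        if self.target.shape != (sys.n,):
            raise ValueError(f"target must have shape ({sys.n},)")
        if np.any(~np.isfinite(self.target)):
            raise ValueError("target excitations must be finite")
        self.weights = (np.ones(sys.n) if self.weights is None
                        else np.asarray(self.weights, dtype=float))
        if self.weights.shape != (sys.n,) or np.any(self.weights < 0):
            raise ValueError("weights must be a non-negative length-n vector")
        if not np.any(self.weights > 0):
            raise ValueError("weights must not all be zero")
        self.lower = (sys.lower if self.lower is None
                      else np.asarray(self.lower, dtype=float))
        self.upper = (sys.upper if self.upper is None
                      else np.asarray(self.upper, dtype=float))
        if np.any(self.lower > self.upper):
            raise ValueError("infeasible bounds: lower > upper")
        if np.any(self.lower < 0):
            raise ValueError("intensities cannot be negative")


@dataclass
class FitResult:
    """Fitted intensities with residuals and provenance."""

    x: np.ndarray
    excitations: np.ndarray
    residual: float                  # weighted residual norm in excitation space
    in_gamut: bool
    stage: str                       # 'linear-only' or 'two-step'
    iterations: int = 0
    converged: bool = True
    notes: str = ""


def _weighted_residual(system: StimulationSystem, x: np.ndarray,
                       target: np.ndarray, w: np.ndarray,
                       transform: Transform) -> float:
    e = transform(system.relative_captures(x))
    return float(np.linalg.norm(w * (e - target)))


def _solve_core(A: np.ndarray, eta: np.ndarray, target: np.ndarray,
                transform: Transform, w: np.ndarray,
                lo: np.ndarray, hi: np.ndarray):
    """Two-step solve on raw matrices; returns (x, nfev, stage)."""
    # Step 1: bounded linear least squares on relative captures.
    b = transform.finv(target) - eta
    W = w[:, None]
    res1 = lsq_linear(W * A, w * b, bounds=(lo, hi), method="bvls",
                      tol=STEP1_TOL)
    x1 = np.clip(res1.x, lo, hi)
    lin_resid = float(np.linalg.norm(w * (A @ x1 - b)))
    if transform.kind == "identity" or lin_resid <= IN_GAMUT_TOL:
        return x1, int(res1.nit), "linear-only", True
    # Step 2: trust-region-reflective refinement in excitation space.
    def resid(x: np.ndarray) -> np.ndarray:
        return w * (transform.f(A @ x + eta) - target)

    def jac(x: np.ndarray) -> np.ndarray:
        fp = transform.fprime(A @ x + eta)
        return (w * fp)[:, None] * A

    res2 = least_squares(resid, x1, jac=jac, bounds=(lo, hi), method="trf",
                         ftol=STEP2_FTOL, xtol=STEP2_FTOL, gtol=STEP2_FTOL)
    x2 = np.clip(res2.x, lo, hi)
    # Keep whichever solution is better; trf never worsens its start in
    # practice, but guard against pathological stalls.
    if np.linalg.norm(resid(x2)) > np.linalg.norm(resid(x1)):
        x2 = x1
    return x2, int(res1.nit) + int(res2.nfev), "two-step", False


def fit(problem: FitProblem) -> FitResult:
    """Solve min ||w * (f(Ax + eta) - e)||^2 subject to bounds.

    Deterministic: repeated calls with identical inputs return identical x.
    """
    sys = problem.system
    transform = sys.transform
    x, nfev, stage, _ = _solve_core(sys.A, sys.eta, problem.target,
                                    transform, problem.weights,
                                    problem.lower, problem.upper)
    resid = _weighted_residual(sys, x, problem.target, problem.weights, transform)
    return FitResult(
        x=x,
        excitations=transform(sys.relative_captures(x)),
        residual=resid,
        in_gamut=resid <= IN_GAMUT_TOL,
        stage=stage,
        iterations=nfev,
    )


def fit_batch(system: StimulationSystem, targets: np.ndarray,
              weights: np.ndarray | None = None, **kwargs) -> list[FitResult]:
    """Fit each row of ``targets`` independently."""
    return [fit(FitProblem(system, t, weights=weights, **kwargs)) for t in targets]


# ---------------------------------------------------------------------------
# Underdetermined systems: secondary objectives over the optimal set.


def _secondary_objective(selector: str, m: int):
    if selector == "min_norm":
        return lambda x: float(x @ x), lambda x: 2 * x
    if selector == "min_diff":
        def f(x):
            d = x[:, None] - x[None, :]
            return float(np.sum(d ** 2)) / 2
        def g(x):
            return 2 * (m * x - x.sum())
        return f, g
    for prefix, sign in (("max_source:", -1.0), ("min_source:", 1.0)):
        if selector.startswith(prefix):
            j = int(selector[len(prefix):])
            if not 0 <= j < m:
                raise ValueError(f"source index {j} out of range for m={m}")
            e_j = np.zeros(m)
            e_j[j] = sign
            return (lambda x, e_j=e_j: float(e_j @ x),
                    lambda x, e_j=e_j: e_j)
    raise ValueError(
        f"unknown secondary objective {selector!r}; use 'min_norm', 'min_diff', "
        f"'max_source:<j>' or 'min_source:<j>'"
    )


def resolve_underdetermined(problem: FitProblem,
                            delta_fit: float = DELTA_FIT) -> FitResult:
    """Among intensities achieving the minimal residual (within ``delta_fit``),
    return the one optimizing the problem's secondary objective.

    The default objective is the smallest L2 norm; alternatives maximize or
    minimize a particular source or minimize pairwise intensity differences.
    The primary fit is never degraded beyond the slack.
    """
    base = fit(problem)
    sys = problem.system
    transform = sys.transform
    w = problem.weights
    obj, grad = _secondary_objective(problem.objective, sys.m)
    budget = base.residual ** 2 + delta_fit

    def resid_sq(x: np.ndarray) -> float:
        return _weighted_residual(sys, x, problem.target, w, transform) ** 2

    if base.in_gamut:
        # The optimal set is the affine slice A x = f^-1(e) - eta within
        # bounds; enforce it exactly rather than through the slack ball.
        b = transform.finv(problem.target) - sys.eta
        cons = [{"type": "eq", "fun": lambda x: sys.A @ x - b,
                 "jac": lambda x: sys.A}]
    else:
        cons = [{"type": "ineq", "fun": lambda x: budget - resid_sq(x)}]
    bounds = list(zip(problem.lower, problem.upper))
    sol = minimize(obj, base.x, jac=grad, method="SLSQP", bounds=bounds,
                   constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-14})
    x = np.clip(sol.x, problem.lower, problem.upper)
    # Accept only if it honours the residual budget and improves the objective.
    if resid_sq(x) <= budget * (1 + 1e-9) + 1e-15 and obj(x) <= obj(base.x):
        resid = np.sqrt(max(resid_sq(x), 0.0))
        return FitResult(x=x, excitations=transform(sys.relative_captures(x)),
                         residual=resid, in_gamut=resid <= IN_GAMUT_TOL,
                         stage=base.stage + "+secondary",
                         iterations=base.iterations + sol.nit,
                         converged=bool(sol.success))
    base.notes = "secondary objective step rejected; returning primary fit"
    return base


# ---------------------------------------------------------------------------
# Gamut membership and gamut correction of capture batches.


def in_gamut(system: StimulationSystem, capture_target: np.ndarray,
             tol: float = IN_GAMUT_TOL) -> bool:
    """Whether a total relative capture vector q_t is reachable within bounds."""
    t = np.asarray(capture_target, dtype=float)
    res = lsq_linear(system.A, t - system.eta,
                     bounds=(system.lower, system.upper), method="bvls",
                     tol=STEP1_TOL)
    return float(np.linalg.norm(system.A @ res.x + system.eta - t)) <= tol


def _scale_interval(system: StimulationSystem,
                    target: np.ndarray) -> tuple[float, float] | None:
    """The interval of scales s >= 0 with s * target reachable.

    The reachable capture set {A x + eta : l <= x <= u} is convex, so its
    intersection with the ray through a target is an interval; found by two
    LPs over (x, s).  Returns None when the target's chromaticity is never
    reachable at any scale.
    """
    from scipy.optimize import linprog

    m = system.m
    A_eq = np.hstack([system.A, -target[:, None]])
    b_eq = -system.eta
    bounds = [(lo, hi) for lo, hi in zip(system.lower, system.upper)]
    bounds.append((0.0, None))
    c = np.zeros(m + 1)
    c[-1] = 1.0
    lo_res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not lo_res.success:
        return None
    hi_res = linprog(-c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    s_hi = np.inf if hi_res.status == 3 else float(hi_res.x[-1])
    return float(lo_res.x[-1]), s_hi


def _best_common_scale(intervals, coverage: float) -> float:
    """Largest s <= 1 covered by the most per-target scale intervals.

    Stops early once ``coverage`` of the batch is reachable; candidate
    scales are the interval endpoints (clipped to (0, 1]).
    """
    finite = [iv for iv in intervals if iv is not None]
    if not finite:
        return 1.0
    cands = {1.0}
    for lo, hi in finite:
        if 0 < lo <= 1:
            cands.add(lo)
        if 0 < hi <= 1:
            cands.add(hi)
    eps = 1e-12
    best_s, best_cov = 1.0, -1
    need = int(np.ceil(coverage * len(intervals)))
    for s in sorted(cands, reverse=True):
        cov = sum(1 for iv in finite if iv[0] - eps <= s <= iv[1] + eps)
        if cov >= need:
            return s
        if cov > best_cov:
            best_s, best_cov = s, cov
    return best_s


def _project_to_gamut(system: StimulationSystem, point: np.ndarray,
                      anchor: np.ndarray, tol: float) -> np.ndarray:
    """Walk from ``point`` toward ``anchor`` until inside the gamut."""
    lo_t, hi_t = 0.0, 1.0  # 0 -> point, 1 -> anchor
    if in_gamut(system, point, tol):
        return point
    if not in_gamut(system, anchor, tol):
        # Anchor itself unreachable: fall back to bounded least-squares
        # projection (closest reachable capture).
        res = lsq_linear(system.A, point - system.eta,
                         bounds=(system.lower, system.upper), method="bvls")
        return system.A @ res.x + system.eta
    for _ in range(60):
        mid = (lo_t + hi_t) / 2
        cand = (1 - mid) * point + mid * anchor
        if in_gamut(system, cand, tol):
            hi_t = mid
        else:
            lo_t = mid
    return (1 - hi_t) * point + hi_t * anchor


def gamut_correct(targets: np.ndarray, system: StimulationSystem,
                  mode: str = "scale", coverage: float = 0.95,
                  tol: float = IN_GAMUT_TOL) -> np.ndarray:
    """Map a batch of total relative capture vectors into the system's gamut.

    ``scale``: one global multiplicative factor, chosen as large as possible
    so every target becomes reachable — chromaticities are preserved exactly.
    Raises when no single scale can work (some chromaticities are outside
    the gamut cone at every intensity).
    ``scale_and_project``: global scale until ``coverage`` of the batch is
    reachable, then project each remaining point toward the batch centroid
    until it enters the gamut.  Batches already in gamut are returned
    unchanged.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target batch")
    if np.any(targets < 0):
        raise ValueError("capture targets must be non-negative")
    feasible = np.array([in_gamut(system, t, tol) for t in targets])
    if feasible.all():
        return targets.copy()
    intervals = [_scale_interval(system, t) for t in targets]
    if mode == "scale":
        if any(iv is None for iv in intervals):
            raise ValueError(
                "some target chromaticities are unreachable at any intensity; "
                "use mode='scale_and_project'"
            )
        s_lo = max(iv[0] for iv in intervals)
        s_hi = min(iv[1] for iv in intervals)
        if s_lo > s_hi:
            raise ValueError(
                "no single scale brings every target into the gamut; "
                "use mode='scale_and_project'"
            )
        return targets * float(np.clip(1.0, s_lo, s_hi))
    if mode == "scale_and_project":
        s = _best_common_scale(intervals, coverage)
        scaled = targets * s
        centroid = scaled.mean(axis=0)
        out = scaled.copy()
        for i, t in enumerate(scaled):
            if not in_gamut(system, t, tol):
                out[i] = _project_to_gamut(system, t, centroid, tol)
        return out
    raise ValueError(f"unknown gamut correction mode {mode!r}")


# ---------------------------------------------------------------------------
# Silent substitution and metamers.


def silent_substitution(system: StimulationSystem, isolate: int,
                        contrast: float,
                        reference: np.ndarray | None = None,
                        tol: float = 1e-9):
    """A pair of intensity vectors modulating one receptor only.

    The reference stimulus reproduces the background (all relative captures
    one) unless ``reference`` captures are given.  The companion stimulus
    multiplies the isolated receptor's total relative capture by
    ``1 + contrast`` while holding every other receptor's capture equal to
    the reference within ``tol``.  Raises if the requested contrast is not
    reachable, reporting the largest achievable contrast.
    """
    if not 0 <= isolate < system.n:
        raise ValueError(f"receptor index {isolate} out of range")
    if np.linalg.matrix_rank(system.A) < system.n:
        raise ValueError("silent substitution requires a full-row-rank system")
    ref_target = (np.ones(system.n) if reference is None
                  else np.asarray(reference, dtype=float))

    def solve(target: np.ndarray):
        res = lsq_linear(system.A, target - system.eta,
                         bounds=(system.lower, system.upper), method="bvls",
                         tol=STEP1_TOL)
        err = float(np.linalg.norm(system.A @ res.x + system.eta - target))
        return res.x, err

    x_ref, err_ref = solve(ref_target)
    if err_ref > tol:
        raise ValueError("reference captures are not reachable within bounds")
    if contrast == 0:
        return x_ref.copy(), x_ref.copy()

    def stim_target(c: float) -> np.ndarray:
        t = ref_target.copy()
        t[isolate] = ref_target[isolate] * (1.0 + c)
        return t

    x_stim, err = solve(stim_target(contrast))
    if err > tol:
        lo_c, hi_c = 0.0, contrast
        for _ in range(60):
            mid = (lo_c + hi_c) / 2
            if solve(stim_target(mid))[1] <= tol:
                lo_c = mid
            else:
                hi_c = mid
        raise ValueError(
            f"contrast {contrast} infeasible for receptor {isolate}; "
            f"maximum achievable contrast is about {lo_c:.6g}"
        )
    return x_ref, x_stim


def metamers(system: StimulationSystem, capture_target: np.ndarray,
             count: int, tol: float = 1e-9, seed: int = 0):
    """``count`` distinct intensity vectors all producing ``capture_target``.

    Requires an underdetermined system (m > n).  For a one-dimensional
    solution set, the returned vectors span the feasible segment from end
    to end; higher-dimensional sets are explored along seeded random
    null-space directions through the minimum-norm solution.
    """
    t = np.asarray(capture_target, dtype=float)
    sys = system
    res = lsq_linear(sys.A, t - sys.eta, bounds=(sys.lower, sys.upper),
                     method="bvls", tol=STEP1_TOL)
    x0 = res.x
    if float(np.linalg.norm(sys.A @ x0 + sys.eta - t)) > tol:
        raise ValueError("target capture is out of gamut; no exact metamers exist")
    N = null_space(sys.A)
    if N.shape[1] == 0:
        if count > 1:
            raise ValueError("system is fully determined: only one solution exists")
        return np.array([x0])
    lo, hi = sys.lower, sys.upper

    def extent(x: np.ndarray, d: np.ndarray) -> tuple[float, float]:
        """Feasible step interval [t-, t+] along direction d from x."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = np.where(d != 0, (lo - x) / d, -np.inf)
            t_hi = np.where(d != 0, (hi - x) / d, np.inf)
        lo_steps = np.minimum(t_lo, t_hi)
        hi_steps = np.maximum(t_lo, t_hi)
        return float(lo_steps.max(initial=-np.inf)), float(hi_steps.min(initial=np.inf))

    if N.shape[1] == 1:
        d = N[:, 0]
        t_min, t_max = extent(x0, d)
        steps = np.linspace(t_min, t_max, count) if count > 1 else np.array([0.0])
        pts = x0[None, :] + steps[:, None] * d[None, :]
    else:
        rng = np.random.default_rng(seed)
        pts = [x0]
        while len(pts) < count:
            d = N @ rng.standard_normal(N.shape[1])
            nrm = np.linalg.norm(d)
            if nrm == 0:
                continue
            d /= nrm
            t_min, t_max = extent(x0, d)
            for step in (t_min, t_max):
                if len(pts) < count and np.isfinite(step) and step != 0:
                    pts.append(x0 + step * d)
        pts = np.array(pts[:count])
    pts = np.clip(pts, lo, hi)
    return pts
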