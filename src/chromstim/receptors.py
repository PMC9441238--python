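"""Photoreceptor capture model.

Implements light-induced photon capture, total absolute capture with a
baseline (dark) capture and gain, von Kries adaptation to a background
(relative capture), and the excitation transform applied to relative
captures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .spectral import (
    SensitivityCurve,
    Spectrum,
    SpectralError,
    WavelengthGrid,
    common_grid,
    resample,
    trapezoid_weights,
)

__all__ = [
    "Transform",
    "TRANSFORMS",
    "get_transform",
    "Photoreceptor",
    "ReceptorSet",
    "capture",
    "total_capture",
    "relative_capture",
    "excite",
]

DEFAULT_EPSILON = 1e-3  # uE; small baseline capture used throughout examples


@dataclass(frozen=True)
class Transform:
    """A monotone excitation transform f with inverse and derivative."""

    kind: str
    f: Callable[[np.ndarray], np.ndarray]
    finv: Callable[[np.ndarray], np.ndarray]
    fprime: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "log" and np.any(x <= 0):
            raise ValueError(
                "log transform requires strictly positive relative captures; "
                "use a baseline capture epsilon > 0"
            )
        return self.f(x)


TRANSFORMS: dict[str, Transform] = {
    "identity": Transform("identity", lambda x: np.asarray(x, float),
                          lambda y: np.asarray(y, float),
                          lambda x: np.ones_like(np.asarray(x, float))),
    "log": Transform("log", np.log, np.exp, lambda x: 1.0 / np.asarray(x, float)),
    # Hyperbolic response x / (1 + x): saturating, maps background 1 -> 0.5.
    "hyperbolic": Transform("hyperbolic",
                            lambda x: x / (1.0 + x),
                            lambda y: y / (1.0 - y),
                            lambda x: 1.0 / (1.0 + np.asarray(x, float)) ** 2),
}


def get_transform(kind: "str | Transform") -> Transform:
    if isinstance(kind, Transform):
        return kind
    try:
        return TRANSFORMS[kind]
    except KeyError:
        raise ValueError(
            f"unknown transform {kind!r}; choose from {sorted(TRANSFORMS)}"
        ) from None


@dataclass(frozen=True)
class Photoreceptor:
    """A single receptor: sensitivity curve, baseline capture and gain."""

    name: str
    sensitivity: SensitivityCurve
    epsilon: float = DEFAULT_EPSILON  # baseline (dark) capture, uE
    abs_sensitivity: float = 1.0      # gain C; usually unknown, default 1

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("baseline capture epsilon must be >= 0")
        if self.abs_sensitivity <= 0:
            raise ValueError("absolute sensitivity C must be > 0")


class ReceptorSet:
    """An ordered set of photoreceptors sharing a wavelength grid.

    On construction all sensitivities are resampled onto a common 1 nm grid
    spanning the union of their tabulated ranges.
    """

    def __init__(self, receptors: Sequence[Photoreceptor],
                 transform: "str | Transform" = "log",
                 grid: WavelengthGrid | None = None):
        receptors = list(receptors)
        if not receptors:
            raise ValueError("need at least one photoreceptor")
        names = [r.name for r in receptors]
        if len(set(names)) != len(names):
            raise ValueError(f"receptor names must be unique, got {names}")
        self.grid = grid or common_grid([r.sensitivity for r in receptors])
        self.receptors = tuple(
            Photoreceptor(r.name, resample(r.sensitivity, self.grid),
                          r.epsilon, r.abs_sensitivity)
            for r in receptors
        )
        self.transform = get_transform(transform)

    @property
    def n(self) -> int:
        return len(self.receptors)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.receptors]

    @property
    def epsilon(self) -> np.ndarray:
        return np.array([r.epsilon for r in self.receptors])

    @property
    def gains(self) -> np.ndarray:
        return np.array([r.abs_sensitivity for r in self.receptors])

    def sensitivity_matrix(self) -> np.ndarray:
        """(n, len(grid)) matrix of sensitivity values on the shared grid."""
        return np.stack([r.sensitivity.values for r in self.receptors])

    def with_transform(self, transform: "str | Transform") -> "ReceptorSet":
        return ReceptorSet(self.receptors, transform=transform, grid=self.grid)

    def __repr__(self) -> str:
        return (f"ReceptorSet({self.names}, transform={self.transform.kind!r}, "
                f"span={self.grid.span})")


def capture(receptors: ReceptorSet, stimulus: Spectrum) -> np.ndarray:
    """Light-induced capture Q_i = integral of S_i(lambda) I(lambda) dlambda."""
    stim = resample(stimulus, receptors.grid)
    w = trapezoid_weights(receptors.grid)
    return receptors.sensitivity_matrix() @ (w * stim.values)


def total_capture(receptors: ReceptorSet, Q: np.ndarray) -> np.ndarray:
    """Total absolute capture C * (Q + epsilon)."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("light-induced captures must be non-negative")
    return receptors.gains * (Q + receptors.epsilon)


def relative_capture(receptors: ReceptorSet, stimulus_Q: np.ndarray,
                     background_Q: np.ndarray, split: bool = False):
    """von Kries-adapted relative capture (Q_j + eps) / (Q_b + eps).

    With ``split=True`` returns ``(q, eta)`` where q is the light-induced
    part Q_j/(Q_b+eps) and eta the baseline part eps/(Q_b+eps); the total
    relative capture is q + eta.
    """
    stimulus_Q = np.asarray(stimulus_Q, dtype=float)
    background_Q = np.asarray(background_Q, dtype=float)
    denom = background_Q + receptors.epsilon
    if np.any(denom <= 0):
        raise ValueError(
            "background capture + epsilon must be positive for every receptor; "
            "set a baseline capture epsilon > 0 for dark backgrounds"
        )
    q = stimulus_Q / denom
    eta = receptors.epsilon / denom
    if split:
        return q, eta
    return q + eta


def excite(receptors: ReceptorSet, relative: np.ndarray) -> np.ndarray:
    """Excitation e = f(q + eta)."""
    return receptors.transform(np.asarray(relative, dtype=float))
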