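"""Wavelength-gridded signals: spectra, sensitivity curves, quadrature and I/O.

All wavelengths are in nanometres.  Spectra carry photon-flux density in
uE nm^-1 (E = mol photons s^-1 m^-2); sensitivity curves are dimensionless.
Integration uses the trapezoid rule on the stored grid, which is exact for
the piecewise-linear interpolation model used throughout.

Signals evaluate to zero outside their tabulated span.  This matters for
captures: a receptor contributes nothing where its sensitivity was not
measured, and a source emits nothing outside its tabulated range.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro, c as _c, h as _h

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SensitivityCurve",
    "resample",
    "integrate",
    "read_spectra",
    "write_spectra",
    "common_grid",
    "energy_to_photon_flux",
]


class SpectralError(ValueError):
    """Raised for invalid spectral data or incompatible grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing grid of wavelengths (nm)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise SpectralError("wavelength grid needs at least 2 points")
        if not np.all(np.isfinite(wl)):
            raise SpectralError("wavelength grid contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise SpectralError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths, other.wavelengths)

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    @classmethod
    def regular(cls, start: float, stop: float, step: float = 1.0) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass(frozen=True)
class _Signal:
    grid: WavelengthGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise SpectralError(
                f"values shape {v.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise SpectralError("signal contains non-finite values")
        if np.any(v < 0):
            raise SpectralError("signal values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def integrate(self) -> float:
        return integrate(self)

    def _replace_values(self, values: np.ndarray, grid: WavelengthGrid | None = None):
        return type(self)(**{**self.__dict__, "values": values, "grid": grid or self.grid})


@dataclass(frozen=True)
class Spectrum(_Signal):
    """Photon-flux density over a wavelength grid (uE nm^-1)."""

    def scaled(self, factor: float) -> "Spectrum":
        if factor < 0:
            raise SpectralError("scale factor must be non-negative")
        return self._replace_values(self.values * factor)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if self.grid != other.grid:
            g = common_grid([self, other])
            return resample(self, g) + resample(other, g)
        return Spectrum(self.grid, self.values + other.values, name=self.name)


@dataclass(frozen=True)
class SensitivityCurve(_Signal):
    """Dimensionless relative spectral sensitivity.

    ``normalization`` records the stated convention ('peak', 'area' or 'none');
    the values are never rescaled implicitly.
    """

    normalization: str = "peak"

    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.values))])


def common_grid(signals: Iterable[_Signal], step: float = 1.0) -> WavelengthGrid:
    """Regular grid (default 1 nm) over the union span of the inputs."""
    signals = list(signals)
    if not signals:
        raise SpectralError("no signals given")
    lo = min(s.grid.span[0] for s in signals)
    hi = max(s.grid.span[1] for s in signals)
    return WavelengthGrid.regular(lo, hi, step)


def resample(signal: _Signal, target: WavelengthGrid) -> _Signal:
    """Linearly interpolate ``signal`` onto ``target``; zero outside its span.

    Raises if the grids do not overlap at all.
    """
    if signal.grid == target:
        return signal
    lo, hi = signal.grid.span
    tlo, thi = target.span
    if thi < lo or tlo > hi:
        raise SpectralError(
            f"target grid [{tlo}, {thi}] does not overlap source span [{lo}, {hi}]"
        )
    vals = np.interp(target.wavelengths, signal.wavelengths, signal.values,
                     left=0.0, right=0.0)
    return signal._replace_values(vals, grid=target)


def integrate(signal: _Signal | np.ndarray, grid: WavelengthGrid | None = None) -> float:
    """Trapezoid integral of a signal over its wavelength grid."""
    if isinstance(signal, _Signal):
        return float(np.trapezoid(signal.values, signal.wavelengths))
    if grid is None:
        raise SpectralError("grid required when integrating a bare array")
    return float(np.trapezoid(np.asarray(signal, float), grid.wavelengths))


def trapezoid_weights(grid: WavelengthGrid) -> np.ndarray:
    """Quadrature weights w such that w @ values == trapezoid integral."""
    wl = grid.wavelengths
    w = np.zeros_like(wl)
    d = np.diff(wl)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def energy_to_photon_flux(wavelengths_nm: np.ndarray, irradiance_w: np.ndarray) -> np.ndarray:
    """Convert spectral irradiance (W m^-2 nm^-1) to photon flux (uE nm^-1).

    Convenience only: photons = E_lambda * lambda / (N_A h c), in micromoles.
    """
    lam_m = np.asarray(wavelengths_nm, float) * 1e-9
    mol = np.asarray(irradiance_w, float) * lam_m / (Avogadro * _h * _c)
    return mol * 1e6


# ---------------------------------------------------------------------------
# File I/O: CSV/TSV with wavelength in column 1, named signals after.


def _detect_sep(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_spectra(path: str | os.PathLike, kind: str = "spectrum", sep: str | None = None):
    """Read named signals from a CSV/TSV file.

    Layout: header row, first column wavelengths (nm, strictly increasing),
    one named signal per remaining column.  Lines starting with '#' are
    comments.  ``kind`` is 'spectrum' or 'sensitivity'.
    """
    sep = sep or _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectralError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectralError(f"{path}: need a wavelength column and >=1 value column")
    if any(str(c).startswith("Unnamed") for c in df.columns):
        raise SpectralError(f"{path}: missing or incomplete header row")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise SpectralError(f"{path}: wavelengths must be strictly increasing")
    grid = WavelengthGrid(wl)
    cls = Spectrum if kind == "spectrum" else SensitivityCurve
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise SpectralError(f"{path}: column {col!r} has negative values")
        out.append(cls(grid, vals, name=str(col)))
    return out


def write_spectra(path: str | os.PathLike, signals: Sequence[_Signal],
                  sep: str | None = None) -> None:
    """Write signals sharing a grid to CSV/TSV (inverse of :func:`read_spectra`)."""
    signals = list(signals)
    if not signals:
        raise SpectralError("nothing to write")
    grid = signals[0].grid
    for s in signals[1:]:
        if s.grid != grid:
            raise SpectralError("all signals must share a grid for writing")
    data = {"wavelength": grid.wavelengths}
    for i, s in enumerate(signals):
        data[s.name or f"signal_{i}"] = s.values
    pd.DataFrame(data).to_csv(path, sep=sep or _detect_sep(path), index=False,
                              float_format="%.17g")
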