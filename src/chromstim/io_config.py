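"""YAML/JSON descriptors for receptor sets, stimulation systems and priors.

A system descriptor looks like::

    receptors:
      sensitivities: sensitivities.csv   # wavelength + one column per receptor
      epsilon: 1.0e-3                    # scalar or per-receptor mapping
      transform: log
    sources:
      spectra: leds.csv                  # wavelength + one column per source
      bounds:
        led400: [0.0, 1.0]               # lower/upper intensity in uE
        led480: [0.0, 1.0]
    background:
      spectrum: background.csv           # or  intensities: {led400: 0.5, ...}

Relative paths resolve against the descriptor's directory.  JSON files with
the same structure are accepted (YAML is a superset).
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import yaml

from .receptors import Photoreceptor, ReceptorSet
from .spectral import Spectrum, read_spectra
from .system import LightSource, StimulationSystem
from .uncertainty import SensitivityPrior

__all__ = ["load_descriptor", "load_receptors", "load_system", "load_prior",
           "config_hash"]


class ConfigError(ValueError):
    """Raised for malformed descriptor files, listing offending fields."""


def load_descriptor(path: str | os.PathLike) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigError(f"{path}: invalid YAML{loc}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: descriptor must be a mapping")
    return data


def _resolve(base: Path, rel: str) -> Path:
    p = Path(rel)
    return p if p.is_absolute() else base / p


def load_receptors(desc: dict, base: Path) -> ReceptorSet:
    problems = []
    if "sensitivities" not in desc:
        problems.append("receptors.sensitivities (CSV path) is required")
    transform = desc.get("transform", "log")
    if transform not in ("identity", "log", "hyperbolic"):
        problems.append(f"receptors.transform: unknown kind {transform!r}")
    if problems:
        raise ConfigError("; ".join(problems))
    curves = read_spectra(_resolve(base, desc["sensitivities"]),
                          kind="sensitivity")
    eps = desc.get("epsilon", 1e-3)
    receptors = []
    for c in curves:
        e = eps[c.name] if isinstance(eps, dict) else float(eps)
        receptors.append(Photoreceptor(c.name, c, epsilon=e))
    return ReceptorSet(receptors, transform=transform)


def load_system(path: str | os.PathLike) -> StimulationSystem:
    path = Path(path)
    data = load_descriptor(path)
    base = path.parent
    problems = []
    for key in ("receptors", "sources"):
        if key not in data:
            problems.append(f"{key} section is required")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    receptors = load_receptors(data["receptors"], base)
    src = data["sources"]
    if "spectra" not in src:
        raise ConfigError(f"{path}: sources.spectra (CSV path) is required")
    spectra = read_spectra(_resolve(base, src["spectra"]), kind="spectrum")
    bounds = src.get("bounds", {})
    sources = []
    for s in spectra:
        lo, hi = bounds.get(s.name, (0.0, 1.0))
        sources.append(LightSource(s.name, s, lower=float(lo), upper=float(hi)))
    background = None
    bg = data.get("background")
    if bg:
        if "spectrum" in bg:
            bgs = read_spectra(_resolve(base, bg["spectrum"]), kind="spectrum")
            background = bgs[0]
        elif "intensities" in bg:
            background = np.array([float(bg["intensities"].get(s.name, 0.0))
                                   for s in sources])
        else:
            raise ConfigError(
                f"{path}: background needs 'spectrum' or 'intensities'")
    return StimulationSystem(sources, receptors, background)


def load_prior(path: str | os.PathLike, transform: str = "log",
               epsilon: float = 1e-3) -> SensitivityPrior:
    """Load a sensitivity prior descriptor.

    Either an explicit list ``samples: [{sensitivities: a.csv, weight: 0.5},
    ...]`` or a parametric grid ``grid: {mean_ranges: [[420, 460], [500,
    540]], sd_ranges: [[30, 70], [60, 100]], step: 10}``.
    """
    path = Path(path)
    data = load_descriptor(path)
    base = path.parent
    transform = data.get("transform", transform)
    epsilon = float(data.get("epsilon", epsilon))
    if "grid" in data:
        from .fixtures import prior_grid

        g = data["grid"]
        samples = prior_grid(
            mean_ranges=[tuple(r) for r in g["mean_ranges"]],
            sd_ranges=[tuple(r) for r in g["sd_ranges"]],
            step=float(g.get("step", 10.0)), epsilon=epsilon,
            transform=transform)
        return SensitivityPrior(samples)
    if "samples" not in data:
        raise ConfigError(f"{path}: prior needs 'samples' or 'grid'")
    samples, weights = [], []
    for entry in data["samples"]:
        samples.append(load_receptors(
            {"sensitivities": entry["sensitivities"], "transform": transform,
             "epsilon": epsilon}, base))
        weights.append(float(entry.get("weight", 1.0)))
    w = np.asarray(weights)
    return SensitivityPrior(samples, w / w.sum())


def config_hash(data: dict) -> str:
    """Stable short hash of a descriptor for reproducibility sidecars."""
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
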