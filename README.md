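# chromstim

Receptor-based chromatic stimulus design for any animal whose photoreceptor
spectral sensitivities are known.

Given sensitivity curves and a bank of light sources, `chromstim` can

- compute photon **captures**, von Kries–adapted relative captures and
  **excitations** for arbitrary spectra (identity / log / hyperbolic
  transforms, with a baseline dark capture ε);
- model a **stimulation system** (normalized capture matrix, intensity
  bounds), project captures into the chromaticity simplex, and score source
  banks with a **gamut metric** (fraction of the animal's chromaticity
  diagram reachable, optionally at a fixed total intensity);
- **fit source intensities** to target excitations with a deterministic
  two-step solver (bounded linear least squares, then trust-region
  reflective refinement in excitation space), including weighted targets,
  secondary objectives for underdetermined banks (min-norm, min/max of a
  source, min pairwise difference), **metamer** enumeration, **silent
  substitution** pairs, and batch **gamut correction** (global scale or
  scale + projection toward the batch centroid);
- propagate **sensitivity uncertainty**: empirical capture-variance
  matrices from a prior over sensitivity curves, first-order variance of
  fitted excitations, variance-minimizing refits, and fitting against
  weighted sensitivity samples;
- decompose hyperspectral images into **projector subframes** (fewer
  subframes than sources) via NMF-initialized alternating bounded least
  squares, with 8/16-bit mask export;
- generate all synthetic fixtures (Gaussian dichromats, Gaussian LED banks,
  artificial broadband spectra, parameter-grid sensitivity priors, low-rank
  hyperspectral cubes) and sample stimuli in source-intensity-log or
  excitation space, or uniformly inside the gamut.

All wavelengths are nanometres; photon flux is in µE (µmol photons
s⁻¹ m⁻²). Spectra files are plain CSV/TSV (wavelength column + named
signal columns, `#` comments allowed).

## CLI

Every command is under a single entry point; descriptors are small YAML
files pointing at spectra CSVs (see `chromstim fixtures` for a complete
worked example it writes to disk):

```sh
chromstim fixtures -o fx/                       # write synthetic fixtures + fx/system.yaml
chromstim gamut --system fx/system.yaml         # gamut metric (TSV to stdout)
chromstim gamut --system fx/system.yaml --choose 2   # rank source pairs
chromstim fit --system fx/system.yaml --targets targets.csv -o intensities.csv
chromstim sample --system fx/system.yaml --space excitation \
    --grid -1:1:11,-1:1:11 -o samples.csv
chromstim metamers --system fx/system.yaml --target 1.0,1.0 --count 5 -o met.csv
chromstim substitute --system fx/system.yaml --isolate 0 --contrast 0.2 -o sub.csv
chromstim decompose-image --system fx/system.yaml --cube cube.tiff \
    --subframes 2 -o outdir/
```

File-writing commands emit a `<output>.run.json` sidecar with the package
version, a configuration hash and the seed, so identical configurations
reproduce byte-identical outputs.

## Package layout

| module | contents |
| --- | --- |
| `chromstim.spectral` | wavelength grids, spectra/sensitivity signals, trapezoid quadrature, CSV I/O |
| `chromstim.receptors` | capture, adaptation, excitation transforms |
| `chromstim.system` | light sources, capture matrix, chromaticity, spectral locus, gamut metric, source-set ranking |
| `chromstim.fitting` | two-step solver, secondary objectives, gamut correction, silent substitution, metamers |
| `chromstim.uncertainty` | sensitivity priors, variance matrix, Taylor propagation, variance-minimizing fits |
| `chromstim.patterned` | hyperspectral capture images, subframe decomposition, mask export |
| `chromstim.fixtures` | synthetic fixtures and sampling strategies |
| `chromstim.io_config` / `chromstim.cli` | YAML descriptors and the `chromstim` CLI |
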