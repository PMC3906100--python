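# paleoxrf

Tissue discrimination in synchrotron micro-XRF maps of flattened fossils.

Exceptionally preserved fossils from Konservat-Lagerstätten are usually
compressed flat, which defeats micro-CT; but their tissues — bone,
phosphatized muscle, other soft tissue, cuticle — take up calcium,
strontium, yttrium and the rare earth elements (REEs) at very different
rates during diagenesis (ppm to ~0.2 wt%). Raster-scanning X-ray
fluorescence records one full photon-count spectrum per pixel, and those
compositional contrasts make anatomy visible that light microscopy and CT
cannot reach. `paleoxrf` implements the two analysis routes for such
hyperspectral cubes, plus the supporting physics and a synthetic phantom
generator so everything is testable without beamline data.

## Methods at a glance

**Spectral-density discrimination (fast, model-free).** Each pixel's
spectrum *S* is normalized to a spectral density
*ŝ<sub>i</sub> = S<sub>i</sub> / Σ<sub>j</sub> S<sub>j</sub>*, the empirical
distribution of detected photon energies — a scale-free fingerprint of the
material. Against a reference pixel *t* the Kullback–Leibler divergence

&nbsp;&nbsp;&nbsp;&nbsp;KL(t, s) = Σ<sub>i</sub> t̂<sub>i</sub> ln(t̂<sub>i</sub> / ŝ′<sub>i</sub>)

is computed per pixel, with one photon added to every channel of the
*evaluated* spectrum (ŝ′) so that empty channels cannot blow up the sum.
The likelihood transform w = exp(−KL) weights pixels; those with w ≥ λ
(default λ = 0.8) form the retained set P<sub>λ</sub>, whose weighted mean
density is a denoised estimate of the reference tissue's spectrum.
Pairwise log-ratios of denoised densities localize which emission lines —
hence which elements — distinguish two tissues.

**Full spectral decomposition (quantifiable, slower).** Each spectrum is
fit as a non-negative combination of element line-group profiles
(Gaussian lines at tabulated energies, detector FWHM(E) = √(a + b·E),
≈150 eV at 5.9 keV) plus a polynomial continuum and an elastic-scatter
peak, using variance-weighted NNLS. This separates overlapping lines —
e.g. the Gd L series inside the Fe K region — that simple
region-of-interest (ROI) integration confounds.

**Information depth.** For a fluorescence line of energy E<sub>f</sub> the
depth still contributing signal at residual transmission *f* is
d = ln(1/f) / Σ<sub>paths</sub> μ<sub>lin</sub>·g, with elemental μ/ρ
computed from atomic physics (Cromer–Liberman photoabsorption plus
Rayleigh/Compton scattering, mixture rule for compounds). The default
geometry reproduces the published 10 %-attenuation depths in pure
hydroxyapatite (e.g. Sr Kα 242 µm, Y Kα 283 µm, Ca Kα 19 µm).

## Worked example

Simulate a small fossil-fish phantom and discriminate bone:

```bash
paleoxrf simulate --layout fish --shape 64x48 --seed 42 --out fish.h5
paleoxrf klmap fish.h5 --ref 5,22 --out bone
```

which prints

```
KL tissue discrimination
========================================
reference pixel      : (5, 22)
pseudocount          : 1
threshold λ          : 0.8
valid pixels         : 3072
retained pixels |P_λ|: 294
divergence min/median: 0.03657 / 2.149
weight of reference  : 0.9641
```

The phantom contains exactly 294 bone pixels: the λ = 0.8 weight map
retains the bone and nothing else, while the median pixel of the map
(matrix) sits at divergence ≈ 2.1 from the bone reference. The command
also writes the divergence/weight images (float TIFF + rendered PNG,
blue→yellow→red for similar→divergent) and the denoised bone density as a
two-column CSV.

Information depths come from the same package:

```bash
$ paleoxrf depth --line Sr:Ka
Sr Ka (14.165 keV) in apatite: 242.3 µm
$ paleoxrf depth --line Y:Ka
Y Ka (14.958 keV) in apatite: 283.0 µm
```

Hard Sr/Y K lines escape from ~250–280 µm below the surface — deep enough
to image a skull through covering sediment — whereas Ca Kα (18.8 µm)
probes only the surface.

The same workflow is available as a library: `make_phantom` /
`forward_spectra`, `KLTissueModel(map, ref).fit(threshold)` returning
divergence, weights and denoised density, and
`SpectralDecompositionModel(map, line_model).fit()` returning per-element
amplitude maps with residual diagnostics and a `summary()` table.

## Layout

| module | contents |
|---|---|
| `paleoxrf.core` | `SpectralMap` container, energy calibration, HDF5/CSV I/O |
| `paleoxrf.lines` | bundled emission-line and absorption-edge tables |
| `paleoxrf.kl` | spectral densities, divergence maps, weights, denoising |
| `paleoxrf.decomposition` | design matrix, weighted-NNLS fits, ROI maps |
| `paleoxrf.depth` | mass attenuation and information depth |
| `paleoxrf.phantom` | tissue compositions, layouts, forward simulation |
| `paleoxrf.render` | percentile stretch, RGB overlays, colormaps |
| `paleoxrf.cli` | `simulate`, `fit`, `roi`, `klmap`, `denoise`, `depth`, `render` |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
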