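# Methods

This note documents the models implemented in `paleoxrf`, the parameter
choices that matter, what the synthetic phantom does and does not emulate,
and the numerical conventions.

## Spectral densities and the divergence map

A raster-scan pixel yields integer photon counts S₁…Sₙ over n detector
channels. The spectral density ŝᵢ = Sᵢ/ΣⱼSⱼ estimates the probability
that a detected photon falls in channel i; it is invariant to dwell time
and flux, so two pixels of the same material (and stratigraphy) share a
density up to counting noise. Dissimilarity from a reference pixel t is
measured by the Kullback–Leibler divergence KL(t,s) = Σᵢ t̂ᵢ ln(t̂ᵢ/ŝᵢ),
the expected log-likelihood ratio when t̂ is the true distribution.

Empirical densities make the raw divergence fragile: a channel with
Sᵢ = 0 but t̂ᵢ > 0 contributes +∞ on counting noise alone. One photon is
therefore added to **every channel of the evaluated spectrum only**
before normalization (the pseudocount, default 1); the reference receives
no regularization, and channels with t̂ᵢ = 0 contribute zero
(0·ln 0 ≡ 0). Natural logarithms are used throughout.

Consequences worth knowing:

* KL(t, t) > 0 with the pseudocount on — approximately ln(1 + n/N) for a
  pixel of N total counts — so the weight w = exp(−KL) of a pixel against
  its own tissue sits below 1 by an amount controlled by n/N. With the
  defaults (n = 1024 channels, ~5×10³–1.3×10⁴ counts per pixel) the
  same-tissue weight mode lands in [0.85, 0.95], comfortably above the
  retention threshold; a much finer channel binning at the same counts
  would push every weight below it. This coupling is why the default
  calibration is 1024 channels × 20 eV (0–20.48 keV): it still oversamples
  the ≈150 eV detector response ~7× and spans Si Kα to the 17.2 keV
  elastic peak.
* Pixels with zero total counts have no density; they carry divergence
  +∞, weight 0, and are excluded from retained sets and histograms.
* The retention comparison w ≥ λ is inclusive, so the boundary case is
  stable; λ defaults to 0.8.

The denoised density of the reference tissue is the likelihood-weighted
mean Σ_{p∈P_λ} w_p ŝ_p / Σ w_p over the retained set — a convex
combination, hence itself a density. Per-channel log-ratios of two
denoised densities localize the energies (lines, elements) that separate
two tissues; channels where exactly one density vanishes are reported as
±∞ rather than clipped.

## Spectral decomposition

The decomposition models a spectrum as D·a with one column per element
line group plus background terms:

* **Line shapes** are pure Gaussians at fixed tabulated energies with
  detector width FWHM(E) = √(a + b·E); defaults a = 0.00889 keV²,
  b = 0.00231 keV give ≈150 eV at 5.9 keV (typical silicon drift
  detector). No tailing or shelf; this keeps the model linear and is
  sufficient to demonstrate and resolve line overlap.
* **Groups** combine an element's series with fixed branching
  (Kα:Kβ = 0.88:0.12; Lα:Lβ:Lγ = 0.55:0.36:0.09; Kα itself split
  2:1 into Kα₁/Kα₂), each column normalized to unit sum so the fitted
  amplitude is the group's total counts. An element gets its K series if
  the K edge lies below the beam energy, else its L series.
* **Background** is a degree-2 Legendre polynomial on the energy axis
  (sign-free coefficients) plus a non-negative elastic-scatter Gaussian
  at the beam energy when it is in range. Degree 2 was kept after
  checking that higher degrees only add variance on the phantom.
* **Solver**: variance-weighted non-negative least squares — first pass
  weighted by 1/√max(S,1), one reweighting pass by the fitted model
  (floored at 0.5 counts). This chi-square iteration is numerically
  indistinguishable from a full Poisson maximum-likelihood fit on the
  phantom, and is deterministic. Line amplitudes are constrained ≥ 0;
  background coefficients are free (realized as ± column pairs).

ROI integration sums counts over channels whose centers lie in
[e_lo, e_hi) — half-open by convention. The helper `roi_window` spans an
element's main series (e.g. Gd Lα…Lβ₁ ± 1 FWHM), which is what makes the
classic artifact visible: the Gd window contains Fe Kα, so in Fe-rich
material the "Gd" ROI image is an iron map. The decomposition separates
the two because the fit uses the full multiplets.

`semi_quant` converts a fitted amplitude to a concentration with a
user-supplied sensitivity (counts per weight-fraction-second);
fundamental-parameters calibration is out of scope.

## Mass attenuation and information depth

Elemental μ/ρ is computed, not tabulated: photoabsorption from the
imaginary anomalous scattering factor f″ (Cromer–Liberman, via gemmi),
Rayleigh scattering by integrating IT92 atomic form factors, Compton from
Klein–Nishina with the incoherent-function correction S(q,Z) ≈ Z − f₀²/Z.
Spot checks against the standard NIST tabulation agree to 1–3 % over
2–20 keV (Fe @ 10 keV: 170.2 vs 170.6 cm²/g; ICRU-44 cortical bone within
1.5 %). The validity window is 1–30 keV; outside it the code errors
rather than extrapolates. Compounds use the mass-fraction mixture rule;
a `TabulatedAttenuation` source accepts user curves with log-log
interpolation that never crosses a listed absorption edge.

The information depth at residual transmission f is

    d = ln(1/f) / Σ_paths μ_lin · g,

where g is each path's length per unit depth. Two conventions are
exposed:

* **Collection-only (default).** Only the emitted line is attenuated,
  along an exit ray of obliquity sec θ = √3 (θ ≈ 54.7° from the surface
  normal — the body-diagonal direction that arises when the detector sits
  at 90° to the beam in the horizontal plane and the specimen plate is
  inclined toward both). This convention reproduces the published
  10 %-attenuation depth table for this mount across all ten tabulated
  lines (3.3–15 keV, linear attenuation spanning two orders of magnitude
  and the Ca K edge) to within ~2 %. The two-path 45°/45° formula does
  not: with NIST-accurate attenuation data it deviates by −27 % to +20 %
  across the same table, so it cannot be the convention behind those
  numbers.
* **Two-path.** ln(1/f) / [μ(E₀)/sin α + μ(E_f)/sin β] with explicit
  incidence and takeoff angles, for users who want the stricter
  excitation-and-escape depth (`DepthQuery.two_path_45` or
  `include_incident=True`).

Apatite defaults to hydroxyapatite Ca₁₀(PO₄)₆(OH)₂ at 3.16 g/cm³
(configurable); the registry also ships calcite and quartz. Between
absorption edges the depth increases with line energy (Rb < Sr < Y Kα);
across the Ca K edge it inverts (a 4.51 keV line probes shallower than
3.69 keV) because apatite absorbs far more strongly just above the edge.

## The synthetic phantom

The generator emulates the compositional structure of phosphatized
fossils in a clayey matrix, not beamline physics:

* **Compositions** (weight fractions). Bone: Ca/P apatite majors with
  Sr 150 ppm, Y 550 ppm, La 750 ppm, Nd 0.18 wt%, Gd 550 ppm, Yb 10 ppm.
  Mineralized muscle: Ca/P with Nd 900 ppm, reduced Y, Gd 275 ppm (bone's
  Gd/Nd ratio applied to the muscle Nd value), plus a clay/organic
  admixture (Si, K, extra Fe). Other soft tissue: more admixture, fewer
  REEs. Matrix: Si/K/Fe-rich, REE-poor. The admixture gradient is what
  makes the tissues' *relative* compositions mutually distinct — without
  it bone and muscle densities are nearly proportional and no
  scale-free method could separate them. A shrimp-section preset
  (cuticle Nd 0.12 wt%) is included; all values are overridable.
* **Layouts**: `fish` (soft-tissue body, bone spine + ribs + skull,
  muscle bands, matrix), `shrimp_section`, `blobs`; every class ≥ 2 % of
  pixels; deterministic per seed.
* **Forward model**: expected counts = dwell × flux × brightness ×
  [Σ_el conc·sens(el)·profile(el) + 5 % continuum + 1 % elastic peak],
  then one Poisson draw per channel from a single seeded RNG stream.
  The per-element sensitivity is photoabsorption of the beam by the
  element times shell fraction (0.87 K / 0.60 L) and fluorescence yield —
  a simplified fixture, not fundamental parameters. The low continuum
  reflects the 90° in-plane detector placement that suppresses Thomson
  scattering in the real geometry.
* **Defaults**: dwell 0.5 s and a flux scale giving ≈5×10³–1.3×10⁴ total
  counts per pixel across tissues — the counting regime where the
  pseudocount visibly matters yet trace REE lines carry tens of counts.

What passing phantom tests does **not** show about real data:
self-absorption and depth stratification (a buried bone under sediment
changes its density; not simulated), detector tailing/pile-up/escape
peaks, spatial mixing at tissue boundaries (labels are hard), and any
fidelity of the sensitivity constants. The phantom validates the
*statistics* of the methods, not instrument physics.

## Numerical conventions and edge cases

* Channel indexing 0-based; pixel coordinates (row, col) with row 0 at
  the image top; energies are channel centers, E(i) = offset + gain·i.
* `line_energy` quotes the strongest member of a Siegbahn group
  (Kα → Kα₁, Lβ → Lβ₁), matching how group energies are quoted in
  practice; full multiplets with branching are available separately.
* Divergence maps clip tiny negative float round-off to 0; all-zero
  spectra error out of density estimation; empty retained sets raise
  with advice to lower the threshold.
* Percentile stretch maps [p2, p98] linearly to [0, 1], clamps outside,
  sends constant images to 0, ignores NaNs; rendering never mutates the
  underlying arrays. Weight maps render excluded pixels white and
  retained weights light-gray→black over [λ, 1].

## Known limitations

* The Gaussian-only line model cannot fit real SDD tails; residuals on
  measured spectra will be structured even when amplitudes are right.
* At trace concentrations the decomposition is information-limited: on
  the default phantom the fitted Gd map reaches Pearson r ≈ 0.89 against
  truth, which is at the Fisher-information bound for ~30 Gd counts per
  bone pixel under the Gd Lα / Nd Lβ₂ near-degeneracy (32 eV apart);
  denser REE inventories or higher dose are needed for r > 0.9.
* The depth calculator treats a homogeneous half-space; layered samples
  and secondary enhancement are out of scope.
* Cross sections below 1 keV and M lines are not covered.
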