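# Methods

This note documents the models, the numerical choices, and the
limitations of `bonerad`, in the order the pipeline runs.

## Materials and emission energetics

Materials are atomic-fraction compositions with a bulk mass density.
Three presets describe the bone composite: whole `bone`
(Ca0.09863 P0.05918 O0.31413 N0.04946 C0.17861 H0.3, 1.41 g/cm³ — a
low-density fish bone; mammalian cortical bone is denser), the `mineral`
phase (H2 O26 P6 Ca10 at 1.01 g/cm³, the effective in-tissue density of
the carbonated-apatite nanocrystals), and the organic `collagen` matrix
(H0.49514 C0.31554 N0.08738 O0.10194, 0.41 g/cm³).

K-shell binding energies, K-alpha line energies and mean ionization
potentials are packaged tables; atomic weights and the imaginary
anomalous scattering factor f″ come from `gemmi` (Cromer–Liberman).
Photoelectric mass attenuation is computed from f″ via the optical
theorem, σ_pe = 2 r_e λ f″. Coherent and Compton scattering are
deliberately omitted: at 18 keV in mineralized tissue the photoelectric
channel dominates the *absorbed* energy, which is what drives both dose
and damage. With these constants, 300 µm of the bone preset transmits
77–78 % of an 18 keV beam, i.e. a ~22 % intensity loss.

Absorbed dose uses the standard definition: absorbed energy
(flux × time × photon energy × (1 − transmission)) over the illuminated
mass (density × beam cross-section × thickness). It is linear in flux and
exposure and inversely proportional to beam area; no dose protraction or
diffusion corrections are applied.

## Electron transport

Photoelectron trajectories are simulated with a single-scattering
Monte-Carlo in the continuous-slowing-down approximation, the published
physics of low-energy electron-microscopy simulators:

* **Stopping power**: Joy–Luo modified Bethe formula, mass-fraction
  weighted, with the low-energy correction k_i = 0.731 + 0.0688 log10(Z)
  keeping the logarithm positive below ~1 keV. For 13.9619 keV electrons
  in the bone preset the CSDA range is ≈ 3.9 µm — this single number
  controls most of what follows.
* **Elastic scattering**: screened-Rutherford cross-sections per element
  (screening parameter α = 3.4·10⁻³ Z^0.67 / E), free flights sampled
  from the total elastic mean free path, scattering element sampled by
  partial cross-section, polar angle from the screened-Rutherford
  distribution, azimuth uniform.
* **Steps and termination**: step lengths are capped so no step loses
  more than 20 % of the current energy (keeps the CSDA loss locally
  linear). Electrons terminate at a 0.2 keV cutoff; the terminal step is
  clamped to land exactly on the cutoff and extended by the small
  sub-cutoff residual range, so energy bookkeeping closes exactly
  (deposited = start − cutoff). Secondary-electron cascades, Auger
  electrons and fluorescence-photon transport are not followed; their
  aggregate effect is absorbed into the damage threshold.
* **Source geometry**: electrons are emitted isotropically from a point
  in bulk material. (A surface-entry pencil-beam mode exists for
  comparison; it shifts the mean reach but not the support, which is
  bounded by the CSDA range either way.)

The quantity handed to the damage model is the penetration depth
d_e = max over the trajectory of |x-projection| — the damage-relevant
reach along a fixed line through the source, matching the 1-D geometry of
the damage model. The alternative (final resting position) is strictly
smaller and is not used. Depths are histogrammed over mirrored signed
values, so the symmetry P(+|d_e|) = P(−|d_e|) holds exactly and total
mass is 1 by construction. Everything is reproducible bit-exactly from
the seed; the fast path (`penetration_depths`) and the
trajectory-recording path share one sampling scheme and give identical
depths for the same seed.

### Tail extrapolation

The damage threshold probes H = Δt·η = 0.05, i.e. η ≈ 1.6·10⁻⁴ at
Δt = 320 s — survival levels at or below the resolution of any
10³–10⁴-electron histogram. The raw histogram is therefore extrapolated
before use: the survival of |d_e| over the bins holding the outer 30 % of
probability mass is fitted log-linearly (each bin edge weighted by the
mass of its bin, so electrons rather than sparse far-tail bins carry the
fit), and the tail beyond the fit knot is replaced by the fitted
exponential, extended until the survival falls below 10⁻⁹ and
renormalized. This mirrors the smooth-extrapolation treatment such
threshold analyses require and removes the dependence of ζ on the single
outermost simulated electron. The fitted 1/e length in the bone preset is
a few tenths of a µm and is stable to ±1 % across seeds at n = 10⁴.

## Damage-spread model

* The beam source rect(x/w) takes the value ½ at |x| = w/2 exactly (the
  distributional convention); after convolution this is irrelevant, but
  it fixes determinism of the point-sampled function.
* η is computed as a discrete convolution (FFT) of the *cell-averaged*
  rect with the P histogram rebinned onto the model grid by
  CDF interpolation. Cell averaging makes ∫η dx = w exact for any grid
  alignment — conservation holds to machine precision, well inside the
  0.1 % requirement.
* The grid step defaults to min(w/8, P bin width/4) (never coarser than
  min(w, bin)/4), and the extent to w/2 + P support + 2 µm; a grid that
  truncates the P support raises rather than silently losing mass.
* H = Δt·η: the time integral collapses to a product because η carries no
  time dependence. Flux does not enter the model — the threshold 0.05 is
  calibrated implicitly to the experimental flux scale through the
  definition of H. This is a model limitation: predictions at very
  different fluxes require rescaling the threshold.
* x_w is the outermost threshold crossing, located by linear
  interpolation between the bracketing grid points on the decaying
  flank. If H never reaches the threshold a "no damage" sentinel is
  returned and ζ is defined as 0; if H is still above threshold at the
  grid edge, the evaluation raises (enlarge the grid) rather than
  returning a truncated extent.
* ζ_V defaults to 1 ("unity" mode) for strongly fiber-aligned tissue,
  where vertical spread is confined by the collagen texture; "computed"
  mode reuses the same machinery with a vertical penetration
  distribution.

Evaluated end-to-end with the Monte-Carlo bone P(d_e) (n = 10⁴–2·10⁴,
threshold 0.05, Δt = 320 s), the model places Z at ≈ 108 % for a 100 µm
beam, ≈ 142 % at 20 µm, ≈ 184 % at 10 µm and ≈ 268 % at 5 µm, and the
damage-to-beam fold ratio at ≈ 9.3× for a 1 µm beam and ≈ 74× at 0.1 µm
(the `scripts/acceptance.py` output; stable to ~1 % across seeds).

### First-order kinetics fits

Damage-vs-time and strain-vs-time series are fitted with
y(t) = y0 + (plateau − y0)(1 − e^(−kt)), anchored at the known initial
value (100 % damage, 0 % strain). Fits use lmfit with a rate-constant
multi-start ladder (×0.1…×10 around a half-rise initial guess); the best
converged restart wins, and total non-convergence raises with the
diagnostics of every attempt. Identifiability caveat: with 20 samples
over 0–320 s (16.8 s spacing), rates near 0.07 %/s are at the resolution
limit (kΔt ≈ 1.2 between samples) and their noisy estimates scatter by
~10–20 %; slower rates (~0.02 %/s) are recovered to a few percent.

## SHG quantification

Stacks are Z-projected per pixel (max or standard deviation; max is the
default, the projection used for boundary measurement). The background is
the median intensity outside candidate imprints, iterated twice so large
imprints do not bias it. Detection thresholds at
(1 − drop_threshold) × background — purely background-relative, hence
invariant to global intensity scaling — and groups pixels by
8-connectivity, discarding components below a minimum area (16 px).
Extents are full widths of the intensity dip along horizontal and
vertical profiles through the imprint center, measured at the half-depth
level (background − 0.5·(background − dip minimum)); drop_threshold is
configurable, but 0.5 makes "full width" the FWHM of the dip, the
standard reading. Profiles are smoothed with a 3-pixel moving average
before crossing detection; crossings are interpolated linearly, and a
profile that reaches the image border before recovering raises
("imprint touches border"). The relative damaged area is the elliptical
area from the two extents over the beam cross-section, which factorizes
into ζ_H·ζ_V.

## XRD strain analysis

Detector-gap stripes are masked; frames are azimuthally integrated over
the full 360° by assigning each unmasked pixel a 2θ from its radial
distance (flat detector normal to the beam) and averaging per 2θ bin.
The per-bin pixel counts are kept, so total counts are conserved exactly
(Σ mean·n_pix = Σ pixels). An empty-beam profile is subtracted pointwise
(grids must match exactly; negative residuals clip to zero). The (002)
peak is fitted with a Voigt plus linear background (lmfit), initialized
from the window centroid and spread with a width multi-start; the default
window 10.5°–12.5° at 18 keV brackets c = 6.8–6.9 Å. Peak centers convert
to the lattice parameter through Bragg's law, d = λ/(2 sin θ), c = 2·d002.
Strain is the percentage change of c relative to the *first exposure
point* of each series — absolute residual strain against a stress-free
standard is out of scope — with the fitted center standard errors
propagated to first order. The multilayer-monochromator bandwidth
(E/ΔE ≈ 500) broadens the peaks and is not deconvolved; it shifts all
points of a series identically and cancels in the relative strain.

## Synthetic data generators

The generators produce the statistical structure the analysis assumes,
with ground truth emitted alongside and bit-exact reproducibility from
the scenario seed. Default conditions mirror the experimental scale: an
18 keV, 5.5·10⁷ ph/s beam through a 20 µm pinhole, a 40/80/160/320 s
exposure ladder, ~200-count SHG backgrounds with Poisson noise plus 5 %
Gaussian read noise (SNR ≈ 14), diffraction arcs at peak SNR 20, and a
strain relaxation of plateau 0.2 %, rate 0.01 1/s whose rate scales
linearly with flux.

* **SHG stacks**: oriented band-pass noise (anisotropic Gaussian-filtered
  white noise, fibers vertical) emulates collagen bundle texture; damage
  imprints are elliptical dips with a logistic edge whose half-depth
  contour sits exactly on the programmed extents (extent = ζ·w from the
  damage model, so imprints elongate horizontally, orthogonal to the
  fiber direction). Not emulated: SHG image formation physics (dipole
  response, quadratic concentration dependence), depth attenuation,
  before/after registration. Passing round trips therefore demonstrate
  the *measurement* chain (projection, background, segmentation, FWHM
  profiling) under realistic noise, not robustness to real-tissue texture
  confounds.
* **Diffraction sequences**: (002) arcs concentrated around the meridian
  (axially textured mineral), ring radius following the programmed c(t),
  exponentially decaying isotropic background, detector-gap stripes,
  Poisson counting noise. The default geometry (345 mm, 75 µm pixels)
  puts the ring at its experimental radius but offsets the beam center to
  a frame corner so a quarter ring fits a compact 1152² frame. Not
  emulated: detector point-spread, polarization/solid-angle corrections,
  calibration-standard refinement.
* **Damage curves**: the first-order model plus Gaussian noise.

## Problem sizes

Defaults are chosen so the full test suite runs in well under a minute of
compute: 2000 trajectories for interactive/default runs (the histogram
scale at which the tail extrapolation already stabilizes ζ), 10⁴ for the
shared test fixture, 2·10⁴ in `scripts/acceptance.py` for tail
stability. The ζ ladder moves by well under 1 % between 10⁴ and 2·10⁴
electrons.

## Known limitations

* Only Ca K photoelectrons of the primary beam are transported; the
  fluorescence-mediated cascade (Ca Kα re-absorption, P photoelectrons)
  is folded into the damage threshold rather than simulated. The model
  therefore underpredicts spread slightly at large beams.
* The outer-tail 1/e attenuation length of the simulated reach
  distribution in the 1.41 g/cm³ bone preset is ≈ 0.36 µm, bounded by the
  ≈ 3.9 µm CSDA range; micrometre-scale attenuation lengths arise in this
  framework only for the low-density collagen matrix (the package's
  density-ordering tests show collagen ≫ mineral > bone) or as the scale
  of a whole-distribution exponential fit, not as an outer-tail slope in
  whole bone.
* The damage threshold is dimensionless and flux-free (see above);
  comparisons across fluxes need an explicit recalibration.
* Voigt fitting assumes a single dominant peak in the window; overlapping
  reflections are out of scope.
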