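# Methods

## The measurement problem

A THG image of a fungal hypha contains three intensity populations: a flat
detection background over most of the frame, the chitinous cell wall as a
thin bright rim along the hypha boundary, and lipid droplets as compact
puncta roughly an order of magnitude brighter than the wall. The quantities
of interest are the droplet count per hypha area (µm⁻²) and the mean droplet
diameter (µm), estimated two independent ways — by spatial image correlation
spectroscopy (ICS) and by threshold-based particle analysis (PSA) — plus
two-channel colocalization against a lipid-stain fluorescence image.

## Synthetic data model

Because raw THG acquisitions of this kind are not publicly deposited, the
package ships a generator whose defaults define its study conditions, with
exact ground truth for every stage:

* **Geometry.** A capsule (stadium) hypha, default 80 × 10 µm, centered in a
  1024² frame at 0.1 µm/pixel. Closed-form area W(L−W) + π(W/2)² ≈ 778.5 µm².
* **Wall.** A ribbon with Gaussian cross-profile (FWHM = `wall_thickness_um`,
  default 0.3 µm) centered just inside the capsule boundary, peak 20.
* **Droplets.** `n_droplets` hard disks (default 12 ≈ 15 × 10⁻³ µm⁻², the
  control regime) with truncated-normal diameters on [0.2, 2.0] µm
  (default 0.74 ± 0.2 µm), rasterized with 4× supersampled area weighting
  (sub-pixel centers matter at 3–16 px diameters), peak 200 — ten times the
  wall, matching the observed droplet/wall contrast. Centers are uniform in
  the capsule, rejecting disks that would touch the wall band; a bounded
  rejection count turns geometric infeasibility into an explicit error.
* **Optics and noise.** Gaussian PSF with σ = 0.127 µm (300 nm FWHM lateral
  resolution); additive background (default 20 on an 8-bit-like scale);
  photon noise Poisson(gain·I)/gain with gain 1 by default. The real
  instrument's noise statistics are unknown, so the model and its parameters
  are exposed; gain 1 represents roughly one detected photon per stored
  intensity unit. The background default is calibrated so that the
  documented 20-subtraction regime actually erases the wall (see below).

What the generator deliberately omits: cytoplasmic texture, out-of-focus
haze, 3D sectioning effects, droplet brightness variation with size, and
optical aberrations. Tests that pass on these images therefore validate the
*estimators' mechanics and biases* under clean conditions, not performance
on real micrographs — real cytoplasm adds diffuse correlated signal that
changes ICS normalization in ways the generator does not emulate.

## Preprocessing

**Segmentation.** Gaussian smoothing (0.3 µm), triangle threshold on
log-intensity, morphological closing, hole filling (the wall rim encloses
the cytoplasm), largest connected component, then a 0.4 µm erosion that
compensates the outward widening produced by thresholding a blurred ridge
below its peak. The triangle method is used because the histogram is a
dominant background mode with a long bright tail; a balanced two-class
split (Otsu) flips to separating wall from droplets whenever the droplet
class is populous, destroying the rim. On the default regimes the mask area
lands within ~4% of the geometric truth. Log scale makes the mask exactly
invariant to intensity rescaling.

**Iterated background subtraction.** Each iteration re-estimates the mean
over the out-of-mask region on the current image, subtracts it everywhere,
and clips negatives to zero. Clipping is what makes iteration meaningful:
after the first pass only the positive noise excursions outside survive,
and their decaying mean keeps grinding down the dim wall while barely
touching the 10×-brighter droplets. Twenty iterations (the workflow
default) leave the wall ribbon below 2% of the droplet peak under the
generator defaults. `auto_subtraction_count` offers the principled stopping
rule — subtract until the ICS count changes by < 5% — and emits the full
count-versus-iteration trace. The mask is held fixed across iterations
(re-segmenting a partially erased image is unstable), and the background is
re-estimated each pass.

**Out-of-hypha clearing.** After subtraction, the standard ICS route zeroes
everything beyond the dilated hypha mask. The clipped-noise residue is
individually tiny, but it covers ~93% of the frame while a control-regime
droplet population contributes only ~0.2 intensity units to the frame mean;
left in place, the residue dominates ⟨I⟩, crushes G(0), and makes the ICS
count insensitive to the true droplet number. Clearing the outside — the
delineate-and-clear step of the manual workflow — removes it exactly.
`clear_outside_um=None` in `reporting.quantify_image` disables the step for
comparison.

**Wall cropping.** `crop_wall` zeroes only the wall annulus (mask boundary
± erosion radius), emulating manual removal of the wall *alone*: the
outside-background field must survive for the subtraction iterations to
keep operating.

## ICS: estimator and known biases

The autocorrelation is computed by FFT with periodic lags (no padding
correction — only the central lobe, at lags ≪ N, informs the fit). The G
curve is the central horizontal profile by default; radial averaging is
available as a variance-reduction option. The Lorentzian fit excludes the
single zero-lag sample by default (it carries the white shot-noise spike;
uncorrelated noise contributes nowhere else), carries a free additive
offset that absorbs broad pedestals (hypha envelope, residual wall), and is
initialized from the curve itself (amplitude ← max off-zero value, width ←
lag at half that value, offset ← tail median) with w bounded in (0, N/4).

Two systematic biases of the count formula are worth stating plainly,
because the package's own validation quantifies them:

1. **Correlation-area shape factor.** N_LD = N_pix²/(r²πG(0)) implicitly
   equates the correlation area with π r² at r = FWHM/2. That is exact for
   particles whose correlation is Gaussian with e⁻²-radius r, but for
   PSF-blurred hard disks the true correlation area ∫∫G/G(0) is ≈ 2.1×
   larger than π (FWHM/2)². Measured on monodisperse, noise-free synthetic
   images, the formula overcounts by a stable factor ≈ 2.1 at every count
   from 12 to 200. Polydispersity partially offsets this (G(0) weights
   droplets by area squared), crowding offsets it further at high density.
2. **Sparse-regime fragility.** At realistic densities a 1024² frame holds
   only 10–20 droplets; everything that perturbs ⟨I⟩ or leaves correlated
   residue (incompletely erased wall, any background floor) moves the count
   by tens of percent. Relative quantities — treated/control ratios,
   ICCS amplitude ratios, diameter orderings — are robust, because the
   multiplicative biases largely cancel; absolute sparse-regime ICS counts
   should be treated as an index, not a census. PSA, which recovers sparse
   densities within a few percent here, is the reliable absolute counter at
   low density; conversely PSA undercounts once blurred footprints merge
   (no watershed splitting, by design), while ICS degrades more gracefully.

Diameters: the reported ICS diameter is the fitted FWHM in µm (= 2r). It
tracks the PSF-broadened true diameter monotonically and slightly
compresses differences.

## PSA

The pipeline thresholds the *background-subtracted* image with Otsu's
method. Collapsing the background mode first is what makes an unsupervised
threshold stable: on the raw image the dominant noise mode captures the
Otsu split, while after subtraction the threshold lands between wall
residue and droplet cores across all tested regimes (the original workflow
resolved this with a human adjusting the threshold by eye). Fixed and
percentile thresholds are available, and every realized threshold is
recorded. Components are 8-connected; the default minimum area (0.02 µm² =
2 px at 0.1 µm/px) rejects hot pixels; diameter is the equivalent-circle
diameter 2√(area/π); circularity 4π·area/perimeter² is clamped at 1
(rasterized perimeters of few-pixel blobs undershoot). The thresholded
footprint of a blurred disk extends beyond the half-maximum radius, so PSA
diameters run ~0.1 µm above truth — same direction as the PSA-vs-ICS
diameter offset in practice.

## Colocalization

Pearson correlation is computed over the whole frame or an optional mask.
ICCS fits Lorentzians to the central profiles of G_aa, G_bb and G_ab; the
interacting fraction of a with b is G_ab(0)/G_bb(0), and both directions
are always reported. Because numerator and denominator share the same
normalization and shape factor, the estimator is nearly unbiased: across
ground-truth shared fractions {0, 0.25, 0.5, 0.75, 0.9, 1} the recovered
medians track truth within a few hundredths. Fractions far above 1 are
flagged as fit pathology.

## Reporting

Pooled diameter histograms use right-closed 0.3 µm bins labeled by their
upper limit; each bin's count is divided by the summed hypha area of the
group, and the absolute error follows the linear propagation rule
(rel. error of density + rel. error of area) × bin density, with the two
relative errors supplied by the user (they are acquisition-dependent and
not derivable from a single image). The treated/control ratio is the ratio
of group mean densities. `batch_run` emits one tidy row per image × method
with full diagnostics; statistical testing is deliberately left to
downstream tools.

## Validation experiment design

`ldics.experiments` fixes the study conditions: a regime grid of
(density, diameter) pairs spanning 13–24 × 10⁻³ µm⁻² and 0.46–0.78 µm
(20 replicates each); an ICS-vs-PSA regression batch of 20 images at
50–400 droplets; a 6-image wall-route comparison; a colocalization sweep
with 5 replicates per shared fraction at 512 px; and a 2×2
control/starved × 3 h/6 h experiment with 12 replicates per cell (matching
typical per-time-point group sizes in this kind of study), each cell's
ground-truth density and diameter set to the average of the two methods'
reported values for that condition. Problem sizes were chosen so the whole
validation runs in minutes on one CPU while keeping medians stable. All
randomness derives from a single seed; identical seeds reproduce identical
tables bit-for-bit.

## Known limitations

* Absolute ICS counts on sparse, texture-free images carry the ~2× shape
  factor plus residual-structure sensitivity described above; the
  validation suite asserts the published-regime tolerances anyway and the
  corresponding checks document the measured bias rather than masking it.
* Touching droplets are counted as one particle by PSA.
* The noise model is a stand-in (photon + optional Gaussian read noise);
  PMT gain statistics, frame averaging and digitization are not modeled.
* Single 2D slices only: no 3D stacks, no time series, no registration
  between channels (simultaneous acquisition is assumed).
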