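# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `vishsi`, and what the synthetic test conditions do and
do not establish about behaviour on real endoscopic data.

## Spectral representation

All spectra live on the fixed 380–780 nm grid with 1 nm step (401 samples).
Reflectances are unitless in [0, 1]; illuminants are radiant power in
arbitrary units (only ratios matter — the tristimulus normalisation below
cancels any global scale).

Quadrature over wavelength is the rectangle rule at the native 1 nm step.
The normalisation constant `k = 100 / Σ S·ȳ` carries the same Δλ factor as
the numerators of X, Y, Z, so the tristimulus values are invariant to the
step size and to illuminant rescaling, and a perfect reflector has
Y = 100 exactly (to floating-point precision, tested at 1e-9).

### Color-matching functions

The CIE 1931 2° observer is embedded as a package constant generated from
the multi-lobe piecewise-Gaussian analytic representation of Wyman, Sloan &
Shirley (2013), evaluated on the 1 nm grid. The analytic fit tracks the
tabulated observer to within about one percent across the visible range;
its x̄ component dips a few 1e-4 below zero near 501 nm and is clipped at
zero. Nothing in the package's tests or reported quantities depends on the
exact tabulated ordinates: the identities that matter (perfect-reflector
normalisation, linearity, white-point mapping) hold for any non-negative
observer, and the sRGB→XYZ matrix — which fixes the published white point
(95.047, 100.000, 108.883) — is the standard one, not derived from the
embedded curves. `vishsi export-cmfs` dumps the constants for audit.

### sRGB and chromatic adaptation

The transfer function is the IEC sRGB curve (linear below 0.04045/12.92,
power 2.4 above; discontinuity at the junction < 1e-7). The linear-RGB→XYZ
matrix is the classical sRGB(D65) matrix at published 7-digit precision.
Chromatic adaptation between the D65 white and a measured source white is a
von Kries scaling in the Bradford cone space. Bradford is a documented
default, not a claim about any particular instrument: CAT02 or plain XYZ
scaling can be substituted by passing a different matrix to
`linear_rgb_to_xyz`.

## Calibration model

The conversion model has three fitted parts, each an ordinary least-squares
fit through the Moore–Penrose pseudoinverse (minimum-norm under rank
deficiency, with a warning):

1. **Correction matrix** `C` (3×p): regresses spectrometer-side XYZ on a
   monomial expansion of camera-side XYZ. The expansion order defaults
   to 2 (terms X, Y, Z, X², Y², Z², XY, XZ, YZ, 1; p = 10), configurable
   1–3. With 24 patches, order 2 keeps the design matrix comfortably
   overdetermined; order 3 (20 terms) is available but close to the
   patch count and easy to overfit.
   The regression target defaults to the illuminant-weighted colorimetric
   XYZ of the measured patch reflectances; regressing directly on the
   spectrometer's own XYZ readings is exposed as an option
   (`xyz_target="spectrometer"`), since instruments report both.
2. **Spectral basis**: mean-centred PCA of the 24 patch reflectances
   (scikit-learn PCA, full SVD). `k` defaults to the smallest number of
   components explaining ≥ 99.9 % of variance, capped at 12; with three
   chromatic degrees of freedom available from a trichromatic camera,
   retaining many more components than the camera can distinguish only
   amplifies noise.
3. **Transformation matrix** `M` (k×q): regresses PCA scores on the
   expanded corrected XYZ. The same expansion order is used on both
   regressions by default.

Reconstruction is affine in feature space (both regressions include a
constant term); the midpoint property — the reconstruction of averaged
scores equals the average of reconstructions — is tested directly.
Reconstructed reflectance is clipped to [0, 1] by default (negative
reflectance is unphysical); the clipped band fraction is reported per
pixel so clipping is never silent.

Separate models should be fitted per illumination modality (white-light
vs narrow-band); the model carries a modality tag.

### Failed transformations

A pixel is masked when its reconstruction is non-finite or when more than
half of its bands required clipping (threshold configurable); a frame with
more than 20 % masked pixels is flagged as a failed conversion. These are
operational definitions — the phenomenon (some frames do not convert
usefully) is real, but no published criterion exists, so the thresholds
are package choices.

## Band analysis and simulated NBI

The analysis window defaults to 415–540 nm — 126 bands inclusive on the
1 nm grid — where the three tissue classes separate most strongly in
reflectivity. Simulated narrow-band rendering integrates each pixel
spectrum against two Gaussian passbands (centres 415 and 540 nm, 30 nm
FWHM; both configurable), maps the 415 nm response to the blue and green
display channels and the 540 nm response to red, min–max normalises over
the whole image jointly across channels (preserving channel ratios), and
sRGB-encodes. Real endoscope display processing is proprietary; per-image
min–max is a stated default, and the rendering is scale-invariant to
cube-wide rescaling as a consequence.

## Evaluation layer

Frame reduction: a frame's true class is the most severe ground-truth
class (SCC > dysplasia > normal); predictions are matched to truths
greedily in descending confidence (ties: larger IoU, then lower index) at
IoU ≥ 0.5; the predicted class is the most severe matched class, or
normal when nothing matched; any prediction on a truth-free frame makes
it a false positive of its class. Severity-max is the clinically
conservative choice where multiple lesions coexist.

Metrics: sensitivity, specificity, precision, F1, accuracy on the binary
collapse; per-class sensitivity/precision/F1, overall accuracy and Cohen's
kappa on the 3×3 matrix. Two specificity definitions are always
co-reported: the standard one-vs-rest TN/(TN+FP), and the "paper-variant"
(true non-class frames classified into their own correct classes), which
is the definition that reproduces the reference study's per-class table.
Rounding — integer percentages, kappa to two decimals, half-up — is
applied only at report serialisation; internals keep full precision.
Undefined ratios (empty rows/columns, single-class kappa) are reported as
`None`, never coerced to zero.

The embedded reference count tables are recomputed on every run;
`find_inconsistencies()` flags the printed cells that disagree with the
counts they accompany (five such cells exist: two detection specificities,
two classification accuracies, and one kappa printed as 0.92 where the
matrix gives 0.84). The package reproduces the matrix-consistent values
and reports the discrepancies rather than matching them.

## Composite detection loss

The per-batch loss is `(1/N) Σ [0.5·L_cls + α·L_obj + 0.05·L_box]` over
matched positive samples. `L_cls` is cross-entropy with probabilities
clamped at 1e-12; `L_box` is 1 − CIoU with the standard centre-distance
and aspect-ratio penalties; `L_obj` is binary cross-entropy between
predicted objectness and the prediction–truth IoU — an interpretation:
the loss is described as a confidence loss comparing predicted and actual
boxes, and BCE-against-IoU is the convention in single-stage detectors of
this family. The objectness gain α is piecewise constant in ground-truth
area with small : medium : large ratio 4 : 1 : 0.4; only the ratio is
published, so the base defaults to 1.0 (α ∈ {4, 1, 0.4}) and the area
thresholds default to the common 32² and 96² px² convention. The
positive-sample rule (size ratio within 4×, centre within the cell or one
of two adjacent cells) is exposed as a standalone predicate; there is no
network, training loop, or NMS here.

## Synthetic data: what it emulates and what it does not

All fixtures are generated, seeded, and deterministic across platforms
(one `numpy` Generator per call).

**Spectra.** Every generated reflectance is a positive mixture of three
shared broad Gaussian endmembers (centres 450/550/650 nm, widths
55/60/65 nm) over a fixed 0.03 baseline, with mixing weights bounded so
values stay inside [0.02, 0.95] without clipping. Three degrees of freedom
is exactly what a trichromatic camera can measure, which makes the
noiseless calibration round trip mathematically exact — the closed-loop
tests (patch recovery < 1e-6, end-to-end region recovery < 1e-3) rest on
this design. Real reflectance spectra are not confined to any
3-dimensional subspace, so real-world reconstruction error is bounded
below by the energy outside the calibration basis; the passing closed-loop
tests certify the fitting machinery, not field accuracy. For the same
reason the synthetic tissue classes are built in the same endmember span
as the checker — a deliberate idealisation.

**Tissue classes.** Default endmember weights place mean 415–540 nm
reflectance at 0.648 (normal), 0.453 (dysplasia), 0.272 (SCC) — ordered
with margins ≥ 0.05 — emulating increased superficial microvascular
absorption with neoplastic progression. Within-class variability is
Gaussian weight jitter with σ = 0.015.

**Camera.** Forward model: XYZ → linear sRGB → 3×3 channel mixing (default
a mild cross-talk matrix) → optional per-channel quadratic distortion →
additive Gaussian noise in linear RGB → gamma encode. Noise before gamma
encoding is the physically sensible place for sensor noise and yields the
monotone noise-vs-recovery-error behaviour the tests assert (σ ∈
{0, 0.002, 0.01}, averaged over 20 seeds).

**Illuminants.** `flat`, `broadband` (smooth, strictly positive), and
`dual-narrowband` (Gaussians at 415/540 nm, 30 nm FWHM). Exact grid
integration puts 1.42 % of the dual-narrowband energy outside 390–570 nm
(the 415 nm lobe's lower tail dominates); the test freezes that computed
value.

**Scenes and detectors.** Elliptical lesions on a normal background
(severity wins on overlap), tight per-lesion boxes, and a detector
simulator with configurable sensitivity, per-class confusion, and
false-positive rate. Two modes: Bernoulli sampling, and deterministic
largest-remainder count allocation (applied per true-class group) so
fixtures hit target tables exactly. `frames_from_confusion_matrix` emits
frames whose evaluation reproduces any given 3×3 matrix cell-for-cell.
Not emulated: endoscopic texture, specular highlights, shadowed regions,
magnification — the known failure modes of real systems are outside what
these fixtures can probe.

## Problem sizes

The test suite runs small by design: checkers are always 24 patches,
conversion tests use frames up to 96×128 pixels (the end-to-end recovery
test needs ≥ 2000 pixels per region so the region-mean sampling error
σ_w/√N sits below the 1e-3 bound), the noise-monotonicity check averages
20 seeds, and evaluation fixtures expand the reference matrices into their
full 602–716 frames. The acceptance script uses the same sizes.

## Known limitations

- The instrument-specific calibration errors a real endoscope/spectrometer
  pair would produce cannot be computed here; the error-assessment
  machinery (XYZ RMSE, spectral RMSE, CIEDE2000 color difference) is
  exercised on synthetic data instead.
- The embedded observer is an analytic approximation (see above).
- Detector behaviour is simulated at the frame-outcome level; no network
  inference happens in this package.
- ENVI cube I/O supports the package's own float32 BSQ layout, not the
  full ENVI header zoo.
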