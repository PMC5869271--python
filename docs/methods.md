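# Methods

## Estimation model

The quantity being estimated is the *relative* anthocyanin concentration of
a tissue sample, expressed as extract absorbance units per cm² of fresh
tissue (AU·cm⁻²): replicate absorbance readings at the pigment's λ_max are
averaged, corrected for chlorophyll in photosynthetic tissue by subtracting
0.24·A₆₅₃, floored at zero (flagged) if the correction overshoots, and
divided by the sampled area. This biochemical value is the response variable
throughout; the package never attempts molar quantification.

The predictors are scalar color indices computed from either of two optical
measurements of the same tissue:

* **Reflectance spectra** (percent relative to a white standard, nominally
  300–800 nm). Window-based indices aggregate reflectance over inclusive
  wavelength windows. Aggregation defaults to the *band mean* rather than
  the raw sum because the defining windows have unequal widths (e.g.
  760–800 nm vs 540–560 nm); a mean makes the two operands of every ratio
  dimensionally comparable and the index invariant to grid density. The raw
  sum is retained (`mode="sum"`) to reproduce literal summation formulas;
  on a uniform grid the two differ only by per-window point counts.
* **Calibrated RGB channel means** from a region of interest in a linear
  digital photograph.

Indices that compare the green channel (or the 545–565 nm band) against red
and blue carry the anthocyanin signal, because anthocyanins absorb at
~520–560 nm and reflect the neighbouring red and blue: AC_CD, AC_CR, AC_CB,
R:G ratios and the channel strengths. Hue, lightness, saturation,
brightness, chroma and the segment-analysis pair (H_SC, C_SC, computed from
the four 100-nm segments of 300–699 nm) complete the set of fourteen per
branch.

Two algebraic identities follow from the definitions and are enforced as
invariants: AC_CR·AC_CB = 2 and S_green + S_red + S_blue = 1 whenever
defined.

### Numerical conventions

* Window bounds are inclusive at both ends, evaluated with a 1e-9 nm
  tolerance on whatever grid the spectrum carries; grids coarser than 1 nm
  trigger a warning.
* Peak-wavelength hue H breaks ties toward the lowest wavelength
  (deterministic output).
* In H_SC, sign(0) is defined as 0 and flagged `sign-degenerate`; the
  result is mapped into [0, 2π). C_SC = 0 leaves H_SC undefined.
* The image-branch hue formula H = (g−b)/((I_max−I_min)×60) is implemented
  exactly as defined, dividing by 60. Standard HSL hue multiplies by 60;
  both conventions are available (`hue_convention={"paper", "hsl"}`), the
  as-defined one is the default.
* Any index whose denominator degenerates on a given sample is stored as
  NaN with a reason flag; a 14-index sweep never raises.
* The normalized family (H, H′, B, L, S) consumes channel values divided by
  the channel maximum (255/65535, or an explicit cap such as 100 for
  percent-reflectance data); the remaining indices consume raw channel
  means. All of the latter are ratios except AC_CD and C′, so the split is
  consequential only for those two scale-bearing indices.

## Image calibration

The camera contract is "linear RGB in, percent reflectance out". Each
channel is calibrated independently by the affine map sending the mean
device value of a dark gray standard to its known reflectance (default
9.11%) and that of a light standard to its reflectance (default 60.90%) —
six parameters in total, exactly determined by the two constraints, with the
fixed-point property asserted after every fit. One chart's map can be
applied to a batch of frames shot under the same light. Gamma-encoded input
can be pre-linearized with a power law; proprietary RAW decoding is out of
scope. Pixels at ≥ 99.5% of the sensor maximum are tracked as clipped;
standards with > 1% clipping raise a warning, mirroring the deliberate
underexposure a careful protocol uses to avoid saturation.

Rectangles are 0-based, origin top-left, half-open in width and height;
rectangle and mask representations of the same pixel set give identical
statistics.

## Regression calibration and validation

Each index is related to concentration by ordinary least squares, optionally
after natural-log transforms of either variable (explicit per-analysis
flags; nothing is transformed automatically). Goodness of fit is r²
(identical to the squared Pearson correlation); fits refuse n < 4 or
zero-variance predictors. Family-wise error across the 14 indices of one
dataset is controlled with the Holm step-down — sorted p-values compared
against α/(k−i+1), stopping at the first failure — which dominates the
plain Bonferroni α/k threshold; both decisions are reported because
"sequential Bonferroni" is used loosely in the literature for either.
Prediction error is NRMSE = 100·RMSE/(max−min of the observed values),
which is invariant to common affine rescaling and comparable across
variables with different units.

Validation regresses independently observed concentrations on model
predictions (back-transformed to the original scale first — the quantity
being validated is concentration, not log-concentration) and tests the
slope against 1 with t = (slope−1)/SE on n−2 df. An exact fit has SE = 0;
the t statistic is then defined as 0 when the slope is 1 and ±∞ otherwise.

## Synthetic specimens

The generator supplies paired (concentration, spectrum, image) samples with
the optical structure the method assumes, so every stage is testable
end-to-end without field data.

**Tissue optics.** Reflectance is a smooth baseline attenuated Beer–Lambert
style, R(λ) = baseline(λ)·10^(−(c_anth·ε_a(λ) + c_chl·ε_c(λ))), with
Gaussian absorptivity bands. Defaults, chosen once to mimic an
anthocyanin-bearing petal: logistic baseline rising from ~10% (UV) to ~70%
(NIR); anthocyanin band at 530 nm (σ 35 nm) with strength 2.5 per AU·cm⁻²,
so the top of the default petal concentration range (0.33 AU·cm⁻²) gives a
peak optical density of ≈ 0.83 and drops 550-nm reflectance to ~13% — the
level of the darkest petals such surveys encounter, and a spectrum with the
characteristic two-peak (450/650 nm) shape with a 550-nm trough;
chlorophyll bands at 430 and 660 nm (strengths 1.0 and 0.8 per unit);
multiplicative lognormal measurement noise with CV 5%, a typical
portable-spectrometer repeatability. Concentrations are drawn uniformly
over (0.04, 0.33) AU·cm⁻² by default, a petal-like range.

**Camera.** Three Gaussian channel sensitivities (centers 600/530/460 nm,
σ 30 nm) integrate the spectrum under a flat illuminant; each
sensitivity×illuminant product is normalized to unit sum, so a flat R%
spectrum maps to gain·R + offset digital numbers. The sensor is therefore
affine in band-weighted reflectance and exactly invertible by two-standard
calibration — the regime the calibration model assumes. Default gains
(560/580/600 DN per %) and offsets (800/900/1000 DN) keep the light
standard near 56% of the 16-bit range (underexposure margin); per-pixel
Gaussian read noise has SD 30 DN.

**Renderer.** Each frame contains the two gray-standard patches (rendered
through the same camera from their reference reflectances) and a tissue
region mixing a pigment-rich and a pigment-poor phase through a pattern
field: uniform, hard-edged stripes with configurable period and duty,
random disks, or a recursive branching vein skeleton. Visual realism is not
the aim; the patterns exist to create controlled within-ROI heterogeneity.
All randomness flows from one seeded generator per dataset, so a fixed seed
reproduces every file bit for bit.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: co-pigmentation, pH and metal-complex
color shifts; carotenoid interference; specular highlights, shading and
non-flat illumination; trichomes and three-dimensional cell geometry;
camera optics beyond a per-channel affine response (vignetting, chromatic
aberration, demosaicing). Real deployments must verify that anthocyanins
dominate the visible color of their samples.

## Problem sizes in the verification suite

The acceptance checks use sample sizes matching the study design the
package targets: calibration fits on n = 30 with validation on independent
n = 28, repeated over 200 seeded replicates; identity sweeps over 1,000
random triplets and 1,000 random spectra; cross-branch agreement over 20
uniform specimens; monotonicity on a 20-point noise-free concentration
grid. Images default to 96×128 px, which leaves every ROI thousands of
pixels while keeping simulation fast.

## Known limitations

* The affine sensor model is declared, not inferred: cameras whose
  processing is nonlinear beyond a single power law will not calibrate
  correctly.
* Index-vs-concentration relations are mildly nonlinear under Beer–Lambert
  optics; at the default noise level a straight line captures them well,
  but wider concentration ranges may need the ln transforms the fitting
  module exposes.
* Only ROI means feed the indices; per-pixel index maps are out of scope.
* The chlorophyll correction uses a single fixed coefficient (0.24) and a
  single reference wavelength (653 nm); tissues with unusual chlorophyll
  a/b ratios may be under- or over-corrected.
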