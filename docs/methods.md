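# Methods

## Per-eye measurement chain

Each eye is measured from three grayscale en-face slabs (SCP, DCP, CC;
nominally 245×245 px over a 3×3 mm scan), a traced FAZ polygon per plexus,
and the eye's axial length.

**Magnification correction.** The physical scan length follows Bennett's
axial-length method, `s_actual = p·q·s` with `q = 0.01306·(AL − 1.82)`.
The camera factor `p` is instrument-specific and not publicly documented;
the default `p = 3.382` is calibrated so an emmetropic eye with
AL = 24.46 mm is magnification-neutral (`s_actual = s = 3.0 mm`). Axial
lengths outside 20–30 mm are rejected as implausible. The analysis annulus
(inner ⌀ 1.0 mm, outer ⌀ 2.5 mm, centered on the image center because the
scans are fovea-centered) is rescaled into pixels with the eye-specific
mm/px scale rather than resampling the image; its physical area is then
constant across eyes to <2% discretization error.

**Large-vessel (LV) segmentation.** The SCP image is filtered with a Gabor
bank (wavelengths 8/12/16 px, 8 orientations, per-pixel maximum magnitude,
FFT convolution on the mean-removed image) and a multiscale Frangi
vesselness (σ = 2/3/5 px, bright-on-dark). Both responses are min–max
normalized and fused by pixelwise product, which rewards agreement; the
fused response is raised to a power (default 2.35) and binarized strictly
above its mean. The response support is a halo around the trunk, so it is
then refined against the image itself: trunk vessels carry a stronger flow
signal than the surrounding capillaries, and an Otsu threshold over the
vessel-bright pixels inside the (3 px-dilated) response support recovers
the trunk boundary at the intensity step. Components smaller than 100 px
or with a major axis below 60 px are then removed so only trunk vessels
remain, and a trunk-presence gate — the ratio of the 99.9th to the 90th
percentile of the fused response must exceed 10 — declares texture-only
images trunk-free (capillary texture has no heavy, localized response
tail). On stroke phantoms spanning large-vessel densities of 4.5–9.5% the
refined segmentation tracks truth with slope 1.02, bias −0.08 ± 0.08 pp
and Dice 0.99, and returns exactly empty masks on trunk-free images.

**Binarization semantics.** Plexus vessels: intensity ≥ mean of the whole
image (ties are vessel), then FAZ pixels forced to background; invariant
under positive affine intensity rescaling. CC flow voids: pixels strictly
below mean − 1 sample SD, with mean/SD computed over pixels outside the
(2 px-dilated) LV-artifact mask; excluded pixels appear in neither the
statistics nor the output, and the flow-deficit denominator is likewise
the annulus minus the excluded area — an artifact-masked pixel is not
validly imaged area, and this convention keeps the flow deficit unbiased
regardless of segmentation quality. A constant image yields zero voids.

**FAZ morphometry** is computed on the traced polygon, not a raster mask
(raster perimeters systematically overestimate): area by the shoelace
formula × scale², circularity as perimeter over the perimeter of the
equal-area circle (≥1, scale- and rotation-invariant). Polygon
rasterization for FAZ masking uses even-odd scanline filling with
half-open spans at integer pixel centers, an unbiased, tie-stable
convention.

**PD decomposition.** The capillary-only perfusion density removes the LV
mask dilated by a removal radius from the numerator only. The radius is
deliberately larger than the vessel edge: large trunks displace and shadow
the surrounding capillary signal, so the published decompositions of total
vs capillary-only vs LV-only density are mutually consistent only with a
removal zone substantially wider than the trunk itself. The default
(5 px ≈ 0.06 mm) is calibrated on the synthetic cohort geometry so the
three densities are internally consistent for ~4 px-wide trunks; it is a
configurable parameter, and studies with different vessel calibers should
recalibrate it.

## Synthetic eyes and cohorts

The generator emulates the study conditions of an MS vs control OCT-A
comparison (58 MS participants / 100 eyes vs 78 controls / 136 eyes, both
eyes included when image quality allows).

* **Capillary beds** are band-pass-filtered Gaussian random fields
  (difference of Gaussians at the capillary scale, default 2 px)
  thresholded at the exact count quantile; vessel pixels render at
  intensity 170 over background 40 with additive noise (SD 12), so the
  mean-intensity threshold separates the classes at >4σ and binarization
  recovers the planted mask essentially exactly. Inside the analysis
  annulus the planted density equals the target exactly (region-exact
  quantile selection); outside, the same field continues at matched
  density.
* **Large vessels** are 4 smooth, slightly curved strokes crossing the
  scan while avoiding the FAZ, rendered at intensity 230; the common
  stroke width is solved by bisection so the in-annulus LV density hits
  its target to ≲0.05 pp.
* **FAZ boundaries** are star-convex polygons: a circle of exactly the
  target area with low-order random harmonic radius modulation; the
  amplitude is solved by bisection to reach a target circularity. Both
  plexus images are carved vessel-free inside their FAZ.
* **CC texture**: bright field (170) with void blobs (70) from a granular
  band-pass field, planted uniformly at the exact annulus rate; pixel
  noise SD 8 keeps the mean−1 SD threshold ≈47σ away from either class.
* **Cohorts**: outcomes are drawn per eye as group mean + participant
  effect + eye effect, giving exchangeable inter-eye correlation ρ
  (default 0.5). Default group means/SDs reproduce the reference study's
  characteristics and outcome tables; per-eye SDs are back-computed from
  the published standard errors of clustered means with the design-effect
  `1 + ρ(m−1)`. Covariates: age 39/41 ± 11 y, male fraction 0.36/0.33,
  IOP 15.4 ± 2.5 / 17.3 ± 2.8 mmHg, axial length 23.3/23.2 ± 0.9 mm
  (clipped to 21–26.5 mm so the 2.5 mm annulus always fits the 3 mm scan;
  the published ±0.1 is read as a standard error), hypertension
  prevalence 0.10, integer signal strength 6–10 from N(9.5, 0.9), MS
  duration ≈ N(8, 6) y clipped ≥ 0.5, episodes 1 + Poisson(2.5), RNFL
  95.3/86.7 µm. Where the reference tables do not state a value
  (hypertension prevalence, duration and episode distributions) the
  defaults are chosen as clinically typical for an RRMS cohort without
  optic neuritis. A master seed spawns per-eye seeds via
  `SeedSequence.spawn`; identical config + seed reproduces cohorts bit
  for bit. The capillary-only (w/o-LV) density is not independently
  controllable — it is implied by the total PD, the LV density and the
  removal geometry — and its stored ground truth is obtained by direct
  counting, like every other stored truth.

**What the generator does not emulate.** Speckle, projection and motion
artifacts, signal-strength-dependent contrast, B-scans and segmentation
errors, real capillary network topology (the texture is a thresholded
random field, not a vascular tree), and CC large-vessel *artifacts* (the
artifact-exclusion step runs on a clean CC, so its effect on real shadowed
data is untested). Passing round-trip tests therefore demonstrate the
internal consistency and calibration of the measurement chain under the
stated image model, not performance on clinical scans.

## Statistics

All regressions are linear GEE (identity link) with exchangeable working
correlation and participant as the cluster. Standard errors use the
bias-reduced (Mancl–DeRouen) sandwich with a t reference at
clusters − parameters degrees of freedom: with ≤2-eye clusters at typical
study sizes the plain sandwich + normal reference is anticonservative
(simulated type-I ≈ 7.8% at 30 clusters vs ≈ 5.3% for the bias-reduced
variant). Adjusted group means are marginal predictions with covariates at
their sample means (proportions for binaries); their SEs propagate the
full coefficient covariance. Covariate selection keeps age, gender,
hypertension and signal strength and adds candidates (IOP, axial length)
with univariate GEE P < 0.10. Characteristics use Shapiro–Wilk per group
at α = 0.05 to gate t-test vs Kruskal–Wallis; categorical tables switch
from chi-square to Fisher's exact when any expected cell is below 5.
Degenerate inputs (no variation) return P = 1 with a warning. No
multiplicity correction is applied across the nine outcomes; group
contrasts flag P < 0.05 and characteristics P < 0.10.

Mean/SD support conventions (whole image for plexus thresholds; non-
excluded pixels, sample SD, for the CC) and threshold tie rules are fixed
as stated above so degenerate images behave deterministically; at 60k
pixels the sample-vs-population SD distinction is negligible.

## Problem sizes used in validation

The round-trip experiment generates and measures the full 236-eye cohort
(~3 min on one CPU) and checks each covariate-adjusted MS-group mean
against its configured reference within 2 model SEs. Frequentist
calibration uses 300 replicates of reduced cohorts (30+30 eyes for type-I
error; 58 participants/100 eyes for CI coverage) at the truth-table level
— generating 300 image cohorts would test the same statistics at ~50× the
cost, and the image chain's per-eye fidelity is already established by
the round trip. Density oracles run on 16×16 toy masks where brute-force
counting is exact.

## Known limitations

* The camera factor `p` is a calibration convention; absolute FAZ areas
  and densities from other instruments require the instrument's own `p`.
* Large-vessel segmentation is calibrated for trunks a few pixels wide on
  a 245 px / 3 mm grid; other scan protocols need re-tuned wavelengths,
  scales and gates.
* The LV-removal radius encodes a specific capillary-free-zone geometry;
  the published decomposition it reproduces is not additive, and the
  "right" radius for clinical data is unidentifiable without vessel-level
  ground truth.
* GEE adjusted means use the overall sample as the covariate reference
  distribution; other reference choices shift both groups equally.
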