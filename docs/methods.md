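# Methods

## The measurement model

A confluent cell layer on a rectangular micropattern behaves, for the
purpose of this package, as an oriented texture: the phalloidin signal
has a locally dominant direction, and across rectangles those directions
scatter around a population mean with an intrinsic sign (the chirality).
Two modelling commitments follow:

* **Orientation, not direction.** A fibre at θ and at θ+180° is the same
  fibre, so angles are *axial*, live on (−90°, 90°], and all statistics
  use the doubling device: map θ → 2θ onto the full circle, compute
  ordinary circular statistics, halve the results (mean and SD alike, so
  reported values are directly comparable to half-circle angles).
* **One angle per rectangle.** Each surviving rectangle contributes a
  single dominant angle from its central window; rectangles, not cells,
  are the sampling unit. No within-dish clustering is modelled.

### Angle conventions

Angles are reported in the display frame as seen from the
culture-medium side: θ = 0 along the rectangle's long axis, θ > 0 for
left-down → right-up textures (counter-clockwise), θ < 0 for
left-up → right-down (clockwise). Because array rows increase downward,
the display angle is the negative of the texture-direction angle in
(row, col) coordinates; this sign is locked by construction against the
synthetic stripe generator (a stripe built to run left-down → right-up
must and does measure positive) and guarded at run time by the
fiducial flip check, since a mirrored image negates every angle.
The θ = ±90° tie maps to +90° (half-open interval).

## Structure-tensor orientation

Gradients are Gaussian derivatives (`grad_sigma`, default 1.0 px — small
enough to resolve fibre texture at any realistic pixel size, large
enough to suppress single-pixel noise; configurable). The tensor is
averaged uniformly over the whole crop, excluding a ~3σ border where the
derivative filters see edge padding. The dominant angle is the minor
eigenvector (the direction of *least* gradient variance); coherence is
the normalised eigenvalue contrast. A crop whose gradient energy is
below 1e−12·(intensity variance + 1) is flagged indeterminate and
excluded downstream rather than raising — blank crops are data, not
errors. The scale-relative guard keeps the rule invariant under affine
intensity rescaling, which the whole estimator is (gradients are linear;
the angle and coherence are homogeneous of degree zero).

Orientation must be measured on the *secondary* crop: the primary
window contains the texture/background boundary of the pattern itself,
whose straight edges contribute axis-aligned gradients that bias the
whole-window estimate by several degrees (measured ~3° on synthetic
scenes). The central window sees only interior texture.

## Cropping and the coverage filter

* Primary window: rectangle + half-gap margins (900 × 600 µm at default
  geometry); vertical rectangles rotated 90° clockwise in display
  coordinates. The rotation bookkeeping is verified by the property that
  horizontal and vertical rectangles carrying the same underlying angle
  measure identically after normalisation.
* Cell-attached area: Otsu's global threshold on the primary crop, holes
  smaller than (20 µm)² closed, centroid as the area centre. Otsu is
  parameter-free and appropriate for the strongly bimodal
  stain/background histogram; a guard rejects crops where the two Otsu
  classes are separated by less than 3× the larger within-class spread,
  which is what pure background noise produces. The segmentation method
  is a free choice here (the area-detection rule is otherwise
  underdetermined); centroid rather than bounding-box centre, and the
  area fraction is taken against the *nominal pattern* (600 × 300 µm),
  not the crop window.
* Inclusion rule: area fraction ≥ 0.8 (configurable
  `coverage_threshold`).
* Secondary window: 400 × 200 µm centred on the detected centre,
  clamped (not padded) at the primary crop's edges so no intensity data
  is fabricated.

## Circular inference

* **CI for the mean.** Large-sample interval for the doubled mean
  direction based on the circular dispersion
  δ̂ = (1 − ρ̂₂)/(2R̄²), half-width arcsin(z √(δ̂/n)); percentile
  bootstrap (9 999 resamples, seeded) when n < 25 or the arcsin argument
  reaches 1. Endpoints are halved back and returned centred on the mean
  (an interval spanning ±90° is left unwrapped so it always contains the
  mean). Measured coverage at the package's own conditions (n = 300,
  κ = 6, 5 000 simulations) is 95.0–95.5%.
* **One-sample mean test.** CI inversion: reject μ = μ₀ iff μ₀ (taken
  axially) falls outside the interval. This is literally the decision
  rule the chirality call needs, and it inherits the CI's calibration
  (type-I ≈ 5%).
* **Chirality call.** CW if rejected with mean < 0, CCW if rejected with
  mean > 0, indeterminate otherwise (including all n < 10 samples).
* **Watson's U².** Computed on doubled angles from the pooled order
  statistics; over a tied block both empirical CDFs jump together, so
  the cumulative difference d is replaced by the block midpoint (the
  mean of d before and after the block) — an order-independent choice
  that is antisymmetric under swapping the groups and reduces to the
  untied statistic otherwise. p-values by label permutation (default
  9 999, seeded; exact null guarantee at any n); the asymptotic series
  P(U² > x) = 2 Σ (−1)^(m−1) exp(−2m²π²x) is available as
  `method="asymptotic"`. Null p-values are uniform by KS test at the
  package's calibration conditions. No multiple-testing correction is
  applied across pairwise tests; users comparing many groups should add
  their own.
* **Kurtosis.** The per-group summary reports the *linear* excess
  kurtosis of the half-circle angles, a peakedness index for alignment
  histograms. Note it is not monotone in the von Mises concentration:
  it rises from −1.2 (uniform) to a peak near κ ≈ 2 and decays to 0
  (Gaussian limit) as κ → ∞, so it discriminates sharpness only among
  broad distributions (κ ≲ 2, circular SD ≳ 20°), which is the regime
  where alignment-quality comparisons actually operate.
* Degenerate inputs: an exactly balanced sample (doubled resultant ≈ 0,
  e.g. {−45°, +45°}) has no defined mean and raises; a zero-spread
  sample has SD 0 and a zero-width CI.

## The synthetic scene generator

The generator's defaults are the study conditions the pipeline is
validated under, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| rect_length × rect_width | 600 × 300 µm | pattern size |
| gap | 300 µm | spacing, both directions |
| n_rectangles | 453 | rectangles kept on the tape |
| layout_diameter | 19 mm | circle containing the lattice |
| um_per_px | 2.0 | image scale (instrument-dependent, free) |
| mu_deg, kappa | −8°, 6 | axial von Mises law of true angles |
| fiber_wavelength | 20 µm | stripe period of the texture |
| coverage | U(0.6, 1.0) | per-rectangle covered-area fraction |
| noise_sd | 0.02 | additive Gaussian noise (normalised units) |
| background_level | 0.05 | uncovered-surface intensity |

Layout: rows of alternating orientation (horizontal rows 300 µm tall
with 900 µm x-pitch, vertical rows 600 µm tall with 600 µm x-pitch,
300 µm gaps everywhere), cells fully inside the circle and clear of the
central fiducial zone, the n closest to centre kept. This reproduces
453 rectangles at the published tape dimensions, which a single square
lattice cannot (only ~320 fit). `orientation_mix` sets the fraction of
vertical *rows* deterministically by cumulative rounding; the realised
per-rectangle fraction differs slightly (vertical rows pack more
rectangles per row).

Texture: an oriented sinusoid at 0.55 ± 0.20·contrast (normalised
units) over a 0.05 background, random phase per rectangle. The offset
exceeds the amplitude so the covered area is uniformly brighter than
background and Otsu segments the *area*, not individual bright stripes;
the sinusoid gives the structure tensor a closed-form dominant
direction, making the generator an analytic oracle. Coverage is a
centred sub-rectangle of equal aspect ratio (area fraction exactly the
drawn coverage, so the 80% filter's expected outcome is known in closed
form). Vertical rectangles are textured at θ*+90° so the pipeline's
rotation recovers θ*. One seed fixes angles, coverages, phases and
noise; identical inputs give bit-identical scenes.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: cell-scale structure (no cells,
no nuclei, no fibre curvature or branching), intensity inhomogeneity
(no vignetting, no stitching seams, no focus variation), irregular
attachment footprints (real detachment is not a centred rectangle), and
any dependence between neighbouring rectangles. Results on synthetic
scenes validate the *pipeline arithmetic* (registration, rotation
bookkeeping, filtering, tensor estimation, statistics), not the
biological segmentation difficulty of real stains.

## Problem sizes

The validation suite uses a 120-rectangle scene at 4 µm/px for
module-level checks and a full 453-rectangle scene at 3 µm/px (6.5k px
canvas) for end-to-end recovery; statistical calibrations use 5 000
simulated samples (CI coverage, type-I) and 500 replicates × 999
permutations (U² null). At these sizes the whole suite runs in well
under a minute of compute; scenes at the 2 µm/px default scale roughly
double the image work and change no conclusion.

## Known limitations

* The dominant angle is a single whole-window estimate; strongly bimodal
  textures (crossing fibre populations) are summarised by a compromise
  angle with low coherence rather than detected as bimodal.
* The Otsu-based coverage estimate assumes a bimodal histogram; very low
  contrast stains or strong shading would need a different segmenter
  behind the same interface.
* The flip check needs the fiducial in the field of view and roughly at
  the expected scale; rotation registration beyond what the fiducial
  anchor provides (the tape assumed already angle-adjusted) is out of
  scope.
* CI endpoints near ±90° are reported unwrapped (outside the nominal
  interval) to keep mean ∈ CI; consumers that need wrapped endpoints
  must wrap axially themselves.
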