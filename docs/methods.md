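# Methods

## The measurement

`fiberaniso` quantifies how strongly the fibrous structures in a 2D
grayscale image share a common orientation, as a function of the length
scale at which the image is examined.  The pipeline is:

1. **Continuous wavelet transform.**  At each analysis scale `a` the image
   is smoothed with an isotropic Gaussian and the gradient of the smoothed
   field is taken.  This is equivalent to correlating the image with the
   two first-derivative-of-Gaussian wavelets ψ1 = ∂ϕ/∂x and ψ2 = ∂ϕ/∂y
   dilated to scale `a` with the a⁻² (L¹) normalisation; the two components
   give a modulus M (strength of the sharpest local intensity variation)
   and an argument A (its direction, oriented toward increasing intensity).
2. **Modulus maxima (WTMM).**  Points where M is locally maximal along the
   direction of A trace the multiscale edges of the image; at a fixed scale
   they organise into connected maxima chains.
3. **Angle density.**  The arguments of all WTMM points are binned into a
   probability density P_a(A) over (−π, π].  For fibers, gradient
   directions sit perpendicular to the fiber axis, so aligned fibers
   produce a density concentrated near two opposite angles.
4. **Anisotropy factor.**  F_a = ∫ |P_a(A) − 1/2π| dA, the L¹ distance from
   the flat (isotropic) density.  F_a = 0 means no preferred direction;
   the supremum 2 is approached when all mass concentrates in a vanishing
   arc.  Because the density is piecewise constant over bins, the integral
   is evaluated as an exact Riemann sum.

Repeating 1–4 over a ladder of scales yields a multiscale anisotropy
profile; cohorts of images are compared per scale with two-sided Wilcoxon
rank-sum tests on per-image F_a values, and profiles are normalised by a
designated control cohort (median / control median per scale).

## Scale conventions

The pixel ladder is geometric from 7 px to 112 px (40 rungs by default).
At the default pixel pitch of 180/512 ≈ 0.352 µm/px these endpoints are
the quoted 2.5 µm and 39.4 µm scales, and the five named scales
(2.5, 4.9, 9.8, 19.7, 39.4 µm) are exact doublings: 7, 14, 28, 56, 112 px.

The quoted scale is interpreted as the **diameter of the smoothing
aperture**: the Gaussian ϕ at scale `a` has standard deviation σ = a/4
pixels, i.e. the scale spans the ±2σ support of ϕ.  This choice is
empirical as well as physical.  Physically, an analysis "at 2.5 µm" should
respond to structures about 2.5 µm across — fiber-diameter sized — which
σ = a/4 delivers, whereas σ = a would average over a ~10 µm window at the
same nominal scale.  Empirically, with σ = a the largest named scale
(112 px on a 512 px frame) retains so few, so strongly angle-correlated
maxima that the finite-sample floor of F_a rises towards its supremum for
*any* input, isotropic white noise included; with σ = a/4 white noise keeps
a small F_a at every scale and strongly aligned fibers remain clearly
anisotropic at the largest scale, which is the behaviour the method is
designed around.  The convention is exposed as
`WaveletConfig.sigma_per_scale` (default 0.25).

## Numerical choices

* **Kernels** are sampled on ±4σ supports; the truncated odd-symmetric
  supports cancel exactly, so adding a constant to the image leaves the
  transform unchanged to round-off.
* **Convolution** is FFT-based on a mirror-extended grid: each side is
  reflect-padded by the kernel half-support (then rounded up to an
  FFT-friendly size with inert zero rows) and the result cropped back.
  There are therefore no periodic wrap seams, and maxima chains remain
  complete even when the smoothing support is a sizeable fraction of the
  frame.  Maxima within 0.5 σ of the border are still discarded because
  reflection can create kink artifacts exactly at the frame edge.
  A pure periodic mode (`boundary_mode="wrap"`) is kept for completeness.
* **Directional maximum test**: the modulus at ±1 px along the argument
  direction is obtained by bilinear interpolation; the comparison is strict
  forward and non-strict backward so plateau ties resolve deterministically
  to a single pixel.
* **Modulus floor**: maxima below 10⁻⁶ of the response maximum are
  discarded (suppresses plateau noise), and a response whose maximum is
  itself at round-off level relative to the input intensity (< 10⁻¹²×) is
  treated as flat — a constant image yields an empty maxima set, not noise.
* **Angle binning**: 72 bins of 5°, matching the 5° granularity of the
  calibration design.  The finite-sample F_a of an isotropic image grows
  with the bin count, so reported F_a values are tied to B = 72.  Angles
  enter unweighted — each WTMM point counts once regardless of modulus;
  a modulus-weighted variant exists behind a flag but is not the default.
* **Missing scales**: a scale whose post-exclusion maxima set is empty is
  reported as NaN, never zero; cohort medians at a scale use only images
  with a defined value there.

## The synthetic fiber generator

Calibration images emulate second-harmonic-generation collagen fields of
view: 512×512 px spanning 180 µm, 50 rectangles ("fibers") per image with
centres uniform over the full frame (silent clipping at the edges), lengths
uniform in 40–60 µm, one of four diameters (2, 4, 6, 8 µm), and
orientations uniform in a configurable range [θmin, θmax].  Rectangles are
rendered with anti-aliased edges (fractional coverage) at intensity 255 on
a 0 background and composited by maximum, so crossing fibers form a union
rather than adding.  The rendered frame is degraded by a normalised pillbox
(circular-averaging) kernel of radius 3 px followed by a normalised linear
motion kernel of length 5 px whose direction is drawn uniformly per image
(recorded in the manifest; a fixed direction can be configured).  The
foreground/background levels are immaterial to F_a, which is invariant
under intensity scaling.

The sensitivity design uses 19 nested ranges widening by 5° per side from
perfect alignment [90°, 90°] through [85°, 95°] down to no alignment
[0°, 180°] — nineteen groups give the eighteen consecutive pairs of the
discrimination analysis — at 4 diameters with 100 images per cell
(7600 images).  The white-noise experiment adds, to [60°, 120°] images, a
uniform non-negative noise field on [0, 2kµ] whose mean is k times the
image mean, k ∈ {1, 2, 5, 10, 20}, plus a pure-noise group whose mean
matches the clean image (the choice of mean is immaterial, again by
intensity invariance).

What the generator deliberately does *not* model: fiber curvature or
waviness, 3D stacks, photon (Poisson) camera noise, illumination gradients,
and any spatial correlation between fiber positions.  Passing calibration
therefore shows the estimator recovers *known planted alignment under this
idealised geometry*; it does not by itself validate performance on tissue,
where fibers curve, bundle and vary in contrast.

## The Fourier baseline

The comparison score treats alignment in the frequency domain: the centred
2D spectral amplitude (DC removed, integration restricted to the inscribed
disk so the square spectrum's corners cannot load the diagonal bins) is
summed into 180 one-degree orientation bins over [0°, 180°), and summarised
by the circular resultant of the binned axial data at doubled angle,
R = |Σ S(θ) e^{2iθ}| / Σ S(θ) ∈ [0, 1].  R = 0 for a flat angular profile
and R = 1 for a single loaded direction, with no fitting or thresholding.
A configurable radial band restricts the integration to a chosen
spatial-frequency annulus; the default integrates all radii.  In the
calibration experiments this full-band score discriminates 15–16 of the 18
consecutive pairs, fewer than the wavelet method's 18.  Variants of this
score that sample a single spatial frequency are markedly less sensitive,
and their performance depends strongly on the frequency chosen (the ring
study behind this observation is reproducible with ``radial_band``); the
package deliberately keeps the frequency-agnostic full-band form as the
default rather than privileging any one annulus.

## Statistics

Group comparisons are two-sided Wilcoxon rank-sum (Mann–Whitney) tests on
per-image scores: the exact permutation null when the pooled sample is
≤ 20 and tie-free, otherwise the tie-corrected normal approximation.  A
pooled sample with all values identical returns p = 1 by convention.  The
discrimination count applies the test to each of the 18 consecutive
angle-range pairs at α = 0.05 with no multiplicity correction — a
faithful-reproduction choice, not a statistical recommendation.  The
sampling unit is always the image, never the pooled maxima.

## Problem sizes

The test suite runs the full 19 × 100 sensitivity design for the 4 µm
diameter, the reduced 25-images/group design for all four diameters
(method comparison and monotonicity), the full 7 × 100 noise design at the
five named scales, and 20-image constructed cohorts for the comparison
machinery.  The acceptance script (`scripts/acceptance.py`) recomputes the
full 19 × 100 design for the 4 µm and 2 µm diameters from scratch.

## Known limitations

* The widest consecutive ranges ([5°, 175°] vs [0°, 180°]) sit close to the
  detection limit of a 100-image design: per-image F_a carries the missing
  10° wedge only through a small shift against a finite-sample floor set by
  the 50 fiber draws.  The measured discrimination is reproducible but a
  different seed can drop a single wide pair.
* F_a of a genuinely isotropic image is positive (finite-sample bias) and
  grows with scale as maxima decorrelate and thin out; comparisons should
  always be made at matched scale and bin count.
* The cohort machinery assumes a shared scale ladder and at least three
  images per cohort; it reports per-scale medians and rank-sum p-values
  without multiplicity correction across scales.
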