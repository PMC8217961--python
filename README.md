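# fiberaniso

Multiscale quantification of fiber alignment in 2D microscopy images with
the wavelet transform modulus maxima (WTMM) anisotropy method, together
with a synthetic fiber-image simulator for calibration and a Fourier
angular-amplitude baseline.

## The problem

Fibrillar collagen remodels in tumor microenvironments and in genetic
models that perturb cell–matrix signalling, and the *scale* of the
reorganisation carries information: two tissues can match at fiber-width
scales yet differ completely in their coarse architecture.  Single-scale
alignment scores (FFT-based indices, curvelet tools) cannot see this.
`fiberaniso` measures alignment as a continuous function of scale, so
differences confined to small or large scales — and reversals in between —
become visible.  It is written for imaging scientists analysing
second-harmonic-generation (SHG) or similar grayscale micrographs of
fibrous structures.

## The method

At scale *a* the continuous wavelet transform with first-derivative-of-
Gaussian wavelets (ψ1 = ∂ϕ/∂x, ψ2 = ∂ϕ/∂y, ϕ an isotropic Gaussian)

    T[f](b, a) = (T_ψ1, T_ψ2) = ∇{ T_ϕ[f](b, a) }

is the intensity gradient of the image smoothed at that scale, with
modulus M_ψ = (T_ψ1² + T_ψ2²)^½ and argument A_ψ = Arg(T_ψ1 + i T_ψ2).
The WTMM — points where M_ψ is locally maximal along the direction of
A_ψ — trace the image's edges at that scale and chain into contours.
The probability density P_a(A) of the WTMM angles is flat (1/2π) for an
isotropic image; fiber-dominated images concentrate it perpendicular to
the fiber axes.  The anisotropy factor

    F_a = ∫_{−π}^{π} | P_a(A) − 1/2π | dA   ∈ [0, 2]

is 0 for isotropy and grows with alignment.  Computed across a 40-step
geometric scale ladder (2.5 µm → 39.4 µm at the default 180 µm / 512 px
pixel pitch) it yields a multiscale anisotropy profile.  Cohorts are
compared per scale by two-sided Wilcoxon rank-sum tests on per-image F_a,
and profiles are normalised by a control cohort's per-scale medians.

The Fourier baseline, `r_computed`, integrates the 2D spectral amplitude
into angular bins and reports the doubled-angle circular resultant
|Σ S(θ) e^{2iθ}| / Σ S(θ) ∈ [0, 1] — 0 for random, 1 for perfect
alignment.

See `docs/methods.md` for conventions (dilation, boundaries, binning),
the synthetic generator, and known limitations.

## Worked example

```python
import numpy as np
from fiberaniso import (FiberSimConfig, WaveletConfig, simulate_fiber_image,
                        multiscale_profile, r_computed)
from fiberaniso.wavelet import NAMED_SCALES_PX

aligned = simulate_fiber_image(
    FiberSimConfig(diameter_um=2, angle_range_deg=(85, 95), seed=1))
random_ = simulate_fiber_image(
    FiberSimConfig(diameter_um=2, angle_range_deg=(0, 180), seed=1))

cfg = WaveletConfig(scales_px=NAMED_SCALES_PX)   # 2.5 ... 39.4 um
for name, img in [("aligned [85,95]", aligned), ("random  [0,180]", random_)]:
    prof = multiscale_profile(img, cfg)
    fa = "  ".join(f"{v:.3f}" for v in prof.fa)
    print(f"{name}:  Fa(2.5..39.4 um) = {fa}   R = {r_computed(img):.3f}")
```

prints

```
aligned [85,95]:  Fa(2.5..39.4 um) = 1.614  1.505  1.273  0.978  0.752   R = 0.504
random  [0,180]:  Fa(2.5..39.4 um) = 0.555  0.463  0.318  0.212  0.395   R = 0.067
```

The near-vertical cohort's angle density is concentrated perpendicular to
the fibers, giving F_a ≈ 1.6 at the fiber-diameter scale and staying well
above the unaligned image across the whole ladder; the unaligned image
sits near the finite-sample floor of an isotropic field.  The Fourier
score separates the same pair (0.50 vs 0.07) but at a single implicit
scale.

A command-line interface mirrors the experiment drivers:

```
fiberaniso simulate  --out sims/  --seed 1 --n-per-cell 10
fiberaniso analyze   --images sims/ --out scores/ --scales 7,14,28,56,112
fiberaniso calibrate --out calib/ --seed 1 --n-per-group 25
fiberaniso noise-exp --out noise/ --seed 1
fiberaniso compare   --out comp/ --cohort a=dirA --cohort b=dirB --control a
```

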