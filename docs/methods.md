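# Methods

## The measurement problem

In cross-sections of a developing feather follicle, the epithelial sheet
meets the mesenchyme along a border whose shape changes across branching:
before branch formation the basal keratinocytes extend thin filopodia a few
micrometres into the mesenchyme, fringing the border; after branching the
border is smooth and gently scalloped. A 2-D proxy for the interface area is
the tortuosity of that border: its arc length λ divided by the straight-line
distance d between its endpoints. A flat border scores 1; a filopodia-fringed
border scores several-fold higher. The package measures λ/d per section and
compares a pre-branch group against a post-branch group with a two-tailed
two-sample t-test.

The pipeline has four stages: synthesize (or load) calibrated two-phase
images; segment them with a region-based active contour; extract the border
as a subpixel polyline; measure λ/d and compare groups.

## Segmentation model

The image I : Ω → R is segmented by minimizing, over a level-set function φ
and fitted intensities (c₁, c₂, f₁, f₂),

F = λ₁∫|I−c₁|²H(φ) + λ₂∫|I−c₂|²(1−H(φ))
  + η₁∫∫K_σ(x−y)|I(y)−f₁(x)|²H(φ(y)) dy dx
  + η₂∫∫K_σ(x−y)|I(y)−f₂(x)|²(1−H(φ(y))) dy dx
  + ν∫δ(φ)|∇φ|,

with H the Heaviside function regularized as H_ε(x) = ½(1+(2/π)arctan(x/ε)),
δ_ε = H_ε′, and K_σ an isotropic Gaussian. The λ-weighted terms are the
global two-phase piecewise-constant (Chan–Vese) data terms; the η-weighted
terms are kernel-local binary fits that tolerate smooth intensity
inhomogeneity (bias fields); ν penalizes contour length. Minimization
alternates the closed-form optimal updates of (c₁, c₂, f₁, f₂) with
fixed-step gradient descent φ ← φ − α·∇_φF. The descent field is derived
from F itself, so the two never disagree: the test suite checks the analytic
gradient against central finite differences of the implemented energy to
10⁻³ (it agrees to ~10⁻⁶), and checks that with η₁=η₂=0 every piece reduces
to an independently coded Chan–Vese oracle to 10⁻⁸.

### Numerical choices

- **Discretization.** All integrals are plain pixel sums; σ and ε are in
  pixel units. ∇φ and the divergence use central differences with replicate
  padding; the curvature part of the gradient is the exact transpose of
  those stencils, so the discrete gradient is exactly the gradient of the
  discrete energy.
- **Kernel convolutions are zero-padded** and f₁/f₂ are ratios of two such
  convolutions (normalized convolution). This makes the double-sum local
  energy a symmetric quadratic form over Ω×Ω, whose exact adjoint the
  gradient then is — including at image edges — and gives the correct
  wide-kernel limit f₁ → c₁. With replicate padding neither holds: the
  replicated edge values dominate the kernel mass.
- **Length density.** |∇φ| is smoothed to sqrt(|∇φ|²+e²) with e = 0.05 px in
  both the energy and its gradient. The raw |∇φ| is kinked wherever φ is
  flat, the normal field ∇φ/|∇φ| is then not Lipschitz, and a fixed-step
  descent oscillates; with the smoothed density the α = 0.05 trace is
  strictly non-increasing. The bias on the measured length is ≤ 0.1% at
  interface slopes.
- **Stopping.** The run stops when the relative energy change stays below
  `tol` (10⁻⁶) for 5 iterations, when the zero level set has not moved for
  50 consecutive iterations (checked after `min_iter` = 300), or at
  `max_iter` = 500. The contour-stationarity signal is load-bearing: the
  arctan Heaviside has heavy 1/x tails, so after the contour freezes the
  energy keeps creeping downhill at a relative 10⁻⁴ per iteration for
  thousands of iterations and a pure energy rule never fires.
- **Degeneracies.** A phase whose mean H_ε mass falls below 10⁻⁶ raises a
  degenerate-phase error naming the phase. Local-fit denominators below
  10⁻⁸ of the kernel mass fall back to the global mean (logged). Non-finite
  energy aborts with a divergence error suggesting a smaller α.
- **Initialization.** Default is a ±2 binary step at the Otsu threshold;
  signed distance to a circle/rectangle and user masks are also supported.
- **Projected descent (`phi_clip`)** optionally clamps |φ| after each step.
  Off by default (the verbatim fixed-step iteration); used when a large
  contour displacement must be covered, because unbounded far-field growth
  of |φ| makes δ_ε(φ) vanish and freezes the contour.

### Default coefficients

λ₁ = λ₂ = 0.2, η₁ = η₂ = 1.0 (local terms carry the model, global terms
stabilize it, the standard hybrid weighting), ν = 1.0 (suppresses
noise-induced speckle without measurably eroding 10-px-wide protrusions),
σ = 3 px, ε = 1 px (the init step is ±2, so ε = 1 yields a usable transition
band), α = 0.1. All are exposed in `ACMParams` and on the CLI.

## Border extraction and tortuosity

The border is the zero level set, extracted by marching squares with linear
interpolation — on φ when available, else on the signed-distance transform
of the mask. The field is first smoothed with a 0.8 px Gaussian: near-binary
fields otherwise produce staircase contours whose λ is biased high by 5–8%
on oblique borders; 0.8 px removes the staircase while keeping the
corner-rounding loss proportional to pixel size, so the measurement error
shrinks monotonically under grid refinement (verified at 0.4 → 0.2 → 0.1
μm/px). Among the contour pieces clipped to the ROI, the longest open piece
whose endpoints touch the two designated ROI sides (default left/right) is
the border; d is the distance between its two endpoints — the simplest
reading of "linear distance", stated here so users can align other
protocols. One ratio is measured per image; group statistics are computed
over images, matching a ten-sections-per-group design, with a pooled
two-tailed t-test (Welch optional).

## Synthetic phantoms

No real micrographs ship with the package, so a generator produces two-phase
images with closed-form border geometry:

- **Pre-branch**: straight base with triangular (or rounded-finger)
  filopodia. Defaults are anchored to the published morphometry — 3–5
  filopodia per 10 μm of border (reading one basal-cell width as ~10 μm, an
  assumption), lengths uniform on [2, 10] μm. Bases are placed on a jittered
  grid (one per cell, confined so bases stay ≥ one base-width apart), which
  is deterministic and cannot collide; densities above 1/base-width raise an
  error naming the feasible maximum.
- **Post-branch**: semicircular scallops (radius ~1.2–2 μm) on a straight
  base.
- λ is accumulated in closed form (triangle sides, arc-chord sums), never
  re-measured off the raster, and equals an independent brute-force polyline
  sum to 10⁻⁹.
- Rasterization assigns each pixel the intensity of the phase containing its
  center (point-in-polygon), then adds an optional bias field (linear ramp
  or quadratic bowl) and seeded Gaussian noise, clipped to [0, 1]. Identical
  (spec, seed) pairs are bit-identical.

With these anchored defaults the pre-branch ratios land at ≈ 4–7 — inside
the low end of the published pre-branch range (5–16) — and the post-branch
scallops at ≈ 1.3–1.5, below the published post-branch mean. A semicircular
scallop border is mathematically capped at λ/d ≤ π/2, so the absolute
published post-branch values (4–8, mean 6) are not reachable with this
geometry; they would require deep branch lobes that the generator
deliberately does not model. The synthetic study therefore reproduces the
*direction and significance* of the contrast (pre ≫ post, p < 0.01 over ten
sections per group), not the published absolute means — those were measured
on real micrographs that are not publicly available.

What the phantoms do not emulate: real filopodia are ~0.2 μm wide (below
light-microscope rasterization at these settings; the phantom uses 2 μm
stylized protrusions), there is no multi-layer epithelium, no nuclei or
texture, and noise is white Gaussian rather than structured stain
variation. Passing tests therefore demonstrate correctness of the
*measurement machinery*, not performance on histology.

### Calibration and resolution limits

Default calibration is 0.1 μm/px. A raster fundamentally cannot carry border
slivers narrower than a pixel: for wedge-shaped protrusions the loss is
≈ 1.6·px/base-width of λ. The known-ratio phantoms (`spec_for_ratio`) use
5 μm tooth bases so that at 0.2 μm/px the full pipeline recovers λ/d ∈
[2, 16] within 10%, improving to ~3% at 0.1 μm/px — verified including the
monotone improvement, ratio by ratio.

## The bias-field experiment

`experiments.bias_challenge` quantifies what the local terms buy. A narrow
strip phantom (51.2 × 6.4 μm — the shape of a practical analysis ROI)
carries a linear intensity ramp (amplitude 0.7, chosen by sweeping) larger
than the phase contrast (0.4). Both models start from the same imperfect
initialization — the true mask with its border displaced 8 px — and run a
projected descent. The full model snaps back to the true border (Dice
≈ 0.99) because its kernel-local fits see the real intensity step; the
global-only model (η = 0) drifts to its own optimum, the iso-intensity
split, losing the border (Dice ≈ 0.85). The experiment is deliberately a
*border-tracking stability* test: from a wholesale mis-thresholded
initialization no model of this family recovers, because the local fits
adapt to whatever labels they are given — a known limitation, shared by the
original local-binary-fitting formulation, and documented here rather than
hidden.

## Known limitations

- Two phases, 2-D only; no multiphase or 3-D support.
- Fixed step length; no line search. Convergence latency scales with the
  init amplitude divided by α.
- The λ/d of sub-pixel features is irrecoverably underestimated (coastline
  effect in reverse); choose the calibration so the narrowest feature spans
  ≥ 3 px, which the generator warns about.
- The t-test treats sections as independent; no nesting within follicles.
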