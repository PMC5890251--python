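# emborder

Quantifying the epithelial–mesenchymal border in feather-follicle sections:
level-set segmentation, subpixel border extraction, and the λ/d tortuosity
statistic.

## The problem

During feather branching, the basal keratinocytes of the follicle epithelium
retract the filopodia that fringe the epithelial–mesenchymal (E-M) border,
and the border smooths out. How much interface area does that cost? In 2-D
sections the natural proxy is the border's tortuosity: its arc length λ
divided by the straight-line distance d between its endpoints (λ/d = 1 for a
flat border; the measured value grows with the measurement scale for
fractal-like borders — the coastline effect). This package is for
researchers who want that measurement reproducible end to end: segment the
two-phase image, trace the border at subpixel precision, compute λ/d per
section, and compare a pre-branch group to a post-branch group with a
two-tailed t-test.

## The model

Segmentation minimizes a hybrid local–global region energy over a level-set
function φ whose zero level set is the border:

    F(φ, c1, c2, f1, f2) =
        λ1 ∫ |I − c1|² H(φ) dx + λ2 ∫ |I − c2|² (1 − H(φ)) dx
      + η1 ∫∫ K_σ(x−y) |I(y) − f1(x)|² H(φ(y)) dy dx
      + η2 ∫∫ K_σ(x−y) |I(y) − f2(x)|² (1 − H(φ(y))) dy dx
      + ν ∫ δ(φ) |∇φ| dx

with H_ε(x) = ½(1 + (2/π) arctan(x/ε)), δ_ε(x) = (1/π) ε/(ε²+x²), and K_σ a
Gaussian. The c's are global inside/outside means (the Chan–Vese terms); the
f's are kernel-local fits that tolerate smooth intensity inhomogeneity.
Minimization alternates the closed-form coefficient updates with gradient
descent φ ← φ − α ∇_φF, where the descent field is the exact gradient of the
implemented discrete energy (finite-difference-checked in the test suite).

Because no micrographs are publicly available for this system, the package
includes a phantom generator with closed-form ground truth — pre-branch
borders fringed with 2–10 μm filopodia at 3–5 per 10 μm, post-branch borders
smoothly scalloped — so every stage is testable offline. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
from emborder.pipeline import RunConfig, run_full

manifest = run_full(RunConfig(mode="full", out_dir="demo", seed=1))
c = manifest["comparison"]
print(f"pre:  mean λ/d = {c['mean_pre']:.2f}  "
      f"(range {c['range_pre'][0]:.2f}-{c['range_pre'][1]:.2f})")
print(f"post: mean λ/d = {c['mean_post']:.2f}  "
      f"(range {c['range_post'][0]:.2f}-{c['range_post'][1]:.2f})")
print(f"decrease {c['percent_decrease']:.1f}%,  t = {c['t_stat']:.1f},  "
      f"p = {c['p_value']:.2g}")
```

This simulates ten phantoms per group, segments each, measures λ/d, and
prints:

    pre:  mean λ/d = 4.55  (range 3.75-5.30)
    post: mean λ/d = 1.38  (range 1.34-1.41)
    decrease 69.8%,  t = 23.0,  p = 8.6e-15

The filopodia-fringed group carries several-fold more border length per unit
span than the smooth group, and the contrast is decisive at n = 10 per
group. `demo/` then contains the images, masks, per-section metrics
(`metrics.csv`, with each measured ratio within 10% of its analytic ground
truth), the comparison JSON and a run manifest.

The same runs from a shell:

    emborder full --out-dir demo --seed 1
    emborder simulate --n-pre 10 --n-post 10 --out-dir phantoms
    emborder measure --input-dir masks/ --pixel-size-um 0.1 --out-dir out

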