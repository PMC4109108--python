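# Methods

## Model

The segmentation functional combines four data terms and two geometric
regularisers over a level-set function φ on a unit grid (images ingested
as floats on [0, 255], φ > 0 inside the contour):

```
F(φ) = (1−w) E_G + w E_L + k [ (1−w) J_G + w J_L ] + ν L(φ) + μ R(φ)
```

with soft memberships M₁ = H_ε(φ), M₂ = 1 − M₁.  The fitting terms
penalise squared deviation of intensity from per-side means — spatially
varying windowed means fᵢ(x) = K_σ∗(Mᵢ I)/K_σ∗Mᵢ for the local term, plain
scalar means C_i for the global term.  The discriminant terms are an
inverse Fisher criterion (V₁+V₂)/(C₁−C₂)², where Vᵢ is the membership-
weighted variance about the side mean with the Bessel-style 1/(Nᵢ−1)
normalisation and Nᵢ the effective (soft) pixel count.  L is the co-area
contour length Σ δ_ε(φ)|∇φ|; R = ½Σ(|∇φ|−1)² penalises deviation from a
signed-distance profile so the evolution never reinitialises φ.

Minimisation alternates two steps each iteration: (1) refit all region
statistics for the current φ; (2) one forward-Euler step of the gradient
flow with the statistics frozen.  The flow force is

```
∂φ/∂t = −δ_ε(φ) [ (1−w)(λ₁(I−C₁ᴳ)² − λ₂(I−C₂ᴳ)²)
                  + w(λ₃(I−f₁)² − λ₄(I−f₂)²) ]
        − k δ_ε(φ) [ (1−w) B_G + w B_L ]
        + ν δ_ε(φ) div(∇φ/|∇φ|)
        + μ (∇²φ − div(∇φ/|∇φ|))
```

where B is the bracket `[(I−C₁)²/(N₁−1) − (I−C₂)²/(N₂−1)] / (C₁−C₂)²` at
the matching window scale.

## Smoothed step and impulse

H_ε is the piecewise arctan step: ½(1 + (2/π)arctan(x/ε)) on |x| ≤ ε,
exactly 1 above ε and exactly 0 below −ε.  As defined it has a jump of
½ − arctan(1)/π ≈ 0.25 at ±ε; this is kept deliberately, and the companion
impulse δ_ε(x) = ε/(π(ε²+x²)) is taken from its own closed form — it is
the exact derivative of the arctan branch, not of the truncated step.  The
impulse has full support, so data forces act on all level curves and new
contours can appear away from the current zero set; this is what gives
the combined model its weak dependence on initialisation.  Default
ε = 1.5.

## Window kernels

Two families, both normalised to unit sum on a square support and
therefore exactly separable (convolution runs as two 1-D passes; a test
pins the fast path to the generic 2-D stencil at 1e-10):

* uniform: constant 1/(2σ+1)² on the (2σ+1)×(2σ+1) square;
* gaussian (default): exp(−r²/2σ²) truncated at ⌈4σ⌉, renormalised.

Image-valued convolutions replicate edge values, which avoids the
artificial dark border that zero padding would feed into the local means.
The window-mass integrals behind the discriminant means/counts integrate
over the image domain only, so the mass tapers below 1 within one support
width of the border; the double-sum test oracles use the same
conventions, evaluated by explicit loops.

The "global" window is computed as the exact whole-image limit (plain
soft means and counts), not as a very wide convolution: mathematically
identical in the σ → ∞ limit and O(N) instead of O(Nσ²).

## Degenerate cases

* **Local mean with empty window** (K∗Mᵢ < 1e-8): no pixel of side *i*
  lies within window reach, so fᵢ is undefined; it is set to the windowed
  image average K∗I.  The local fitting difference then vanishes exactly
  where one-sided local evidence is absent and the (1−w)-weighted global
  terms steer the contour alone.  The alternative of substituting the
  scalar regional mean Cᵢ was tried and rejected: far from the contour
  only one side is ever degenerate, so that substitution turns the local
  term into a one-sided repulsion that prevents distant objects from ever
  being captured and can invert the segmentation polarity outright.
* **Coincident means** ((C₁−C₂)² < 1e-6·range²): the discriminant energy
  and force contribute zero for that iteration.
* **Near-collapsed counts**: Nᵢ ≤ 1+1e-6 substitutes denominator 1;
  Nᵢ < 1e-3 aborts the run as a collapsed contour (reported as
  `converged=False` with a diagnostic, not an exception).
* **Flat gradients**: |∇φ| is floored at 1e-10 inside the curvature
  quotient.

## Discretisation and stability

First/second derivatives are the standard central differences on a unit
grid with replicate boundaries; the mixed derivative is the four-corner
stencil /4 (exact on bilinear fields).  Curvature uses the rational form
(φxx φy² − 2 φxy φx φy + φyy φx²)/|∇φ|³.  On near-flat plateaus this
quotient is ill-conditioned (the normal direction is undefined) and can
reach ~1e7, which destroys an explicit scheme; inside the flow it is
therefore clamped to |κ| ≤ 2 — the largest curvature a unit grid can
represent — while diagnostics keep the raw value.

The distance-regularisation force is applied ungated by default
(`dr_dirac=False`): μ(∇²φ − div(∇φ/|∇φ|)) is exactly the descent flow of
R(φ) and diffuses φ everywhere, which erases isolated wrong-sign pixels
and keeps the far field mobile.  The gated variant μδ_ε(φ)(·) remains
available (`dr_dirac=True`); it confines the regulariser to a band around
the contour, so pixels pushed to large |φ| by the strong data forces
freeze permanently — measurably worse on every protocol here.

Time stepping is forward Euler with Δt = 0.1 and μ = 2 by default
(μΔt = 0.2; the CFL-type bound μΔt < 0.25 is enforced when parameters are
constructed).  Evolution stops when fewer than `stop_pixels` = 10 pixels
change sign per iteration for `stop_window` = 5 consecutive iterations
(the window length is a free choice and exposed as a parameter), or at
`max_iter` = 1000.  On noisy images the contour keeps exchanging a few
dozen boundary pixels indefinitely (explicit-scheme overshoot against
steep data forces), so runs typically use the full budget; the mask
itself is stable.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| w | 0.98 | local-vs-global blend (local dominant) |
| k | 0.3 | discriminant weight |
| ν | 0.002·255² | length penalty (scale set by the [0,255] range) |
| μ | 2.0 | distance regularisation (μΔt = 0.2 < 0.25) |
| λ₁..λ₄ | 1 | per-side fitting weights |
| ε | 1.5 | step/impulse smoothing width |
| Δt | 0.1 | time step |
| σ_L | 3 (4 for the noise sweep) | local window scale, px |
| σ_G | ∞ (exact global) | global window scale |
| c₀ | 2 | binary initial level-set amplitude |

The presets differ only in their defining overrides (`cv`: w=0, k=0;
`rsf`: w=1, k=0; `lgif`: w=0.98, k=0 — an internal ablation of the
combined model without the discriminant; `rsdf`: the full functional), so
score differences between arms are attributable to the energy.

A note on the discriminant terms: with the 1/(Nᵢ−1) normalisation their
force is ~1e-6 of the fitting force on a 128² image — numerically inert
at any realistic image size (k would need to be of order N to matter).
They are retained at k = 0.3 for fidelity to the functional; the
comparative behaviour of the combined arm is carried by the local+global
fitting blend.

## Synthetic phantoms

Phantoms are piecewise-constant fields on [0, 1] (background plus discs,
rectangles, and 5-pointed stars at stated levels), optionally modulated
by a smooth multiplicative bias field (linear ramp, centred quadratic, or
Gaussian blob; amplitude a modulates by 1 + a(u−½)) and corrupted by
additive zero-mean Gaussian noise at the conventional variances 0.01 /
0.05 / 0.1 *on the unit scale*, then clipped to [0, 1] and mapped to
[0, 255].  Ground truth is the union of object supports, exact by
construction; everything is deterministic given the seed.  Named
families:

* `two-level-disc` / `fig2-style`: one disc (0.6) on background (0.2),
  optional noise/bias — the clean-recovery and noise-sweep material;
* `three-objects`: faint disc (0.35), rectangle (0.65) and star (0.95,
  with extra noise whose variance ramps 0.02 → 0.1 across its bounding
  box) on background 0.15.  The levels are chosen so one global two-phase
  threshold cannot keep the faint disc, while local statistics can; the
  background itself is clean, matching the character of the multi-object
  test material this family emulates;
* `two-discs`: two disjoint equal discs (topology-change case);
* `brainlike`: a thresholded smoothed random field (blobby two-tissue
  foreground) under a 40% quadratic bias and variance-0.01 noise — a
  stand-in with brain-like geometry, not an MRI simulation.

What the phantoms do not emulate: partial-volume mixing at tissue
boundaries, spatially correlated (Rician) MR noise, texture, and real
anatomy.  Passing the protocols here shows the energies and the solver
behave as designed under piecewise-constant truth with smooth bias and
i.i.d. Gaussian noise; it does not certify accuracy on clinical data.

## Evaluation protocols

All protocols run at 128×128 with fixed seeds and shared engine controls.

* **Clean recovery**: every arm reaches Jaccard ≥ 0.98 on the clean disc
  from a rectangle straddling the disc boundary (margin = side/4) — the
  canonical init that gives even the purely local arm statistics on both
  sides.
* **Noise sweep**: fixed init, fixed per-level seed, σ = 4 windows;
  the combined arm degrades monotonically with variance and is scored
  against the local arm at variance 0.1.
* **Initialisation sweep**: three nested enclosing rectangles on the
  three-object phantom, all within window reach of every object (the
  model's documented applicability regime); the combined arm's final
  masks must mutually overlap (min pairwise Jaccard) and its score spread
  is compared with the local arm's.
* **Topology**: one rectangle init over two disjoint discs must end as a
  two-component mask.

## Known limitations

* Two-phase only; single-channel only.
* Objects entirely beyond window reach of the initial contour are found
  only through the weak (1−w) global term, and only when their intensity
  is on the global foreground side: a faint object outside both the
  initial contour and window reach stays unsegmented.
* The explicit scheme trades speed for simplicity; with steep data forces
  the contour jitters by a few dozen boundary pixels per iteration
  instead of settling, so the pixel-count stopping rule often does not
  fire before `max_iter`.
* Heavy noise (variance 0.1 with clipping) leaves residual speckled
  misclassification near the contour for all local arms; the global arm
  is the most noise-robust, as expected for threshold-like behaviour.
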