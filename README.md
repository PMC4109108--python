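# rsdfseg

Two-phase level-set segmentation of single-channel images by a
**region-scalable discriminant-and-fitting (RSDF)** geometric active
contour.  The package targets images that defeat purely global region
models — medical images with smooth intensity inhomogeneity (bias fields),
weak boundaries, several objects at different gray levels, and noise — and
provides, on one shared evolution engine, the classical comparison arms as
parameter presets: the piecewise-constant global model (`cv`), the
region-scalable fitting model (`rsf`), a local+global fitting blend
(`lgif`), and the full combined model (`rsdf`).

## The model

The contour is the zero set of a level-set function φ (φ > 0 inside) on a
unit grid, evolved to minimise

```
F(φ) = (1−w) E_G(φ) + w E_L(φ) + k [ (1−w) J_G(φ) + w J_L(φ) ]
       + ν L(φ) + μ R(φ)
```

* **Fitting energies.**  E_L is the region-scalable fitting energy
  `Σᵢ λᵢ ∬ K_σ(x−y) (I(y) − fᵢ(x))² Mᵢ(y) dy dx` with window K_σ and soft
  memberships M₁ = H_ε(φ), M₂ = 1 − M₁; its minimising means are the
  windowed ratios fᵢ = K_σ∗(Mᵢ I) / K_σ∗Mᵢ.  E_G is the same construction
  in the whole-image limit, i.e. the Chan–Vese data term with scalar means
  C_i.
* **Discriminant energies.**  J = (V₁ + V₂)/(C₁ − C₂)², an inverse Fisher
  criterion: within-region scatter over squared between-region mean
  separation, evaluated with local- and global-window statistics.
* **Regularisers.**  L(φ) = ∫ δ_ε(φ)|∇φ| penalises contour length;
  R(φ) = ½∫(|∇φ| − 1)² keeps φ near a signed-distance profile, so no
  reinitialisation is ever performed.

`w ∈ [0,1]` blends local against global information, `k ≥ 0` weighs the
discriminant terms.  Minimisation alternates refitting the region
statistics with an explicit forward-Euler step of the gradient flow
(central-difference stencils, CFL bound μ·Δt < 0.25 enforced at
construction).  H_ε/δ_ε are the smoothed arctan step and the Cauchy
impulse ε/(π(ε²+x²)); the full-support impulse lets new contours appear
away from the current zero set, which is what makes the combined model
robust to initialisation.  Evolution starts from a binary ±2 level set and
stops when fewer than `stop_pixels` grid points change sign per iteration
for `stop_window` consecutive iterations.

Accuracy is scored by the Jaccard index J(S₁,S₂) = |S₁∩S₂| / |S₁∪S₂|
against ground-truth masks.

## Worked example

Segment a built-in synthetic phantom — three objects at distinct gray
levels (a faint disc, a mid-gray rectangle, and a bright star corrupted by
strongly nonuniform noise) on a dark background — with the full model and
with the global-only arm:

```python
import rsdfseg as r

image, truth = r.render_phantom(r.three_objects(seed=1))
init = r.InitialContourSpec("rectangle", (20, 20, 108, 108))

for preset in ("rsdf", "cv"):
    res = r.run(image, r.get_preset(preset), init)
    print(preset, round(r.jaccard(res.mask, truth), 3))
```

```
rsdf 0.977
cv 0.687
```

The combined model recovers all three objects (Jaccard 0.977).  The global
arm scores 0.687 because a single intensity threshold cannot keep the
faint disc without flooding the background: it recovers the rectangle and
star but drops the disc entirely.

The same thing from the shell:

```sh
rsdfseg segment --phantom three-objects --preset rsdf \
    --init rect:20,20,108,108 --out out/
```

which writes `mask.png`, a per-iteration energy log `trace.csv`
(`iter,delta_pixels,E_G,E_L,J_G,J_L,L,R,F`), and `result.json` with the
full parameter echo and the Jaccard score.  `rsdfseg phantom --preset
fig2-style --variance 0.05 --seed 7 --out data/` renders phantoms to disk
(16-bit PNG + truth mask + JSON sidecar).

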