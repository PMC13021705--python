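# se2cc — δ-connected components on the roto-translation group SE(2)

Curvilinear structures that cross — blood vessels in a retinal image, fibers,
line drawings — collapse into a single blob under ordinary planar
connected-component labeling: at a crossing, the pixels touch.  `se2cc`
separates them by lifting the image to the space of positions *and*
orientations, the Lie group SE(2) of roto-translations, where a crossing
splits into well-separated orientation layers.  It is written for people
analyzing multi-orientation image data (vessel trees in particular) and for
people who want a tested reference implementation of morphological
PDE-based grouping on SE(2).

## The method in brief

An image f is lifted to an orientation score
(W_φf)(x, θ) = ∫ φ(R_θ⁻¹(y − x)) f(y) dy by correlation with rotated *cake
wavelets* φ, whose Fourier wedges tile the frequency plane.  Distances on
SE(2) use a left-invariant metric with weights (w₁, w₂, w₃) for forward,
lateral and angular motion, approximated by the logarithmic norm
d(g, h) ≈ ‖Log(g⁻¹h)‖_w — cheap, left-invariant, and exact for small
separations.

For a threshold δ > 0, two points of a binarized lifted set I are
**δ-connected** if a chain inside I joins them with hops ≤ δ.  Components
are computed by iterating a morphological (Hamilton-Jacobi-Bellman)
dilation and an intersection,

    U_n = 1_I · φ_δ¹(U_{n−1}),

which provably reaches each component in finitely many steps.  The package
also provides: persistence diagrams and K(δ) sweeps to choose δ (deaths are
minimum-spanning-tree edge weights for point clouds); affinity matrices
a_ij ∈ (0, 1] that score proximity-and-alignment of components via p-means
of dilated component masses (with analytic bounds under a constant data
term); and an end-to-end synthetic vessel pipeline
(lift → vesselness → cost → Otsu → components → grouping) with
split/merge scores against ground truth.

## Worked example

```python
import numpy as np
import se2cc as s

# two crossing lines; ground truth carries each line's pixels and angle
img, gt = s.generate_fixture("crossing_lines", size=128, seed=0)
cfg = s.PipelineConfig(No=16, delta=1.5)          # 16 orientations
res = s.run_pipeline(img, cfg, trees=gt.lifted(16))
print(f"SE(2) components: K = {res.labels.K}")
print(f"E_split = {res.metrics[0]:.1f}, E_merge = {res.metrics[1]:.1f}")
print(f"planar 8-connectivity baseline: K = {res.baseline_2d.max()}")

# choosing delta on a point cloud: 20 points on a circle + 2 outliers
pts, _ = s.generate_fixture("circle20plus2", seed=0)
w = s.MetricWeights(1, 2, 2)
sw = s.sweep(pts, np.linspace(0.5, 8.0, 40), w)
(lo, hi), K = s.suggest_delta(sw)
print(f"suggested delta in [{lo:.2f}, {hi:.2f}] with K = {K}")
```

prints

```
SE(2) components: K = 2
E_split = 1.0, E_merge = 1.0
planar 8-connectivity baseline: K = 1
suggested delta in [1.65, 8.00] with K = 3
```

The two crossing lines come out as exactly two components with a perfect
split/merge score — the planar baseline sees one blob — and the circle
cloud's most persistent regime keeps the circle as one component and each
outlier as its own (K = 3).

The same operations are available from the shell:

```bash
se2cc synth circle20plus2 -o cloud.csv
se2cc persistence cloud.csv --weights 1,2,2
se2cc pipeline crossing_lines --out-dir run/ --size 128
```

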