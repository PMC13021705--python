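# Methods

## The model

`se2cc` identifies connected components of curvilinear structures after
lifting them to the roto-translation group SE(2), the set of pairs
g = (x, R_θ) of a planar position and an orientation with product
g₁g₂ = (x₁ + R₁x₂, R₁R₂).  A 2D image f is lifted to an *orientation score*

    (W_φ f)(x, θ) = ∫ φ(R_θ⁻¹(y − x)) f(y) dy,

a correlation with rotated copies of an anisotropic wavelet φ.  Crossing
lines, which form one blob in the plane, occupy different orientation layers
of the score and separate.

Distances on SE(2) use a left-invariant Riemannian metric with diagonal
weights (w₁, w₂, w₃) pricing forward, lateral and angular motion in the
moving frame, approximated by the logarithmic norm

    d(g, h) ≈ ‖Log(g⁻¹h)‖_w = √(w₁c₁² + w₂c₂² + w₃c₃²),

with (c₁, c₂, c₃) the Lie-algebra coordinates of the group logarithm,
c₃ = θ ∈ (−π, π] and (c₁, c₂) = (θ/2)(x cot(θ/2) + y, −x + y cot(θ/2)).
The approximation is exact for pure translations and pure rotations, tight
for nearby elements, cheap to evaluate, left-invariant by construction, and
carries the 2³ reflectional sign-flip symmetries of the algebra
coordinates.  It is *not* a true metric globally: the triangle inequality
can fail for widely separated elements (the test suite checks the violation
rate stays below 5% for norms ≤ 2).  All distances in the package are this
approximation; no fast-marching solver is used.

## δ-connected components

Two points of a compact set I ⊂ SE(2) are δ-connected when a finite chain
inside I links them with hops of distance ≤ δ.  The equivalence classes
(δ-connected components) are computed by the morphological iteration

    U_n = 1_I · φ_δ¹(U_{n−1}),    U_0 = 1_{seed},

where φ_t^α is the Hamilton-Jacobi-Bellman dilation flow, a max-plus
convolution with the kernel k_t^α(g) = (t/β)(d(g,e)/t)^β, 1/α + 1/β = 1.
At α = 1 the kernel is the flat 0/∞ indicator of the closed ball of radius
t, dilating an indicator function produces exactly the t-thickened set, and
thickenings compose additively — which is why the component iteration fixes
α = 1 and t = δ.  The iteration grows the support by one δ-hop per step and
stops at the first fixed point; all components are extracted by reseeding at
the first unlabeled node in a fixed (k, j, i) scan order, which makes the
labeling deterministic.

Discretely, the ball is a per-orientation-layer stencil of integer node
offsets whose log-norm (with the spatial offset rotated into the layer's
frame) does not exceed the radius — exact at grid nodes, no interpolation.
Dilations execute as per-layer 2D (grey/binary) dilations grouped by angular
offset; spatial offsets leaving the domain are dropped, the orientation axis
wraps.  For [0, 1]-valued fields the stencil is truncated where the kernel
reaches 1 — exactly the radius ε(t, α) = t(β/t)^{1/β} — which provably never
changes the result, since the identity offset already contributes f(g) ≥ 0.

Ball membership uses the closed inequality d ≤ radius throughout (thickened
sets and δ-hops are closed; an exact-δ chain is connected).

### Iteration budget

The number of growth steps for one component equals the seed's hop
eccentricity in the ≤δ graph.  A greedy farthest-first cover of the
component by closed δ-balls upper-bounds the covering number n_δ; the
eccentricity is bounded by about twice that (one step to reach each new
cover ball, one to absorb it).  A frequently quoted tighter budget of
n_δ + 1 steps per component does not hold for chain-shaped sets: five
collinear points spaced 0.9δ have n_δ = 2 (exhaustively verified) but need
4 steps from an end seed.  The diagnostics report both the iteration counts
and the greedy bounds.

### Continuum vs. grid

The identity "thickening twice by δ equals thickening once by 2δ" is exact
in the continuum and exact on the grid whenever two δ-hops have grid-node
midpoints.  Mixed spatial-angular offsets generally lack midpoints (the
node one pixel and one layer away may lie inside the 2δ ball yet be
unreachable in two grid hops), so the tests assert exact equality in
grid-resolved configurations (metrics confining the ball to the spatial
plane or to the orientation axis) and an inclusion elsewhere.

## Choosing δ: persistence

On finite point sets, δ-connectivity is single-linkage clustering at
threshold δ: component deaths coincide with minimum-spanning-tree edge
weights, and the elder rule yields classical (birth, death) pairs with all
births at 0.  The component count K(δ) is non-increasing; `suggest_delta`
returns the longest plateau with 1 < K < K(δ_min), tie-broken toward
smaller δ (persistent yet as distinctive as possible).  The sweep path
re-runs the component algorithm per δ; the MST path is an independent exact
oracle, and the two are cross-checked (K(δ) = 1 + #{deaths > δ}).

## Affinities

Components are grouped by proximity-and-alignment scores a_ij ∈ (0, 1]:
component i's data-weighted, sup-normalized mass W_i⁰ = D·1_{[g_i]}/sup D is
dilated once with an α > 1 kernel for a time above the diameter threshold
r^α β^{1−α} (so the dilated mass is positive on all of I; the implementation
uses 1.01× the threshold), and a_ij is the larger of the two directed
p-means of the dilated mass over the other component.  With constant data
the diagonal is exactly 1 and off-diagonals lie strictly between
1 − (t/β)(r/t)^β and 1 − (t/β)(δ/t)^β; both facts are asserted.  Because the
affinity dilation time spans the whole set, it is evaluated directly over
the support of W_i⁰ (exact, no truncation) instead of through a stencil.
Thresholding a_ij > T and taking graph components merges the labels; one
global t is used for all pairs.

## Orientation scores in practice

Cake wavelets are built in the Fourier domain: angular wedges whose
underlying B-spline profiles (order 3 by default) tile the circle exactly;
the wedge amplitude is the square root of the profile so that the *squared*
transfer magnitudes of the stack sum to 1, times a flat generalized-Gaussian
low-pass exp(−(ρ/0.9ρ_Nyq)^32) that is ≈1 on the working annulus
(0.1–0.8 of the Nyquist rate, within 10%) and vanishes at the Nyquist rate.
The DC bin is shared equally over orientations; the spatial filter is √2
times the real part of the inverse transform.  Default filter size is 49
pixels — the sharp radial roll-off needs that much spatial support, and a
size check errors below it.  Lifting evaluates the same analytic transfer on
the image-sized frequency grid (periodic boundaries), which is equivalent to
correlating with the untruncated filters.

Taking the real part makes layer k identical to layer k + N_o/2: an
unoriented structure appears at θ and θ + π.  Components of lifted sets
therefore come in exact antipodal copies; the pipeline's
`fold_antipodal_labels` stage merges each component with its θ+π-rolled
copy so one 2D structure receives one label.  Projection back to 2D takes
the per-pixel maximum label over orientations.

## The synthetic pipeline

Stages: lift (N_o = 32 orientations by default; tests use 16 for speed) →
vesselness → cost C = 1/(1 + λV^p) (λ = 100, p = 3) → Otsu binarization
(vessels have low cost; 256-bin histogram) → optional per-layer thinning
with anisotropic re-dilation (weights (0.2, 1.5, 50), α = 1.3, t = 1, i.e. a
forward-elongated ε(t, α)-thickening of the centerlines) → δ-components
(δ = 1.5, weights (0.1, 1, 4); a (w̃₁, w̃₂, w̃₃)-times-k parameterization
with k = (13/3)^{6/13} is also supported) → antipodal folding and a
small-component filter (≥ 20 nodes) → optional affinity grouping.

The vesselness here is a deliberately simple stand-in for a full
crossing-preserving vessel filter: per layer, the rectified second
derivative of the Gaussian-smoothed score *energy* across the layer's own
direction, minus the rectified tangential one, maximized over scales
s ∈ {1.5, 2, 2.5, 3} with s² normalization.  Squaring the magnitude and
penalizing tangential curvature suppress the responses a junction produces
at spurious diagonal orientations, which would otherwise chain crossing
structures together.  It is pluggable; its limits show up at junctions of
curved and straight structures, where separation needs slightly different
parameters (δ = 1, w = (0.2, 1, 4) for the ovals scene — image-specific
metric parameters are expected for this method).

Thinning defaults to off for the synthetic scenes, whose strokes are drawn
at near-centerline width already (skeletonizing 2-px lines fragments them);
the stage exists for variable-width vessels.

### What the generator emulates — and what it does not

`generate_fixture` produces: two crossing straight lines (near-perpendicular,
±7.5° jitter, the regime where orientation separation is well-posed at 16
orientations), an ellipse ring plus a line, smooth curves with gaps of
configurable length, a 7-point planar scatter in three groups, and 20
points on a circle with tangential orientations plus two outliers.  All are
deterministic given a seed, with pixel-precise (or index-precise) ground
truth; line fixtures also carry per-structure angles so that ground truth
can be lifted to disjoint orientation-resolved supports.  The fixtures have
clean contrast, no background texture, no width variation and no
illumination gradients; passing tests therefore demonstrate the geometry of
the method (crossing separation, gap bridging, grouping), not robustness to
photometric nuisances of real retinal imagery.

### Split/merge scores

E_split averages over ground-truth structures the number of components
touching each; E_merge averages over components the number of structures
each touches; a perfect labeling scores (1, 1).  "Touching" is the
indicator of nonempty intersection (with lifted ground truth intersected in
SE(2), so two structures sharing crossing pixels do not spuriously count).
A cardinality-weighted reading would make both numerators identical and the
two scores indistinguishable.

## Numerical choices

- Angles are stored in [0, 2π); angular offsets in distances wrap to
  (−π, π].  θ = π uses the same closed-form logarithm (cot(π/2) = 0).
- Distance comparisons use plain `<=` with no tolerance; stencil offsets
  and point-pair distances are computed by the same code path, so the two
  agree bit-for-bit away from measure-zero ties.
- The stopping test compares support cardinalities (supports grow
  monotonically, so equal counts imply equal sets; an assertion checks the
  full equality).
- Problem sizes in the test suite: component oracle checks run 25 random
  clouds of up to 200 points on 24×24×8 grids; the crossing-lines contrast
  runs one 128×128×16 lift; both finish in seconds on one CPU.

## Known limitations

- The log-norm distance is local; large δ relative to the curvature scale
  degrades both the metric quality and the ball stencils.
- The vesselness substitute is not the crossing-preserving filter of the
  vessel-analysis literature; junctions of curved structures may need
  per-image metric parameters.
- Affinity evaluation is O(|support| × grid) per component; fine for the
  scales here, but large grids with many components would need the
  truncated-stencil path or subsampling.
- Persistence for grid sets re-runs the component algorithm per δ (no
  incremental union-find across the sweep).
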