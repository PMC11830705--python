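# Methods

## Seed-grid division

A blanket tray has no physical pots, so counting units are defined from the
transplanter's geometry: one seed grid = one unit seedling-taking area,
i.e. horizontal cutting step × longitudinal cutting step.  The 18-row
seeder fixes 18 horizontal strips; the horizontal cut is the inner tray
width over 18 (280 / 18 = 15.56 mm).  The longitudinal step is a transplanter
gear, an integer from 8 to 18 mm (11 gears), and admits
`cols = ⌊inner_length / gear⌋` cuts along the 580 mm axis.

Expected seeds per tray come from mass: `N = round(density / TGW × 1000)`
with TGW the thousand-grain weight in grams (24.75 g for the reference
hybrid variety).  Rounding is half-away-from-zero, matching the printed
division table (2020 / 2424 / 2828 for 50 / 60 / 70 g).  The gear is chosen
so the mean `N / (18·cols)` lies in [2.7, 2.9] — at field germination rates
of 75–85 % this delivers the 2–2.5 seedlings per hill that precise
transplanting targets.  With floor-division for columns exactly one gear is
feasible at each of the three standard densities (14, 12, 10 mm), which is
why floor, not round, is used; among multiple feasible gears the one with
mean closest to 2.8 wins, ties to the smaller gear.  Derived quantities
(seeds/grid, frame dimensions) are reported at two decimals, the precision
of the reference tables.

## Image pipeline

**Binarization.** Foreground is fixed as 1 = bright content (seeds and the
tray border), background 0.  Nursery soil images darker than both, so Otsu
thresholding separates the two populations; a fixed threshold is available
for controlled fixtures.  (Some descriptions of this procedure assign seeds
the *low* gray value; the polarity here is chosen so projection profiles
rise where content appears, which is the behaviour the localization step
relies on.)

**Tray outline and rectification.** The largest 8-connected foreground
component is the tray; its four corners are the convex-hull points extremal
along the diagonal directions (min r+c, max c−r, max r+c, max r−c), valid
for trays upright or tilted < 45°.  Rectification uses a full 4-point
homography rather than an affine map: a hand-held photograph has
perspective distortion, and an affine transform cannot fit four arbitrary
corners.  Corners map exactly; interior error is interpolation-level.

**Detection-area localization.** Row and column cumulative sums of the
binary image (`w(i) = Σ_j p(i,j)`, `h(j) = Σ_i p(i,j)`) show four abrupt
segments: the profile rises from zero where the bright border band enters
and falls back where the soil cavity begins.  The band's outer onset is the
first value ≥ `threshold_frac` (default 0.05) of the profile maximum; the
inner edge is the first subsequent index where the profile drops below
`drop_frac` (default 0.5) of the running band maximum.  A minimum run
length (default 5 px) rejects isolated spikes.  A relative drop criterion
rather than a fixed threshold is used because interior columns are not
empty — they carry seed mass and soil speckle — while the border band sums
over the full image height; the two regimes differ by roughly an order of
magnitude, so the 0.5 drop is insensitive to seed density and noise.
Detection-area edges are the four inner-edge indices, half-open
`[b2, c2) × [b1, c1)`.

**Tiling.** Cut positions are `round(linspace(lo, hi, n+1))` per axis, so
tiles partition the area exactly and sizes differ by at most 1 px; the
rounding remainder is distributed across the grid instead of accumulating
on the last tile.  Tiles are row-major, 0-based, half-open.

## Detector

The deterministic backend (`blob_detect`) reports every 8-connected
foreground component of area ≥ 9 px (rejecting soil speckle) as one seed
with confidence 1.  Components touching the tile edge are kept regardless
of area: they may be slivers of a seed cut by the tiling, and discarding
them would break fragment merging.  This backend is exact on non-touching
seeds and anchors all pipeline-level tests.

The neural building blocks are NumPy forward-path implementations with
explicit parameters:

- **ODConv** — the effective kernel is `Σ_i α_wi (α_fi ⊙ α_ci ⊙ α_si ⊙ W_i)`
  over n candidate kernels, with softmax attention over kernels and sigmoid
  attentions along the spatial (k×k), input-channel and output-channel
  axes, produced by a GAP → bottleneck (reduction 4) → four-head block.
  With n = 1 and unit attentions it reduces exactly to a standard
  convolution, which is the anchor test.
- **ECA** — per-channel gates from a 1-D convolution (no dimensionality
  reduction) over the globally average-pooled channel vector, kernel size
  the nearest odd integer to `|log2(C)/γ + b/γ|` with γ = 2, b = 1.
- **Losses** — `L_IoU = 1 − IoU`; CIoU adds the normalized center distance
  `ρ²/(W_g² + H_g²)` and the aspect term `αv` with
  `v = (4/π²)(arctan(w/h) − arctan(w_gt/h_gt))²`, `α = v/(L_IoU + v)`
  (`α = 0` when `v = 0`).  Wise-IoU v1 multiplies `L_IoU` by
  `exp(ρ²/(W_g² + H_g²))` with the enclosing-box term held constant
  (no gradient).  v3 multiplies by the non-monotonic focusing coefficient
  `r = β / (δ·α^(β−δ))` with α = 1.9, δ = 3, where the outlier degree β is
  the detached current `L_IoU` over its running mean.  `r(δ) = 1` exactly
  and r vanishes at both extremes, concentrating gradient gain on
  medium-quality anchors.  The running mean is an exponential moving
  average, momentum 0.9, initialized at 1.0 (no momentum value is standard;
  0.9 per-batch is the common detector practice).

The assembled network follows the nano-scale one-stage layout (stride
8/16/32 heads): the backbone C2f blocks that feed the neck use
dynamic-convolution bottlenecks (second 3×3 conv replaced by ODConv), an
ECA block follows each neck fusion stage, and the box loss is Wise-IoU v3.
The assembly is validated structurally — three finite prediction scales,
parameter count (~3.0 M at nano scale), loss swap changing values but not
shapes.  Full-scale training (SGD, lr 0.01, batch 32, 200 epochs, 640 px
input) is provided as a configuration preset only; the desk-scale
convergence contract is finite-difference gradient descent of a box onto a
target under the v3 loss, which must reduce the loss over 20 steps.

## Seed ownership and uniformity

A detection may intersect up to four grids.  Ownership goes to the grid
covering the largest share of the *bounding box* (the detector's output,
and cheap to intersect with the rectangular grid); exact ties go to the
smallest (row, col), a deterministic, order-independent rule.  Seeds cut by
tile boundaries are first re-merged: two detections unify when their boxes
overlap with IoU ≥ 0.3, or when they come from adjacent tiles, both abut
the shared boundary within 2 px, and their projections on that boundary
overlap; merging is transitive, and the merged seed takes the union box.
The qualification rate is the percentage of grids with 1–3 seeds, the
empty-grid rate the percentage with 0, both at two decimals; the miss rate
is `(annotated − detected)/annotated × 100`; the test error is the signed
difference between actual and estimated qualification rates.

## Synthetic scenes

The generator renders what the pipeline consumes: a dark margin, a bright
border band (default 30 px), a soil-gray detection area (level 60, optional
Gaussian texture noise), and bright elliptical seeds (level 200, default
8 × 3 px at a scale of 2.8 px/mm ≈ 40 px per grid frame) with uniformly
random orientation.  Gray levels are two-level by design so Otsu
binarization is unambiguous and noiseless renders are pixel-exact.  An
optional random homography (corner displacement up to tan 5°) exercises the
outline-extraction and rectification stages.

Seed placement emulates the three sowing methods.  Broadcast is uniform
over the area.  Strip modes allocate seeds evenly to the 18 strips, confine
the lateral coordinate to a band of 0.4 (ditching) or 0.7 (no ditching) of
the strip pitch, and meter seeds along the length with jittered even
spacing — ±0.35 of the mean spacing for ditching, ±0.7 for no ditching.
The steadier metering of the ditching mode is what makes its rendered trays
measurably more uniform, so the field ordering (ditching strip >
no-ditching strip > broadcast qualification rates) emerges from the
placement model rather than being asserted.  Placements are rejected until
every seed's bounding box clears every other's by ≥ 2 px (seeds never
touch, so the component detector is exact) and, unless the seed is in the
configurable straddling fraction, stays ≥ 3 px inside its tile (so
fragments arise only when requested).  A scene's manifest stores each
seed's drawn pixel bounding box and its grid label computed with the same
largest-coverage rule the pipeline uses, making manifest-versus-pipeline
agreement a genuine end-to-end oracle rather than a tautology about shared
code paths: the pipeline must re-derive the area, tiles, detections and
merges from pixels alone.

What the generator does *not* model: photometric gradients and shadows,
lens distortion, soil texture with seed-like bright particles, seed
overlap/occlusion (available behind an `allow-straddle`-style flag only for
boundary cutting; overlapping seed bodies are excluded by construction, as
high-density overlap is excluded from the method's scope), and non-elliptic
seed silhouettes.  Passing the synthetic suites therefore demonstrates the
correctness of the geometry, bookkeeping and statistics — not field-level
detection robustness, which requires real photographs and the trained
network.

## Problem sizes

Synthetic benchmarks run at 2.8 px/mm (≈ 1620 × 780 px detection areas,
full seed counts of 2020–2828), the package's chosen desk-scale rendering
resolution; reduced 6 × 10-grid trays (~150 seeds) back the high-repetition
property tests (50-tray fragment-merging study, 20-tray border-localization
study).  All stochastic stages take explicit integer seeds and are
bit-reproducible.
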