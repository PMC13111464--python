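# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phenopoint`, a toolkit for extracting organ-level traits
(leaf length, stem diameter) from single-view colored point clouds of
greenhouse tomato seedlings.

## Pipeline overview

A raw depth-camera cloud passes through: (1) region-of-interest condition
filtering, (2) color-based noise removal, (3) downsampling, (4) semantic
organ segmentation (stem / growing point / leaf) with a PointNet++-style
network whose sampling layer is voxel-grid based, and (5) geometric trait
extraction on the segmented organs.

## Coordinate conventions

Coordinates are millimetres. The package treats **z as the vertical (up)
axis** everywhere: the default augmentation rotation axis, the synthetic
stem direction, and the stem-slice height axis. All of these are
configurable; acquisition rigs differ, and the ROI filter is fully generic
per axis (documented defaults: depth z ∈ [350, 450] mm, height y ∈
[500, 650] mm for a downward-tilted camera).

## Noise removal

Time-of-flight sensors produce "flying pixels" along silhouettes where one
pixel mixes foreground and background returns. These points are embedded in
the plant's volume — they are *not* spatial outliers — but they carry
neutral gray colors, so the package removes them in color space:

- **K-means color clustering** on the per-point RGB matrix (Lloyd
  iterations, seeded greedy farthest-color initialization, tolerance 1e-4 on
  centroid movement). The cluster count k comes from the number of dominant
  modes in a smoothed luminance histogram, clamped to [2, 4]; ambiguous
  histograms default to the background/target binary split (k = 2). The
  plant is the union of clusters whose mean Excess Green clears a
  vegetation floor (default 25 ExG units, ≈ 1σ of per-point ExG noise at
  10-unit channel noise); the greenest cluster is kept as fallback when
  none clears it. The floor is physical, not relative: achromatic flying
  pixels have ExG ≈ 0 *by construction* (foreground/background mixtures
  are gray), while any vegetative surface — including brown-green stems —
  clears a few tens of units. A relative rule such as "above the
  across-cluster mean" misassigns the stem whenever k ≥ 3 separates leaf
  green from stem brown. Note also that flying pixels are usually a small
  fraction of points, so the histogram behind `choose_k` cannot always see
  them; for whole plants with visible stems, set k = 3 explicitly — the
  per-sample histogram inspection the acquisition protocol implies. RGB-only
  features are used (no spatial coordinates): the separation signal is
  chromatic, and adding coordinates would entangle the two.
- **Excess Green segmentation** (ExG = 2G − R − B ∈ [−510, 510]) with an
  automatic threshold at the histogram valley between the two
  highest-count modes (bin width 10 ExG units, 102 bins over the full
  range). Unimodal histograms fall back to the midpoint between mean and
  max. Fixed thresholds are supported but not default; any fixed value is
  sample-specific.

## Downsampling

- **Voxel-grid downsampling (VGDS)**: half-open cells `[lo, lo+s)` anchored
  at the cloud's min corner; one representative per occupied voxel
  (centroid by default — it suppresses noise; voxel centers and
  nearest-to-centroid points are options), output ordered by lexicographic
  voxel index. Label-carrying clouds take the per-voxel majority label in
  centroid mode.
- **Farthest point sampling (FPS)**: greedy max–min with squared Euclidean
  distances, start index 0 (deterministic; seeded random start optional),
  ties to the lowest index.
- **Cost accounting**: both samplers report `distance_ops`, the count of
  point-to-point distance evaluations — a hardware-independent complexity
  surrogate. FPS updates one distance per candidate per iteration
  (m·N total); centroid-mode VGDS performs none. This asymmetry, not any
  wall-clock value, is the portable form of the samplers' runtime gap, and
  the package's benchmark asserts it alongside a machine-local timing
  comparison.
- **Exact-count matching**: a set-abstraction layer needs exactly N′
  centroids, but voxel size controls the count only indirectly. The package
  bisects the voxel edge length over [ε, cloud diameter] (occupancy is
  non-increasing in the edge length), then reconciles the residual
  mismatch with a seeded uniform drop (count > target) or seeded duplicate
  padding (count < target).

## Segmentation network

A compact encoder–decoder in the PointNet++ family, written in NumPy with
explicit forward and backward passes (dense layers, ReLU, neighborhood max
with argmax gradient routing, gather/scatter through grouping indices;
Adam with L2 weight decay).

- **Set abstraction (3 levels)**: sampling (VGDS exact-count by default,
  FPS as a drop-in toggle), ball-query grouping (radius fractions 0.05 /
  0.1 / 0.2 of the normalized cloud diameter, K = 32/16/8 neighbors,
  groups short of K padded with the centroid-nearest point), then the
  symmetric encoder `gamma(max_i h(x_i))` — shared MLPs h and gamma with a
  coordinate-wise max, exactly invariant to within-neighborhood
  permutation and duplication.
- **Input features**: the normalized absolute coordinates of each point
  (plus RGB, off by default). Neighborhood-relative coordinates alone carry
  no global position, and organ identity in a canopy is strongly
  height-coded, so the coordinates-as-features choice matters; RGB stays
  off by default because organ palettes are a sensor- and lighting-specific
  signal.
- **Decoder**: 3-nearest-neighbor inverse-distance-squared interpolation of
  coarse features (weights collapse onto a coincident centroid), skip
  concatenation with same-level encoder features, shared MLP per stage,
  then a per-point head with dropout 0.5 and a 3-class softmax.
- **Loss**: cross-entropy with inverse-support class weights (∝ 1/N_k,
  normalized to mean 1). Leaf points dominate a tomato canopy (~60 %), and
  support-proportional weights would amplify that majority rather than
  counter it.
- **Training**: Adam, weight decay 1e-4, learning rate halved every
  `lr_step` epochs, early stopping on validation mIoU with the best-epoch
  weights restored. Field-scale defaults follow common practice for this
  model family (batch 7, lr 1e-4, 20,000 input points, 100 epochs); the
  **desk preset** — 1,024 points, narrow layers, lr 2e-3, ≤ 100 epochs —
  is the configuration the test suite exercises end to end. Sampling and
  grouping geometry is independent of the weights, so each training cloud's
  pyramid is precomputed once and reused across epochs.
- **Full-resolution prediction**: the input cloud is resampled to the
  network budget, scored, and scores are propagated back by
  inverse-distance blending over the three nearest sampled points, averaged
  over three small-rotation resampling views (rotations are part of the
  training augmentation, so the views are in-distribution).

**Resolution ceiling.** Propagating even *perfect* 1,024-point labels back
to a ~17k-point plant caps the growing-point IoU near 0.7 — the blob's
boundary interleaves with young leaves below the sampling density. Network
quality at the desk scale is therefore assessed at the operating resolution
(held-out plants resampled to 1,024 points); full-resolution IoU is
reported alongside as a property of the resample-and-propagate pipeline,
not of the classifier. Field-scale budgets (20,000 points) do not sit at
this ceiling.

## Leaf length

Single-view leaf clouds are non-closed surfaces, so mesh-skeleton methods
do not apply. Instead: project the leaf onto the XOY and YOZ planes, fit
each projection with a least-squares polynomial (shared parameter y),
extrude both fits into surfaces, and take their intersection — the space
curve r(y) = (f(y), y, g(y)) — as the midrib. The leaf length is its arc
length ∫√(x′² + 1 + z′²) dy, integrated by composite Simpson (1,000
subintervals, doubled until the relative change is < 1e-8; derivatives are
analytic from the polynomial coefficients).

Choices that the procedure leaves open, and how they are resolved:

- **Shared parameter axis**: a PCA pre-alignment rotates each leaf so its
  principal axis is y (and its flattest axis is x), making both planar
  projections single-valued functions of y. This also gives rigid-motion
  invariance (< 1 % length change under arbitrary rotation + translation).
- **Polynomial degree**: default 3 (configurable 1–6). A cubic captures
  the single bend of a tomato leaflet without oscillating; strongly curled
  leaves violate the single-valued-projection assumption at any degree and
  are a known limitation.
- **Fit domain**: [min, max] of the parameter among leaf points — no
  extrapolation — with an **endpoint correction**: the observed extremes
  overshoot the true extent by the extreme-value tail of the measurement
  noise (≈ σ√(2 ln n) for Gaussian noise), which inflates the integral.
  The smaller of the two fit RMS residuals estimates σ without
  contamination from the leaf's own width; the domain shrinks by that tail
  estimate per end, capped at 2.5 % of the span. The correction vanishes on
  noiseless data.

## Stem diameter

Seedling stems taper, so the diameter is measured at a fixed height:
10 mm above the base (the minimum height coordinate of stem-labeled
points). The chain is: straighten → slice → oriented bounding box → align →
project → least-squares circle, d = 2r.

- **Straightening**: the stem's principal axis (covariance PCA) is rotated
  onto the vertical before slicing; slicing a tilted stem horizontally
  yields an elliptical section and a biased diameter.
- **Slab**: half-thickness 2.5 mm — thick enough for a dense ring at
  typical sensor densities, thin enough that taper within the slab is
  negligible.
- **OBB**: PCA of the slab covariance, eigenvalue-ordered, sign-fixed,
  determinant +1 (RᵀR = I to 1e-9). An exact minimal-volume box is
  disproportionate for a thin annulus; the PCA box is the standard
  approximation.
- **Projection**: the `auto` rule drops the OBB axis most parallel to the
  stem direction, always presenting the cross-section plane. A
  max-2D-spread plane choice fails on single-view (partial-arc) stems,
  whose chord/height spread exceeds their sagittal depth; fixed XOY/XOZ
  choices remain available.
- **Circle fit**: the algebraic (Kåsa) linearization of
  Σ[(x−a)² + (y−b)² − r²]² solved in closed form on centered data, then
  Gauss–Newton refinement of the same quartic objective (default on). The
  algebraic objective is what the fit minimizes; a geometric-distance fit
  differs only in the noise weighting and is available through the
  refinement machinery.
- **Single-view bias**: a 180°-visible stem biases the fit by a few
  percent (documented by test at < 10 % for an 8 mm stem); full-ring
  sections recover to < 2 %.

## Synthetic plants

The generator emulates the acquisition conditions the pipeline targets —
potted tomato seedlings at the three-to-seven-true-leaves stage — with
exact ground truth:

- **Stem**: cylinder-surface samples, diameter default 8 mm (corpus sweeps
  4–13 mm, matching field-measured ranges), height 150 mm, radial noise
  σ = 0.1 mm, optional partial arc for single-view emulation.
- **Growing point**: a dense Gaussian cluster (σ = 5 mm, truncated at
  15 mm) at the stem apex.
- **Leaves**: bands of half-width 8 mm around polynomial midribs attached
  along the stem (extent 70–130 mm, single arch, point noise σ = 1 mm);
  the true arc length of each midrib is computed by 100,000-interval
  Simpson quadrature on the generating curve. Leaves are simple bands, not
  pinnate compounds: the leaf-length definition follows the main axis,
  which a band models sufficiently for recovery tests.
- **Palettes**: leaf green (60, 150, 70), stem green-brown (100, 120, 70),
  flower yellow (200, 190, 60), noise gray (128, 128, 128), each with
  ~10-unit channel noise — chosen so ExG separates vegetation (≈ +170)
  from gray noise (≈ 0), the precondition the denoising stage exploits.
- **Flying pixels**: gray points offset 5–30 mm outward from
  silhouette-biased anchor points, labeled −1 — reproducing the edge-pixel
  mechanism rather than uniform scatter.

What the generator does *not* model: pinnate leaflet structure, occlusion
between organs, sensor-specific depth noise anisotropy, laser bloom, or
photorealistic color variation. Passing recovery tests on these plants
demonstrates the geometry pipeline closes the loop under controlled noise;
it does not certify accuracy on field data.

## Dataset bookkeeping

Corpora split 7:3 at the *plant* level before augmentation (training count
= round(0.7·n)), so no augmented variant of a test plant leaks into
training: 97 plants → 68/29. The default augmentation scheme is pinned to
exactly 16 variants per sample — 8 rotations (0°…315° at 45°) × {identity,
horizontal mirror} — which expands 68/29 into 1,088/464 (1,552 total).
Coordinate inversion (x, y, z → −x, −y, −z) exists as a separate operator
but is not part of the default scheme: the rotation × mirror composition
already accounts for the full 16× expansion.

## Evaluation metrics

Per class k: precision TP/(TP+FP), recall TP/(TP+FN), F1 as their harmonic
mean, IoU TP/(TP+FP+FN). Aggregates are support-weighted
(w_k = N_k / Σ N_j); overall accuracy is Σ TP_k / N. The per-class
"accuracy" column uses the one-vs-rest reading (TP_k + TN_k)/N — the only
interpretation under which a per-label accuracy can exceed that label's
recall, as organ-level tables in this literature show. Metrics that would
be 0/0 (absent classes) score 0 and carry an `undefined` flag rather than
silently inflating aggregates.

## Problem sizes used by the test suite

The suite runs on synthetic corpora sized for a laptop-class machine: the
97-plant bookkeeping corpus, 20-plant trait-recovery sweeps, a
200,000-point cloud for the sampler comparison (m = 10,000), and the desk
network preset (1,024 points, 4 training plants, ≤ 100 epochs, 3 seeds).
The field-scale network configuration (20,000 points) shares every code
path but is not exercised by default.

## Known limitations

- Leaf-length fitting assumes single-valued projections along the
  principal axis; strongly curled or twisted leaves break this.
- The stem circle fit assumes a near-circular cross-section; elliptical
  stems bias d = 2r.
- Single-view stems (partial arcs) carry a documented few-percent bias.
- The NumPy network trains CPU-scale problems; it is a faithful but small
  sibling of GPU implementations of this architecture.
- Occlusion detection ("non-occluded leaves" selection) is the caller's
  responsibility.
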