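# phenopoint

Organ-level trait extraction from single-view colored point clouds of
greenhouse tomato seedlings: preprocessing and color-based denoising,
voxel-grid vs farthest-point downsampling with hardware-independent cost
counters, a PointNet++-style organ-segmentation network whose sampling layer
is voxel-grid based (VGDS-PointNet++), and geometric measurement of leaf
length and stem diameter. A deterministic synthetic-plant generator with
exact ground truth makes the whole pipeline testable offline.

## Who this is for

Plant-phenotyping researchers working with depth-camera (ToF) point clouds
of greenhouse crops, who need reproducible organ segmentation and trait
measurements, and tool builders who want the individual stages (ExG
segmentation, K-means color denoising, exact-count voxel sampling,
least-squares space-curve fitting, OBB-aligned circle fitting) as a library.

## The core methods

**Noise removal in color space.** ToF "flying pixels" sit inside the plant
volume but are chromatically gray. K-means clustering of the RGB matrix
separates them; where colors are ambiguous, the Excess Green Index
`ExG = 2G − R − B` with an automatic histogram-valley threshold segments
vegetation.

**Sampling.** A set-abstraction layer needs exactly N′ centroids. Farthest
point sampling gives them at O(m·N) distance evaluations; voxel-grid
downsampling gives them at zero distance evaluations (centroid mode) via
bisection on the voxel size. Both samplers report a `distance_ops` counter
so the complexity gap is measurable on any machine.

**Segmentation.** Three set-abstraction levels (sample → ball-query group →
symmetric encoder `γ(maxᵢ h(xᵢ))`), a feature-propagation decoder with
3-NN inverse-distance interpolation and skip connections, and a per-point
3-class head (stem / growing point / leaf). Implemented in NumPy with
explicit backpropagation; trained with Adam, weight decay, lr decay,
dropout 0.5, and early stopping on validation mIoU.

**Leaf length.** Project the leaf onto two orthogonal planes, fit each
projection with a least-squares polynomial (degree 3 by default), intersect
the two extruded surfaces into the space curve r(y) = (f(y), y, g(y)), and
integrate its arc length L = ∫√(x′² + 1 + z′²) dy.

**Stem diameter.** Slice a 5 mm slab 10 mm above the stem base, align it
with its oriented bounding box (RᵀR = I), project onto the cross-section
plane, and fit the circle (x−a)² + (y−b)² = r² by the algebraic least-squares
(Kåsa) solution with Gauss–Newton refinement; d = 2r.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from phenopoint import (PlantSpec, generate_plant, kmeans_color_denoise,
                        leaf_traits, stem_traits)
from phenopoint.denoise import ColorClusterConfig

# a synthetic plant with known ground truth and 400 gray flying pixels
cloud, truth = generate_plant(PlantSpec(seed=7, flying_pixel_count=400))
print(len(cloud))                        # 17879 points

# three dominant color components (leaf green, stem brown, noise gray):
# k-means with k=3 keeps both organ clusters and drops the gray one
clean = kmeans_color_denoise(cloud, ColorClusterConfig(k=3))
print(len(clean), int(np.sum(clean.labels == -1)))   # 17477 0

# leaf length of instance 2 vs its ground-truth midrib arc length
pts = clean.coords[clean.labels == 2]
length, curve = leaf_traits.leaf_length(pts)
print(round(length, 1), round(truth.leaf_lengths_mm[2], 1))   # 126.1 129.2

# stem diameter vs the generating cylinder
stem_pts = clean.coords[clean.labels == 0]
d, fit, obb = stem_traits.stem_diameter(stem_pts)
print(round(d, 2), truth.stem_diameter_mm)            # 7.99 8.0
```

The denoiser keeps 17,477 of 17,479 organ points and drops all 400 flying
pixels; the measured leaf length lands within 2.4 % of the generating
midrib's true arc length, and the fitted stem diameter within 0.2 % of the
generating cylinder's.

Command-line equivalents:

```bash
phenopoint synth --n 5 --out plants/ --seed 7
phenopoint denoise --in plants/plant_000.ply --out clean.ply --method kmeans
phenopoint traits leaf --in clean.ply --report leaves.csv
phenopoint traits stem --in clean.ply --report stem.csv
```

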