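# Methods

`pigback` estimates body measurements and weight of sows from a single
back-view 3D point cloud captured by an overhead depth camera. This note
describes the models and procedures the package implements, the choices
made where the design was genuinely open, and what the synthetic test bed
does and does not demonstrate.

## Pipeline

The measurement chain is `filter → segment → trim → pose-correct →
measure → predict`, operating on a PLY point cloud in meters (camera at
the origin, z the depth axis; a floor at 2.5 m depth appears near
z = −2.5).

### Voxel filtering

Space is divided into cubic cells of side `edgelength` (default 0.03 m,
the value at which down-sampling preserves back-surface structure while
cutting the cloud by an order of magnitude). Each occupied cell's points
are replaced by their arithmetic mean; colors by the rounded mean. The
grid is anchored at the cloud's minimum corner with half-open cells
`[k·e, (k+1)·e)` — the anchoring convention is ours, since only the cell
size is standard.

### K-means segmentation

Lloyd's algorithm on xyz coordinates only (RGB never enters the metric):
assignment by squared Euclidean distance, centroid update by cluster mean,
convergence when no centroid moves more than 1e-6 m, capped at 300
iterations. Initialization draws K distinct data points uniformly;
the best of `n_restarts` runs by SSE is kept. The default is 40 restarts:
on scene-scale clouds the SSE landscape has a deep object-aligned optimum
separated from shallower slicing optima by less than 2% of SSE, and 10
random restarts miss it on roughly a quarter of scenes. Empty clusters
during iteration are reseeded from the point farthest from its centroid.

The number of clusters can be chosen by the elbow of the SSE(K) curve,
operationalized as the interior K maximizing the second difference
`SSE(K−1) − 2·SSE(K) + SSE(K+1)`. Two caveats, both verified
experimentally: the rule recovers the component count only when the
components are compact (on compact well-separated blobs the SSE curve is
linear before the true K and flat after, giving a sharp maximum exactly
there); on full station scenes, whose floor and wall structures are
extended, splitting a background structure keeps paying beyond the
component count and the raw-SSE curvature peaks at K = 2. The pipeline
therefore defaults to the fixed operating point K = 3 (animal, floor,
walls) with `k: auto` available in the configuration.

The animal is the cluster with the greatest mean elevation toward the
camera (largest mean z with our sign convention), ties broken by size —
the back is the raised surface between floor and lens. Axis and sign are
configurable for other camera conventions.

### Head/tail trimming by weighted local density

Blocks of a square 0.02 m grid over the horizontal plane are scored by the
mean 3D distance of member points to the block center, excluding the
single farthest point (zero for blocks with one point). Over the nearly
flat top of the back a block's points are tightly grouped; over steep
structures — the flanks of the head and tail — they spread vertically, so
high scores outline the protrusions. This is especially crisp after voxel
filtering: flat regions retain about one point per block while steep
regions stack several.

Blocks above the 90th percentile of scores are clustered with DBSCAN
(radius 0.5 m, minimum neighborhood 10; re-implemented by region query and
expansion) to discard isolated noise blocks. Among the clustered block
centers, the two with extreme projections onto the body axis (the
horizontal principal direction of the cloud, configurable to a fixed
coordinate axis) are the end points, and all points within 0.4 m of either
end point along the axis are removed. If the maxima span no more than the
two trim extents (a single knot, or no maxima at all), trimming is skipped
with a warning and the input is returned unchanged — the caller still gets
a total operation.

The head end is identified as the end point whose neighborhood of maxima
blocks is wider across the body axis: the head is the broader protrusion.
This labeling feeds the anatomical mapping of the measurement stage.

### Pose correction and width extraction

A PCA oriented bounding box (principal axes of the point covariance,
extents from projection ranges) defines the body direction; an exact
minimum-volume box is deliberately not used — for elongated bodies the
PCA box is standard, deterministic, and its long axis is the quantity the
pose step needs. If the long axis deviates from the x direction by more
than 1° in the horizontal plane, the cloud is rotated about the vertical
axis through its centroid to null the angle; pitch and roll are left
untouched. The correction is idempotent and preserves pairwise distances
to machine precision.

The aligned cloud's x-range is split into three equal sections; each
section into 20 x-bins; a bin's width is `y_max − y_min` over its points
and the section width the maximum over non-empty bins (binning replaces
the measure-zero "same x coordinate" condition on real data). Sections
map to anatomy by proximity to the recorded head end point: nearest =
shoulder, middle = abdomen, farthest = hip. Anatomy, not slice numbering,
is the invariant — slice numbering conventions vary between write-ups,
so the package never relies on index order.

Width accuracy is scored by the mean relative error `100·mean(|true −
est|/true)` with the tape-measured value as denominator. On the bundled
seven-animal reference table this reproduces the published shoulder
(3.144%) and hip (3.820%) figures exactly; the published abdominal figure
(3.798%) is only reproducible with the *extracted* value as denominator
(the true-value convention gives 3.787%), an internal inconsistency of the
source table; the package reports the true-value convention for all three.

### Weight regression (MACNN)

The regressor consumes a fixed-size point set (default 1024 points
resampled uniformly, seeded; coordinates centered at the cloud centroid;
optional RGB scaled to [0,1]) and applies:

1. five pointwise convolutions (kernel size 1 across the point dimension —
   spatial kernels are meaningless on unordered point lists) with strictly
   increasing channel counts, default (32, 64, 128, 256, 512), each
   followed by an activation and batch normalization;
2. k parallel scaled-dot-product attention heads,
   `softmax(QKᵀ/√d)·V` with learned linear maps Q, K, V per head, heads
   concatenated (default 4 heads × 128 dims, matching the 512-channel
   output);
3. global max pooling over points (the source of permutation invariance),
   dropout (0.5), and a single linear output node.

Training is plain SGD at learning rate 0.001, batch size 128, MSE loss
with L2 penalty λ = 0.001 on weights (not biases or batch-norm affine
parameters), Xavier-uniform initialization, and an 80/20 train/validation
split, all seeded. Everything — forward, backward, batch-norm and
attention gradients — is implemented in numpy and verified against central
finite differences to 1e-4 relative error.

Numerical choices that mattered in practice:

* **Target standardization.** Raw kg-scale MSE (~10³–10⁴ kg²) diverges
  under plain SGD at lr 0.001; the network is trained on standardized
  targets and predictions are de-standardized, leaving the public
  interface in kg.
* **Batch-norm calibration.** After the last epoch the running mean and
  variance of every batch-norm layer are re-estimated layer-by-layer over
  the training set (the inference recipe batch normalization was
  originally defined with). Momentum-averaged estimates lag the final
  weights and can mispredict sharply-fit samples by large margins.
* **Activation.** The activation is configurable (`relu`,
  `leaky_relu`); the default is leaky ReLU (slope 0.01) as the more
  robust member of the family. No published choice exists to follow.
* **Attention placement.** The attention block sits after the fifth
  convolution block and before pooling.

## Synthetic test bed

No farm recordings are available to this package, so the generator is
its test instrument. It is first-class, fully tested code whose
ground truth is exact by construction.

**Animal.** The back is the upper surface of a tapered elliptical
cylinder. The half-width profile is piecewise linear through the
shoulder/abdomen/hip control widths at the three section midpoints, with
each width transition placed inside the wider section — this makes the
maximum chord of every third of the body equal its control width exactly,
so measured widths have exact targets. Head and rump are elliptical domes
running from the torso ends outward; their apices sit ≈0.4 m beyond the
torso ends so that the fixed 0.4 m trim removes the caps and spares the
torso; the head dome is broader and steeper than the tail dome (the cue
the trimmer's head/tail labeling uses). Coordinates get isotropic
Gaussian sensor noise (default σ = 5 mm); colors follow a base color plus
an along-body gradient.

**Scene.** The station is built around the animal the way the camera sees
it: a circular field-of-view footprint (a cone-FOV depth sensor gated to
the station yields a round crop), the floor with the animal's
self-occlusion shadow removed (a nadir camera cannot see the floor within
≈0.15 m of the silhouette), floor/wall point densities scaled by
1/depth² relative to the back (a projective sensor spreads a fixed pixel
budget over solid angle), two channel walls parallel to the body, and a
0.12 m weighbridge platform under the animal (hidden inside the occlusion
shadow). Sampling density defaults to 24,000 points/m² at the back,
matching the order of magnitude of raw station captures.

These geometric elements are not decoration: coordinate K-means recovers
an elongated animal as a single cluster only when the background
structures are compact relative to their separation from the body.
Rectangular "infinite floor" scenes make slicing the scene along its long
axis the global SSE optimum, which cuts the animal in half — with the
circular crop, occlusion shadow, perspective density and wall anchoring,
the object partition is the verified global optimum across random animals.
Passing segmentation tests therefore demonstrates that the method works in
the station geometry the generator models, not on arbitrary scenes.

**Weight.** Ground-truth weight follows a generic allometric volume proxy,
`a·(length · mean width · height)^b` with a = 430, b = 1 and 5 kg of
Gaussian scatter, placing the sampled cohort in roughly 130–360 kg — the
adult-sow range. It exists to make weight a recoverable function of shape,
not to model sow growth. One cohort preset ties color brightness to the
body-size scalar (so RGB features carry genuine weight information — the
regime in which the RGB ablation has signal to find); a negative-control
preset draws brightness independently.

**What the tests do not show.** The generator has no occluding equipment,
no missing-data holes, no motion blur, no multi-animal scenes, no
posture variation beyond yaw, and its weight law is synthetic. Error
magnitudes on real recordings are expected to be larger; directional
results (RGB features helping, trimming isolating the torso) are the
transferable findings.

## Problem sizes

Default test and acceptance runs use 50 random scenes for the measurement
chain, 6 scenes for segmentation quality, 20 animals for trimming rates,
and a 200-animal cohort (40 held out) with a reduced network — 128 points,
channels (8, 16, 32, 48, 64), 80 epochs — for the RGB ablation; the
memorization check uses 10 animals, 500 epochs and no dropout. Model
cohorts are generated at 6,000 points/m²: features are resampled to the
fixed network input size anyway, so the extra density would be discarded.

## Known limitations

* The elbow rule on full scenes selects K = 2 (see above); component-count
  recovery holds on compact-blob constructions only.
* Head/tail identity relies on the head being the broader protrusion; an
  animal with head tucked against a wall would defeat it.
* Trimming assumes the measurement protocol's fixed 0.4 m extent; animals
  shorter than twice that extent cannot be trimmed meaningfully (the
  operation degrades to a warning and returns its input).
* The per-animal tail of torso-removal rates reaches ~13% on occasional
  specs (aggregate ≈5%) when the rump rim thins out after voxel
  filtering.
* Weight predictions are only as good as the synthetic weight law; no
  claim is made about kg-scale accuracy on real animals.
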