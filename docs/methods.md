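# Methods

`rotovol` implements a label-free single-cell 3-D tomography pipeline.  A
cell held in an acoustofluidic trap is rotated through full revolutions
while a bright-field camera records it; a 3-D convolutional network, trained
against confocal z-stacks, regresses a volumetric reconstruction directly
from one rotation period of video.  Texture statistics of the reconstructed
volumes then drive cell-type classification and drug-response scoring.
Because no public recordings accompany this problem, every stage is
validated against a synthetic phantom generator with exactly known geometry.

## Phantom model

A cell is modelled as a soft-edged ellipsoid whose radius is modulated by
band-limited angular noise,

    r(θ, φ) = r₀ · (1 + A · g(θ, φ)),

where `g` is a unit-normalized superposition of 12 random plane waves
evaluated on the unit sphere, with amplitude `A` and angular frequency band
set by the preset:

| preset        | A    | band | emulated phenotype                        |
|---------------|------|------|-------------------------------------------|
| smooth        | 0    | —    | epithelial (HeLa-like), flat surface       |
| rough         | 0.18 | ~9   | macrophage-like, dense protrusions         |
| striated      | 0.12 | 6    | cardiac-myoblast-like, periodic banding    |
| intermediate  | 0.08 | ~5   | melanoma-like, moderate roughness          |

Striations are a deterministic sinusoid along the z body axis rather than
random noise.  The interior intensity carries a matching volumetric texture
confined to [0.55, 0.95] so that the 0.5 iso-level of the membrane field is
exactly the geometric surface — this is what makes voxel-count and
Cavalieri volume oracles exact.  A concentric smooth nucleus sits at half
the radii; its support is clipped to the membrane support.

Default scale: semi-axes of 10–15 µm at 1 µm isotropic voxels (cells of
20–30 µm diameter), on grids of 40–64 voxels per axis.  All generators are
pure functions of `(seed, parameters)`.

An optional eccentric bright inclusion (`granule_contrast > 0`) places a
nucleolus-like landmark at half the cell radius.  A bare ellipsoid is
point-symmetric: its projection after a half revolution is nearly identical
to frame 0, which makes rotation phase ambiguous.  Real cells carry
distinguishable internal features (the feature points used for tracking),
so rotation-video studies here enable the granule; it is off by default so
the symmetric-geometry contracts (e.g. identical sphere projections at any
angle) hold exactly.

Rendering is an orthographic absorption-free sum along the optical (z)
axis after rigid trilinear rotation about the grid center, followed by
Gaussian blur (default σ = 1 px), additive Gaussian noise, clipping and
renormalization to [0, 1].  This is deliberately the simplest projection
model that preserves silhouette and internal texture; bright-field PSF
physics is out of scope.  Videos default to the recording protocol of 310
frames over 15 s; the synthetic default of 62 frames per revolution (five
revolutions per video) is a convenience, since real revolution rates vary
per cell and are estimated, not assumed.

Limitations the phantom does not emulate: optical diffraction and depth-
dependent defocus, absorption, non-rigid cell deformation during rotation,
neighbouring cells or debris, and photobleaching.  Passing tests therefore
demonstrate pipeline correctness on well-posed single-cell inputs, not
robustness to every imaging artefact.

## Preprocessing

Frames are Otsu-binarized with border-based polarity normalization (cells
may be bright-on-dark or dark-on-bright).  A single radius-1 disk dilation
bridges thin gaps before 8-connected component labeling; the largest
component's bounding rectangle is the ROI.  The network input stack takes
`depth` (default 10) frames equispaced over one estimated rotation period
starting at frame 0, crops each per-frame ROI (tolerating drift), resizes
bilinearly to `side × side` (default 100) and min-max normalizes the whole
tensor.  Confocal targets instead use one global bounding rectangle from
the union mask across slices, so all z-slices stay co-registered, then
resample z to `depth` equispaced slices (nearest-integer of a linspace over
both endpoints).

## Rotation stability

The correlation series is the Pearson coefficient between each frame and
frame 0, after re-centering every frame on its binarized centroid so
translational drift does not masquerade as rotation-phase change.  The
period estimator takes the mean spacing of near-maximum local peaks
(prominence floor 10 % of the series range, parabolic sub-frame
refinement, frame 0 as the first anchor) with two octave guards: peaks more
than 25 % of the range below the tallest are discarded, and if surviving
peak heights alternate low/high by more than 2 % of the range the spacing
is doubled.  The second guard is what disambiguates nearly 2-fold-symmetric
cells, whose correlation also peaks (slightly lower) at half revolutions.

Feature tracking locates a frame-0 template by normalized cross-correlation
in the frames nearest each full revolution (match-score floor 0.5) and
reports the absolute angle at the cell centroid between the frame-0 and
frame-k feature vectors.  The major axis comes from a second-order-moment
ellipse fit of the largest undilated component; a circular Hough transform
serves as an advisory consistency check only (cells are not circles), with
>10 % disagreement flagged as low confidence.

## Volumetric regression network

The network maps the 100×100×10 input stack to a volume of the same shape:
a ladder of 3×3×3, stride-1, zero-padded ('same') convolutions — default
filter counts 64, 32, 16, 8, 4 — each followed by an elementwise ReLU, and
a final linear 1×1×1 convolution to one channel.  'Same' padding is forced
by the geometry: with valid padding the 10-deep axis would vanish before
the fifth layer.  The convolution is the plain cross-correlation sum

    Z[i,j,k,o] = Σ_{l,m,n,c} W[l,m,n,c,o] · X[i+l, j+m, k+n, c] + b[o],

implemented in NumPy as 27 shifted-slice matrix products with analytic
backward passes (transposed-kernel convolution for the input gradient; the
weight gradient is the corresponding window/output contraction).  A
brute-force nested-loop evaluation of the same sum is kept as the test
oracle, and the analytic gradients are checked against finite differences.

Training minimizes voxelwise MSE with full-batch Adam (β₁ = 0.9,
β₂ = 0.999), seeded He-uniform initialization, float32 arithmetic, and
per-epoch loss and RMSE recorded.  Three guards stabilize optimization of
the deep ReLU ladder:

* ladder biases start at +0.1 — with zero biases, nonnegative image inputs
  and symmetric weights, half the units start inactive and whole layers can
  die irrecoverably;
* before the first update, the init is calibrated on one training pair
  (LSUV-style): each layer is rescaled to unit pre-activation standard
  deviation and the output layer matched to the target's mean and standard
  deviation, removing the large seed-to-seed variability in effective gain;
* a stalled run — best RMSE still at the constant-prediction baseline
  (the pooled target standard deviation) after 25 epochs — restarts from a
  fresh seeded init, up to three times, since that fixed point is never
  escaped once reached.

All three are deterministic given the seed.  One model is trained per cell
class and per channel (nucleus or membrane).
Desk-scale experiments in the test suite use 12 training phantoms and a
reduced five-stage ladder (4, 4, 4, 2, 2 filters) at learning rate 3e-3,
which keeps a full 200-epoch run in the minutes range on one CPU core
while preserving the five-layer depth — depth matters here beyond
capacity: each 3×3×3 stage widens the depth-axis receptive field by 2, and
only a five-stage ladder (receptive field 11) lets every output voxel see
all 10 temporally sampled input frames, which is what the video → z-stack
mapping requires.  A two-stage ladder plateaus at roughly twice the RMSE.
The filter ladder, epoch count and learning rate are all configuration
fields.

## Morphometrics

Volumes are uniformly quantized over their own [min, max] into 8 levels
(constant volumes are flagged rather than binned).  The 3-D gray-level
co-occurrence matrix pools counts over the 13 unique unit offsets, adds the
transpose (symmetric), and normalizes to sum 1; by default pairs are counted
only inside an Otsu foreground mask so empty background does not flatten
the statistics.  The six texture features use the common conventions:

    contrast       Σ p(i,j) (i−j)²
    dissimilarity  Σ p(i,j) |i−j|
    energy         Σ p(i,j)²
    homogeneity    Σ p(i,j) / (1 + |i−j|)
    entropy        −Σ p log₂ p          (0·log 0 = 0)
    correlation    Σ p (i−μᵢ)(j−μⱼ) / (σᵢ σⱼ)

Correlation is flagged undefined when σᵢσⱼ = 0.  Homogeneity's
inverse-square form and other entropy bases are switchable, as is a
slice-wise offset restriction for workflows that treat stacks as
independent sections.  Isosurfaces are marching-cubes meshes at an Otsu (or
given) isovalue, padded by the volume minimum so boundary-touching surfaces
stay closed; enclosed volume is computed by signed tetrahedra and
watertightness by the every-edge-shared-twice criterion.  Cross-correlation
matrices are pairwise Pearson coefficients of flattened volumes after
resampling to a common grid, with NaN flagging constant volumes.

## Statistics

PCA operates on z-scored features (the six texture scalars span orders of
magnitude; unstandardized PCA would be dominated by contrast) via SVD of
the centered matrix.  Classification is a linear-kernel, C = 1, one-vs-one
SVM evaluated by leave-one-out — the natural estimator in the ~30 samples
per class regime — aggregated into a confusion matrix with per-class
precision, recall, F1 and overall accuracy.  Traditional augmentation
(flips, right-angle rotations, ≤2 px / ≤10° affine jitter, σ = 0.01 noise)
is seeded and records per-output provenance; generative augmentation and
transfer-learning classifiers are intentionally out of scope.

Drug time courses run each timepoint's volume through the texture pipeline,
giving six feature trajectories; the coefficient of variation
(100 · sample SD / |mean|, n−1 denominator; population variant behind a
flag) summarizes each feature's variability over time.  Two conditions are
compared by a paired t-test on their six-long CV vectors, paired by
feature (n = 6, df = 5) — the pairing under which the published CV table
reproduces its stated p-value — with the two-sided p from the t
distribution.  No multiple-testing correction is applied, matching the
single-test design.  The CV percent convention uses the sample SD; the
underlying per-timepoint values needed to settle sample-vs-population are
not recoverable, so the population variant stays available behind a flag.

## Numerical and degenerate-input policy

Constant images make Otsu thresholds and Pearson correlations undefined and
raise typed errors (`DegenerateImageError`, `UndefinedStatisticError`);
empty masks raise `NoCellError`; monotone correlation series raise
`AperiodicSignalError`; lost templates (score < 0.5), non-finite training
losses and out-of-range isovalues similarly raise dedicated exceptions
rather than returning sentinels.  Quantization uses half-open bins with the
top bin closed (a range midpoint maps to the upper label).  Ties in peak
finding break toward the earlier frame.  Images and volumes are normalized
to [0, 1] at creation; min-max normalized tensors attain both bounds for
any non-constant input.
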