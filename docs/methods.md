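# Methods

## Pipeline

The pipeline classifies two-class radiograph datasets in five stages:
dataset preparation, pyramidal patching, frozen-backbone feature
generation, iterative ReliefF feature selection, and cubic-SVM
cross-validation. Each stage is a pure function of its inputs and a seed; a
single master seed fans out to per-stage seeds through a `SeedSequence`, so
any stage can be re-run in isolation and a whole run is reproducible from
its config snapshot.

### Dataset preparation

Images are loaded from `root/<class>/*.{jpg,png}` in lexicographic path
order (fixing the fold assignment downstream) and resized to 512×512×3 by
bilinear interpolation. The resize stretches without preserving aspect
ratio: the target is a fixed square input and a documented deterministic
convention matters more here than geometric fidelity.

Class balancing generates augmented copies of originals until both classes
reach a target count, cycling over each class's originals and applying one
randomly drawn geometric op per copy: rotation (uniform in ±10°), isotropic
scaling (uniform in 0.9–1.1, center crop/pad back to frame) or horizontal
mirroring. One op per copy and these mild ranges are this package's choice
— the augmentations must not move an arch between classes, and a ±10°/±10%
perturbation of a lateral foot view does not. Every augmented record stores
its transform log, and the suite checks the log replays to the exact pixels.

### Pyramidal patching

A 512-square image becomes 21 images: itself, the 2×2 grid of 256-square
quadrants and the 4×4 grid of 128-square tiles, row-major within each
level, coarse-to-fine overall. Tiling is exact cropping: each level's
patches are pairwise disjoint and reassemble the original bit-exactly
(tested as a conservation and stitching property). The within-level order
is a convention only — it permutes feature columns without affecting
selection or classification — but it must be stable, and row-major is the
stable choice made here.

### Feature generation

Each pyramid image is resized to the backbone's native input side,
per-channel normalized, and forward-passed; the pre-softmax 1000-way class
score ("logits") vector is the feature block. Blocks are concatenated in
pyramid order, slot *i* occupying columns `i·d … (i+1)·d − 1`, giving
21·1000 = 21,000 columns for the standard backbones. Feeding 512/256/128
patches to a 224-input network by plain bilinear resize is standard
transfer-learning practice and keeps all 21 slots dimensionally uniform.

Backbones are a registry (`mobilenet_v2` default; alexnet, densenet201,
googlenet, vgg16, resnet50, squeezenet) loaded lazily through torchvision;
a missing runtime or missing weights raises an explicit load error rather
than ever falling back to random weights. The **stub extractor** — resize
to a 32-square grid, flatten, multiply by a seeded Gaussian projection
scaled by 1/√n_pixels — satisfies the same contract deterministically with
no weights, and is what the tests and the acceptance script use. It is a
linear map of pixels, so it preserves geometric class signal (phantom arch
height) while being far weaker than a CNN at texture; results obtained with
it validate the pipeline's mechanics, not medical-image performance.

### ReliefF and iterative selection

Features are min–max normalized per column; constant columns map to zero
(avoiding 0/0) and consequently receive weight exactly 0 and sort last
under the stable descending argsort. ReliefF then runs one update cycle
per instance in index order (m = n) rather than sampling m random
instances: determinism costs nothing at these n and removes a nuisance
source of variance. Neighbor search uses Manhattan distance (the sum of
per-feature diffs, the metric consistent with diff-based updating), with
distance ties broken by lower instance index. The per-feature diff is
|a − b| on normalized values — the standard continuous extension of the
0/1 discrete rule — and the miss terms are weighted by the empirical prior
ratio P(C)/(1 − P(class(R))). When a class has ≤ k members, k is clipped
per class with a warning and the 1/(m·k) scaling uses the clipped count.
On [0,1]-normalized data every weight lies in [−1, 1]; a perfect balanced
class-indicator feature attains exactly +1 (a closed-form identity the
acceptance script recomputes).

Iterative selection evaluates ranked prefixes of sizes step, 2·step, … up
to `max_prefix` with a cross-validated classifier loss and keeps the first
minimum (ties resolve to the smallest subset). `step=1` with the full
width sweeps every prefix — the reference procedure; the `step`/`max_prefix`
knobs exist because a full 21,000-prefix sweep re-fits the SVM tens of
thousands of times, and a coarse grid loses little at desk scale. The
selected column set is the ranked prefix, not a contiguous slice of the
original column order.

### Cubic SVM evaluation

Folds are stratified: per class, a seeded shuffle then round-robin deal, so
per-class fold sizes differ by at most one. Within each fold the training
data alone supplies the standardization statistics (zero-variance columns
standardize with divisor 1) and the kernel scale; held-out cases are
predicted exactly once and pooled into a single confusion matrix — the
single-matrix convention, not per-fold averaging.

The kernel is (1 + x·y/s²)³ with C = 1, implemented via scikit-learn's SVC
with `gamma = 1/s²`, `coef0 = 1`. The "auto" scale s is the median pairwise
Euclidean distance among up to 1000 seeded-subsampled standardized training
rows (fallback 1.0 when the median is 0). This heuristic is deterministic,
scale-adaptive, and duplication-covariant: duplicating every column doubles
both x·y and s², leaving the kernel — and hence the loss — unchanged, which
the suite checks directly.

Metrics: accuracy (TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN),
F1 the harmonic mean. The positive class is *normal* by convention
(configurable), so TP counts correctly classified normal images.
Zero-denominator precision/recall are defined as 0 with a warning.

## Synthetic data

**Phantoms** are geometric cartoons of a weight-bearing lateral foot view:
a dark noisy background (offset 18, Gaussian pixel noise SD 8 on the 0–255
scale), a bright two-segment "foot" polyline whose inferior arc angle is
the class variable, an ankle bar and a calcaneal blob. Default angle means
are 15° (flatfoot) vs 25° (normal) with SD 3°, straddling the 18° clinical
decision boundary for calcaneal inclination; draws are truncated to their
class's side of the 20° midpoint so a single angle threshold reproduces the
labels exactly, keeping the ground truth recoverable by construction.
Phantoms carry the pipeline's *shape and statistics* contracts; they have
no anatomy, no texture, no projection physics, and a pipeline that
classifies them perfectly has demonstrated its mechanics — not clinical
performance on real radiographs, which depends on the external dataset and
real backbone weights.

**Feature matrices** are n×D standard Gaussians with q informative columns
whose class means differ by a standardized shift δ (±δ/2 per class), the
informative positions a seeded permutation. They drive the selection tests:
recovery (q = 5 of D = 50 at δ = 2, n = 200: all informative columns rank in
the ReliefF top 10 in ≥95% of seeds), monotonicity of the ReliefF weight in
δ, and null calibration (δ = 0: pooled cubic-SVM CV accuracy within three
standard errors of 0.5 over 50 replicates).

## Numerical and design notes

- Resize of an already-target-size image returns the input unchanged;
  rotation by 0°, scaling by 1.0 and double mirroring are exact identities.
- The stable argsort everywhere (weights, neighbor ties) makes results
  invariant to instance permutation whenever all distances are distinct;
  with ties, the documented index rule applies.
- Desk-scale problem sizes throughout (40-case phantom runs, 200×50
  selection matrices, 50-replicate calibrations) were chosen as the
  package's own test conditions; the full-scale settings (1400 cases,
  21,000 features, step-1 sweep) remain available through the same flags.
- `run_grid` evaluates every backbone in both pyramidal (21-slot) and plain
  (original-image-only) modes, so the pyramidal-vs-plain accuracy gain is a
  single subtraction on its output table.

## Known limitations

- Real-backbone extraction requires torch/torchvision and pretrained
  weights (an optional extra); without them only the stub path runs.
- The darknet19 architecture has no torchvision port and is not provided.
- ReliefF here is the deterministic full-pass variant; a sampled-m run of
  the same data would produce slightly different weights.
- The phantom generator draws one fixed foot geometry with a variable arc
  angle; it does not model patient variation beyond that angle and pixel
  noise.
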