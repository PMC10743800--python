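# Methods

This note records the scientific and numerical choices behind `projage`: what
each stage computes, which conventions were fixed where several were
defensible, and what the synthetic phantoms can and cannot demonstrate.

## Input model

Inputs are gray-matter probability volumes (per-voxel likelihood that tissue
is gray matter, from tissue segmentation of skull-stripped T1-weighted MRI)
in native space — no registration, resampling or intensity normalization.
Values are clamped into [0, 1] on load; only non-finite voxels are rejected,
since slightly out-of-range values are a routine interpolation artifact while
NaN/Inf indicate corruption. Volumes are zero-padded symmetrically to a
common grid (default 256×256×208); an odd padding remainder puts the extra
plane on the high-index side. The convention is arbitrary but fixed, so
cached projections are bit-reproducible. Axis labels (sagittal, coronal,
transversal) are attached to storage axes 0/1/2 by configuration rather than
inferred from NIfTI orientation metadata: the method operates on raw grid
axes, and unregistered native-space volumes carry no guarantee that header
orientations are consistent across a cohort.

Recorded ages are whole years. For a continuous age uniform over any span of
whole years, |age − round(age)| is uniform on [0, 0.5], so even a perfect
predictor of true age scores MAE 0.25 years against the labels. This floor is
verified in the acceptance tests and is the right reference point when
judging residual error.

## Moment maps

For collapse axis a and orders k = 1..4:

* k=1, k=2: mean and population standard deviation over the **full** line,
  including outside-brain zeros. The population (divide-by-n) form of the SD
  was fixed for cache reproducibility; with lines of 208+ voxels the
  distinction from the sample form is far below the noise floor of any
  downstream model.
* k=3, k=4: standardized central moments over the **support hull** only —
  the first through last nonzero voxel. μ₁ inside the standardized-moment
  formula is the hull mean (the sums run over i = α..ω, so the consistent
  choice is the mean over the same range). Interior zeros within the hull are
  included in the sums. k=4 subtracts 3, reporting excess kurtosis.

Degenerate contracts: all-zero lines, hulls shorter than 8 voxels, and
zero-variance hulls return exactly 0 rather than NaN — short or constant
hulls make the ratio numerically unstable or undefined, and 0 is a neutral
value for a batch-normalized network. The vectorized implementation is tested
against a naive per-line oracle to 1e-10, and property tests cover
shift/scale/permutation invariance of the standardized moments.

No normalization is applied to the moment images before the CNN; the
network's batch-normalization layers absorb channel scale.

## Eigenslices

The slice stack along one axis, flattened column-wise into M (row-major
raster per slice), is decomposed through the Gram matrix MᵀM — never the
large MMᵀ. Choices the underlying algebra leaves open:

* **No mean-centering** of slices: the decomposition acts on raw data, so the
  first eigenslice resembles a weighted average slice rather than a
  deviation pattern.
* **Normalization:** eigenslices are M vᵢ/√λᵢ, unit Euclidean norm, with λᵢ
  kept as metadata. Unit norm makes channel magnitudes comparable across
  subjects; batch norm removes any residual scale.
* **Sign:** eigenvectors are sign-ambiguous; the element of largest absolute
  value is made positive (ties: first such element). Fixed for deterministic
  caches and tests.
* **Rank tolerance:** λ below 1e-10 × λ₁ counts as zero. Requested
  eigenslices beyond the numerical rank are zero images, not errors, because
  boundary zero-slices routinely reduce rank.
* **Ties:** exactly degenerate eigenvalues leave the spanning eigenvectors
  solver-dependent; the stable descending sort preserves the symmetric
  eigensolver's order. Cross-subject correspondence of higher eigenslices is
  inherently fragile for exactly this reason (eigenvalues crowd together as
  the index grows), which is a known limitation of the representation.

Tests verify the Gram-trick equivalence against an explicitly formed MMᵀ
eigendecomposition, Σλᵢ = ‖M‖²_F, orthonormality above rank, and that the
top-k eigenslices capture at least as much variance as 100 random
orthonormal rank-k bases.

## The regression network

Three independent 2D convolutional stacks (one per axis) with identical
structure and separate weights. Each of the six units is
`conv(3×3, stride 2, doubles features) → ReLU → conv(3×3, stride 1) →
batch norm → ReLU → dropout`, progressing 4→8→16→32→64→128 features. Spatial
halving uses ceiling semantics, so 256→4 and 208→4 after six units. A capping
convolution spanning the remaining 4×4 extent maps 128 features to a
156-dimensional vector per stack; the concatenated 468 features pass through
a dense head 468 → 256 → 166 → 1 (ReLU between layers).

The capping width (156) and head widths (256, 166) are this package's own
resolution of the architecture's least-constrained region: they were chosen,
together with biases on every convolution and dense layer and affine batch
norm, so that the trainable parameter count is exactly 2,009,261 at one
channel per axis, 2,009,369 at two, 2,009,585 at four — with the structurally
forced slope of 108 parameters per added channel (3 stacks × 4 first-layer
filters × 3×3 kernel) — and 8,037,476 for a four-member two-channel ensemble.
Within those anchors several head shapes are arithmetically possible; this
one keeps a conventional monotonically narrowing head. Batch-norm running
statistics are buffers, excluded from the count. The activation is ReLU and
the default dropout rate 0.2; neither affects parameter counts.

A `reduced` variant (4 units, cap width 16, head 48 → 32 → 1) serves
desk-scale phantom experiments (64×64 and 64×52 inputs also reach 4×4 after
four halvings). The parameter-count anchors apply only to the `full` variant.

The whole network is implemented in NumPy (im2col convolutions, manual
backpropagation) and gradient-checked against central finite differences in
the tests; no GPU, no autodiff framework.

### Training

Adam with learning rate 0.003, batch size 32, a fixed epoch budget (default
400, overridable), and model selection by minimal validation MAE over epochs
(early stopping without interruption). Mean square error is the default
loss; mean absolute error is available but non-default. Targets are
standardized to zero mean and unit SD over the training fold during
optimization and inverted at prediction; the transform is stored in the
checkpoint. This keeps the optimizer's first steps centered on the cohort's
age range instead of spending epochs traversing a ~60-year offset, which
matters at small epoch budgets and is neutral at large ones. It is exposed as
`standardize_targets` and can be disabled.

Ensembles aggregate by the unweighted mean of member predictions, which by
convexity can never have a higher MAE than the mean of its members' MAEs.

### Splits

Test and validation sizes are floor(0.15·N); training takes the remainder
(the only rounding convention consistent with 20,325 training subjects out of
29,035). The three folds draw disjoint validation blocks of size floor(0.15·N)
from the combined train+validation pool via a seeded permutation; the test
set is shared across folds. Repeated trainings within one grid configuration
differ by initialization and batch-order seed on fold 0.

### Caching

Projection channels are computed once per subject and stored in one `.npz`
container keyed by channel name (`moment_k{k}_{axis}`, `eigen_{i}_{axis}`),
with a JSON sidecar recording a hash of the generation parameters. Any
parameter change (grid, channel definitions, sign convention) invalidates the
whole subject entry atomically; entries are then regenerated on demand.

## Synthetic phantoms

The phantom generator provides a fully synthetic stand-in for gray-matter
volumes so the pipeline is testable end to end. Each subject is an ellipsoid
brain mask (semi-axes 0.42/0.45/0.42 of the grid) whose center is jittered by
up to ±5% of the grid per subject, emulating unregistered native-space
variation. Age drives three linear effects, all expressed per year beyond the
minimum age (45):

| parameter | default | meaning |
| --- | --- | --- |
| grid | 64×64×52 | 1:4 scaling of the full 256×256×208 grid |
| age range | 45–80 y | uniform sampling, biobank-like span |
| shell thickness | 4.0 vox − 0.03/y | cortical gray-matter shell |
| cortex likelihood | 0.85 − 0.004/y | shell intensity |
| ventricle radius | 0.18 + 0.006/y (of brain radius) | central zero region |
| white-matter likelihood | 0.15 | constant interior |
| deep-gray blobs | 0.6, fixed geometry | 4 ellipsoidal blobs |
| noise | SD 0.05, smoothed at 1 voxel | additive Gaussian, then clamped |

With noise off, total gray matter is strictly decreasing in age (intensity
decline is continuous and strict; thinning and ventricle growth reinforce
it), and the summed mean-projection correlates with age at |r| > 0.95 — the
floor a downstream model needs. Recorded ages are rounded to the nearest
year, reproducing the 0.25-year floor.

What the phantoms do **not** emulate: cortical folding and any realistic
anatomy, tissue-segmentation artifacts, scanner and site effects, disease,
and — critically — the weak, heterogeneous coupling between age and structure
in real brains. Passing the phantom-recovery tests shows the pipeline is
wired correctly and can extract a monotone structural signal; it says nothing
about attainable accuracy on real cohorts, where MAEs in the 3–4-year range
are typical for this model family.

## Desk-scale study conditions

The acceptance-level phantom experiment uses 200 subjects at the default
conditions above (seed 7), split 140/30/30, reduced-scale models trained for
30 epochs — sizes at which one model trains in under a minute on one CPU. The
criteria are deliberately coarse (beat half of the constant-predictor MAE;
ensemble no worse than its members' mean + 0.1 y) because stochastic training
at this scale varies across members; observed margins are much wider.

## Known limitations

* The full-scale model is instantiable and parameter-exact but not trainable
  in reasonable time on CPU; training-path tests run the reduced variant.
* Eigenslice correspondence across subjects degrades with index (eigenvalue
  crowding); no reordering is attempted.
* The NumPy engine is single-device and deterministic given seeds, but
  determinism across BLAS builds is not guaranteed to the last bit.
* Group-level PCA (eigenvolumes, shared bases across subjects) is out of
  scope.
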