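# Methods

## Problem and decision model

Given a training set of co-registered 3D volumes and a synthetic set on the
same grid, the task is to decide per synthetic volume x̂ whether it is a
replica of some training volume. The decision variable is, at the image and
feature levels, the distance ratio

r(x̂) = d(x̂, x₁) / E_{y ∈ S_x̂}[d(x̂, y)],

with x₁ the closest training volume under the chosen measure and S_x̂ the
n closest training volumes. The ratio normalizes the rank-1 distance by the
local neighborhood scale, so it is insensitive to global intensity scaling
(for homogeneous measures such as MAE/RMSE the scale factor cancels
exactly) and to how "busy" a dataset region is. S_x̂ **includes** the
rank-1 volume itself; this choice guarantees r ∈ [0, 1] and therefore a
bounded threshold grid. `distance_ratio(..., include_rank1=False)` switches
to averaging over ranks 2..n+1, which can exceed 1 and is provided for
comparison only — all calibration defaults assume the bounded convention.

At the segmentation level the absolute converted value of the closest
match is used instead of the ratio: the segmentation mask already isolates
the anatomy of interest and discards background, so neighborhood
normalization adds nothing and an absolute tolerance (e.g. "flag if the
converted Dice distance is below 0.1") is directly interpretable.

The replica decision is strict: value < T → replica, value ≥ T →
non-replica. Boundary values are non-replicas.

### Degenerate cases

* All n neighborhood distances zero (every neighbor is an exact copy):
  r is defined as 0 with a `degenerate_flag` — maximal evidence of
  replication, not an error.
* n larger than the training set: capped at the training-set size with a
  warning, so small studies run.
* Ties in the ranking are broken lexicographically by training id, making
  every ranking deterministic.

## Measures and conventions

* **MAE / RMSE** — voxel-wise, over the full grid.
* **3D SSIM** — uniform (boxcar) window of side 7 (configurable, odd,
  must fit every axis), stabilizers k1 = 0.01, k2 = 0.03, data range =
  joint max−min of the pair, sample (N−1) normalization for local
  variances, mean over windows fully inside the grid. These are the most
  common published SSIM conventions; they are explicit because SSIM values
  are only comparable under fixed conventions.
* **Feature RMSE / cosine** — on fixed-length vectors; cosine returns the
  raw similarity in [−1, 1] and is converted downstream.
* **Dice** — per label; doubly-empty = 1 (agreement on absence), flagged.
* **ASD** — symmetric mean of the two directed mean surface distances.
  Surface voxels are foreground voxels with at least one 6-connected
  background neighbor; the volume border counts as background. Distances
  are exact Euclidean in physical units (voxel offsets scaled per axis by
  spacing), computed via the exact Euclidean distance transform. A label
  present in exactly one mask yields the image physical diagonal as a
  flagged penalty; absent from both yields a flagged 0.
* **Multiclass aggregation** — macro-average over labels present in at
  least one mask; labels absent from both are skipped; per-label flags are
  carried through so users can re-aggregate from the per-label values.

### Similarity → distance conversion

Similarities are min-max mapped from their **theoretical** range onto
[0, 1] and subtracted from 1: dice → 1−v, ssim and cosine →
1−(v+1)/2. Batch-empirical normalization is deliberately avoided: it would
make thresholds non-transferable between runs, defeating automation.
Values outside the theoretical range by ≤ 1e-9 are clamped; larger
violations raise.

## Threshold calibration

The sweep evaluates T on a regular grid: [0, 1] in `step` (default 0.01)
increments for ratios and converted similarities; [0, max observed] in
`step`·max increments for unconverted absolute variables (ASD in mm),
the only reading of "increments relative to the value of the measure" that
yields a finite grid for unbounded distances. The grid interpretation is
echoed in the calibration output. The optimum maximizes balanced accuracy
(replica = positive class); ties resolve to the smallest threshold —
deterministic and conservative (fewer flags at equal accuracy).

The margin (automation) threshold is the mean of the highest replica and
the lowest non-replica value, emitted with a separability flag; when the
classes overlap the midpoint is still returned but no threshold is perfect.

Ground truth comes either as explicit labels or as two raters' 4-point
scores with 3–4 meaning replica; rater disagreement requires an explicit
adjudicated column — silent majority rules are refused because a 2-rater
majority does not exist.

## Feature extraction

The framework treats extractors as opaque: any callable producing a fixed
length vector per volume can be registered, and precomputed embeddings
(e.g. from a pretrained medical foundation model) can be supplied as CSV
through the manifest. The built-in pooled descriptor min-max scales each
volume to [0, 1], partitions it into 2^ℓ blocks per axis for pyramid
levels ℓ = 1..L (boundary blocks absorb remainders; default L = 2, length
144), and concatenates per-block mean and standard deviation. It is
deterministic, weight-free, and sensitive to both intensity and coarse
spatial structure — sufficient for the pipeline's logic, but it is a
summary statistic, not a learned representation: it will not capture the
abstract anatomical similarity a foundation-model embedding can.

## Synthetic studies

The simulator emulates the structure the pipeline consumes: small
co-registered volume sets with smooth anatomy-like background (Gaussian
filtered noise, σ = 2 voxels, mapped to intensity range [0.1, 0.6]) plus
1–3 disjoint hyperintense ellipsoidal lesions (semi-axes 2–4 voxels,
contrast +0.4) and paired masks, on a default 32×32×16 grid with 1 mm
spacing. Default study shape is 40 training / 50 synthetic volumes with 90%
planted replicas, matching a realistic screening batch where most generated
images turn out to be copies. Perturbation kinds for planted copies:
`none` (exact copy), `gaussian_noise` (additive, σ in intensity units on
the nominal [0, 1] scale), `intensity_shift` (constant offset),
`translation` (integral voxel shift; shifted-out voxels are cropped,
vacated voxels take the background floor — registration-jitter-like, no
wraparound; masks move with the volume, intensity perturbations leave
masks untouched). Every planted copy is labelled replica regardless of
magnitude; the magnitudes used in the test suite (σ ≤ 0.2) keep copies
well within what a rater would call a replica.

Reproducibility is hierarchical: one study seed derives per-subject and
per-lesion seeds through `numpy` seed sequences with fixed spawn keys, so
(params, seed) determines every byte and individual subjects are stable
when the study size changes.

What the phantoms do **not** emulate: scanner physics and noise spectra,
real anatomy and its inter-subject correlation structure, generative-model
artifacts, imperfect registration, and segmentation-model errors (masks
are exact by construction). Passing the planted-replica suites therefore
demonstrates the pipeline's logic — ranking, ratio, calibration, decision
— not field performance on patient data, where class overlap is governed
by the generator and the anatomy.

## Problem sizes and numerical choices

The test and acceptance runs use 32×32×16 phantoms, 40–50 volume studies,
and 10 seeds per condition in the graded-difficulty analysis — small
enough to run interactively while leaving the class geometry (exact copies
at ratio 0, novel volumes near ratio 0.85) unambiguous. Oracle-agreement
tests run on ≤(8, 8, 4) grids where brute-force loops are exact
references: 1e-12 for arithmetic measures, 1e-9 for SSIM and surface
distances (accumulated floating-point in the transforms).

Grids must match exactly in shape and in spacing to 1e-6 mm; mismatches
are refused rather than resampled — resampling is preprocessing and out of
scope, as are registration, intensity normalization, and training of
generative or segmentation models. Inputs are assumed comparably
intensity-scaled; the ratio's scale invariance softens but does not remove
this assumption for MAE/RMSE, and SSIM/features are computed on per-pair
or per-volume normalized scales.

## Known limitations

* Image-level analysis is O(n_train · n_synth) volume comparisons; the
  distance-matrix CSV cache lets large runs resume, but feature-level
  analysis is the practical choice at scale.
* The framework does not model augmentation-invariant replication: a copy
  that the generative model rotated or flipped will not sit at rank 1
  under voxel-wise measures.
* The margin threshold is calibrated on a scored subset and assumes the
  larger batch is exchangeable with it.
* Approximate nearest-neighbor indexing, ROC/AUC analysis, and perceptual
  or learned similarity measures are intentionally out of scope.
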