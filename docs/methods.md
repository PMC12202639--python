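# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Pressure metrics

All surface statistics run over *contact cells*: cells whose pressure is
strictly above a configurable threshold (default 0 kPa, matching the
"non-zero units" convention of mat software; a sensor noise floor can be
passed instead). The average pressure is the mean over contact cells, not
over the whole pad — averaging over all cells would make the uniformity
index depend on pad size rather than on the load distribution.

The seat-pressure-distribution uniformity index is

SPD = Σᵢ (pᵢ − p̄)² / (4 n p̄²), i over the n contact cells.

It is dimensionless, non-negative, zero exactly when all contact pressures
are equal, and invariant under uniform pressure scaling (both properties
are tested). Contact area is n × (cell pitch area); pressure histograms
use half-open bins [k·w, (k+1)·w) with w = 4 kPa by default, so counts
always sum to n and bin membership at the boundary is unambiguous.

Region segmentation is row-based with row 0 at the top of the mat as
exported (orientation is metadata, not semantics — every metric is
orientation-invariant). Backrest maps split at the projection row of the
superior endplate of L1: rows 0..l1_row form the back, rows below form the
waist. Cushion maps split at a user-chosen row: rows above it are hip,
rows from it downward are legs; no default is claimed because the division
depends on mat placement and sitter anthropometry. Degenerate splits
(empty region) are allowed with a warning rather than rejected, since they
arise legitimately at sweep extremes.

Comfort classification compares a region's peak pressure with a closed
ideal interval: buttocks (hip) 7–11 kPa, lower back (waist) 4–8 kPa by
default, both configurable. Closed bounds were chosen because published
ranges are quoted without boundary semantics and an inclusive reading is
the weaker assumption.

## Spinal angles

CC, TTK and LL are Cobb angles between two endplate lines after orthogonal
projection onto the sagittal plane. Default lines (configurable): CC =
inferior C2 vs inferior C7; TTK = superior T1 vs inferior T12; LL =
superior L1 vs superior S1 — standard radiographic conventions. The
sagittal plane defaults to the least-squares plane of all endplate corner
points; the in-plane frame (anterior, up) is derived from the data itself
(cranio-caudal chain direction and mean posterior→anterior endplate
direction), which makes every angle invariant under rigid motion and
uniform scaling of the whole landmark set (tested to 1e-9°).

Signs are oriented so anatomically normal lordosis and kyphosis are all
positive, and negating the sagittal curvature of the whole spine flips all
three signs. Coincident endplate corners raise a degenerate-geometry error
rather than returning an arbitrary direction.

Measurement noise propagates through the short endplate lever arms: with
~32 mm endplate depth, 0.5 mm Gaussian landmark jitter produces ≈1.8° mean
absolute angle error. The stochastic tests therefore check unbiasedness
and that scale of error; only noise-free recovery is exact.

## Mean shape (generalized Procrustes)

Correspondence: the base cloud is warped by the landmark-driven RBF field
(shared anatomical landmarks), then each warped point snaps to its nearest
neighbour on the target (Euclidean; deterministic kd-tree). Alignment:
both clouds are centered, and the proper rotation minimising the Frobenius
objective comes from the SVD of the cross-covariance with the determinant
sign corrected to +1 — reflections are excluded because a body must never
be mirrored, and translation removal is the standard preprocessing even
though scanner frames could in principle agree. No similarity scaling is
fitted: absolute anthropometric size is the quantity of interest.

The mean iterates align-to-mean / re-average; both half-steps are exact
coordinate-descent minimisers, so the objective trace is non-increasing
(asserted on every run). Convergence: relative objective change < 1e-6,
max 100 iterations, warning on non-convergence. Rank-deficient
cross-covariances are resolved deterministically (flip the axis of the
smallest singular value) and flagged. The mean is reported in the base
cloud's frame.

## Morphing (thin-plate spline + affine drift)

The deformation field is the universal-Kriging-with-linear-trend
interpolant: an RBF expansion (thin-plate φ(r) = r² log r by default, or a
Gaussian with explicit width) plus a full affine polynomial, solved as the
symmetric bordered system with the side condition Pᵀw = 0. That side
condition guarantees affine reproduction: any globally affine
control→target configuration yields a globally affine field, so pure
scalings of a template reproduce the closed-form scaled template. With
zero regularization (the default) the field interpolates every target
exactly; a regularization parameter trades exactness for smoothness on
noisy landmark sets. Coordinates are centered and scale-normalised before
the solve for conditioning; a warning is emitted when the system condition
estimate still exceeds 1e12 and a least-squares fallback handles outright
singularity. Duplicate or coplanar control sets are rejected with the
offending names. No equivalence with any specific commercial morphing
tool's covariance settings is claimed.

## Foam model and identification

Loading follows the tabulated monotone engineering stress–strain curve
(piecewise-linear; queries beyond the last knot raise rather than
extrapolate, because foam tails steepen sharply). Unloading from ε_max is

σ_unload(ε) = σ_load(ε) · [HU + (1 − HU) (W(ε)/W(ε_max))^SHAPE],

with W the exact piecewise-quadratic integral of the loading curve. The
form is continuous at the reversal point, degenerates to no hysteresis at
HU = 1, and keeps σ_unload ≤ σ_load pointwise for HU ≤ 1. It is a
documented phenomenological stand-in for solver-internal hysteretic
unloading laws that use the same (HU, SHAPE, BETA) parameterisation;
equivalence with any commercial material model is not claimed. BETA
(creep/rate decay) is stored but excluded from the quasi-static fit, and
tension and compression are treated as separate curves.

Identification is bounded nonlinear least squares on the unloading-branch
residuals over (HU, SHAPE), HU ∈ [1e-4, 1], SHAPE ∈ [1e-2, 10], with 8
multi-starts (one deterministic midpoint start plus seeded uniform/log
draws). Noise-free recovery is exact to optimizer tolerance; with 2%-of-
peak Gaussian noise the mean relative error over 20 replicates is ~4%,
dominated by SHAPE, which is weakly identified near zero strain where the
unloading stress itself vanishes.

## Synthetic data

The generators emulate the *statistical structure* of the study
instruments, not their mechanics:

- **Pressure maps**: sums of isotropic exponential-decay bumps (heavier
  tails than Gaussians, closer to mat data) clipped to an elliptical
  contact patch, plus truncated-at-zero Gaussian sensor noise. Cushion
  defaults place two bumps at the ischial loci with amplitudes normalised
  for bump overlap so the rendered maximum equals the nominal 9.5 kPa —
  inside the 7–11 kPa ideal window; backrest defaults place one mid-waist
  bump at 6 kPa. Default grids are 32×32 (cushion) and 40×32 (backrest)
  at 10×10 mm pitch — mat resolution is hardware-specific, so pitch is
  always explicit metadata.
- **Spines**: chains of parallel-endplate vertebral quadrilaterals whose
  per-region linear tilt ramps realise the requested (CC, TTK, LL)
  exactly; nominal body heights 13/20/27 mm (cervical/thoracic/lumbar),
  32 mm depth, 5 mm disc gaps. Consecutive tilt jumps beyond 45° are
  rejected as interpenetrating geometry.
- **Body clouds**: template + per-subject smooth RBF warps whose anchor
  displacements are recentred to zero mean across subjects (so the
  template is the exact pre-rotation mean — required for a well-posed
  recovery experiment), then a random rotation bounded by rot_amp and
  isotropic Gaussian noise. Defaults (4 subjects, 10 mm deformation, ≤20°
  rotation, 1 mm noise) represent a small scanned cohort.
- **Condition series**: 5 whole-chair angles (0–40°) or 4 backrest angles
  (−10–20°); recline moves amplitude from the cushion bumps to the
  backrest bump, and internal responses follow configurable linear or
  U-shaped effect models plus noise.

Every generator is a pure function of its arguments including the seed.
Passing tests on these inputs demonstrates correctness of the *computations*
(metrics, alignment, angle and parameter recovery) under controlled ground
truth; it does not validate biomechanical realism — real mats have sensor
crosstalk and calibration drift, real spines have wedged vertebrae, and
real pressure fields are not sums of isotropic bumps.

## Reports

Condition reports are validated against a pydantic schema before writing
and serialised with sorted keys and 10-significant-digit float formatting,
so reruns on identical inputs are byte-identical. Percent deviation uses
the experimental value as denominator (100·|sim − exp|/|exp|). Trend
correspondence uses Spearman rank correlation (ties mid-ranked) because
the scientific claim is "moves together", not linear proportionality; a
Pearson option is exposed. Constant series raise an explicit error rather
than returning NaN. Histogram comparison reports per-bin absolute
differences plus total-variation distance on the normalised counts.

## Problem sizes

Default test and acceptance workloads: 100 random pressure grids (up to
20×20), 20 Procrustes pairs of 50 points against 10⁴ Monte-Carlo
rotations, 642-vertex torso templates with 24 landmarks for averaging and
morphing, the 27-point spinal angle grid, and 20 noisy foam replicates —
sizes at which every property is exercised while the full suite runs in
seconds.

## Known limitations

- No contact mechanics: pressure maps are inputs or synthetic; the package
  never simulates body–seat deformation, and internal responses
  (vertebral/disc stress, strain) are consumed as external tables only.
- The foam model is 1-D and quasi-static (no rate effects, no 3-D stress
  states).
- Correspondence assumes landmarks capture the dominant shape variation;
  nearest-neighbour snapping cannot recover features between sample
  points.
- Comfort classification thresholds are population-level heuristics, not
  subject-specific predictions.
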