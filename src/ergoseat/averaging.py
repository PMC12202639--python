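"""Mean body-shape construction from homologous surface point clouds.

The pipeline mirrors how representative (e.g. 50th-percentile) body
surfaces are built from a handful of scanned subjects:

1. ``correspond`` — bring each target scan into point-to-point
   correspondence with a base scan: warp the base cloud by the
   landmark-driven RBF field (shared anatomical landmarks on both scans),
   then snap each warped base point to its nearest neighbour on the
   target. The result has the base's point count and ordering.
2. ``orthogonal_align`` — rigid (proper-rotation) Procrustes alignment of
   one corresponded cloud to a reference, solved in closed form from the
   SVD of the cross-covariance with determinant sign correction so bodies
   are never mirrored. No scaling: absolute anthropometric size is the
   quantity of interest.
3. ``mean_shape`` — generalized Procrustes iteration: align every cloud
   to the current mean, re-average point-wise, repeat until the summed
   squared alignment objective stops improving. Both half-steps are exact
   coordinate-descent minimizers, so the objective trace is non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .morphing import build_field
from .types import DegenerateGeometryError, InvariantError, LandmarkSet, PointCloud

__all__ = ["CorrespondedSet", "AlignmentResult", "correspond",
           "orthogonal_align", "mean_shape"]


@dataclass(frozen=True)
class CorrespondedSet:
    """Base cloud plus targets re-sampled to the base's topology."""

    base: PointCloud
    targets: tuple[PointCloud, ...]

    def __post_init__(self):
        targets = tuple(self.targets)
        for i, t in enumerate(targets):
            if len(t) != len(self.base):
                raise InvariantError(
                    f"target {i} has {len(t)} points, base has {len(self.base)}"
                )
        object.__setattr__(self, "targets", targets)

    @property
    def clouds(self) -> tuple[PointCloud, ...]:
        return (self.base,) + self.targets


@dataclass(frozen=True)
class AlignmentResult:
    """Output of the generalized Procrustes iteration."""

    rotations: tuple[np.ndarray, ...]
    translations: tuple[np.ndarray, ...]
    mean_shape: PointCloud
    objective_trace: tuple[float, ...]
    converged: bool


def correspond(base: PointCloud, base_lm: LandmarkSet,
               target: PointCloud, target_lm: LandmarkSet,
               kernel: str = "thin_plate", width: float = 1.0,
               regularization: float = 0.0) -> PointCloud:
    """Re-sample ``target`` into one-to-one correspondence with ``base``.

    The base cloud is warped by the RBF field taking the base landmarks to
    the target landmarks; each warped point is then replaced by its
    nearest neighbour on the target surface (Euclidean metric, ties broken
    toward the lowest target index).
    """
    field = build_field(base_lm, target_lm, kernel=kernel, width=width,
                        regularization=regularization)
    warped = field(base.points)
    tree = cKDTree(target.points)
    _, idx = tree.query(warped, k=1)
    return PointCloud(target.points[idx], base.faces)


def orthogonal_align(x: PointCloud | np.ndarray,
                     xbar: PointCloud | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ‖(X·R + t) − X̄‖_F.

    Both clouds are centered first; the rotation comes from the SVD of the
    centered cross-covariance with the determinant sign corrected to +1
    (reflections excluded — a body must not be mirrored). Rank-deficient
    cross-covariances (with genuinely ambiguous optimum) are resolved
    deterministically by flipping the axis of the smallest singular value
    and flagged with a warning.
    """
    xp = np.asarray(x.points if isinstance(x, PointCloud) else x, dtype=float)
    bp = np.asarray(xbar.points if isinstance(xbar, PointCloud) else xbar, dtype=float)
    if xp.shape != bp.shape:
        raise InvariantError(f"point counts differ: {xp.shape} vs {bp.shape}")
    if len(xp) < 3:
        raise DegenerateGeometryError("need at least 3 points for rigid alignment")
    cx, cb = xp.mean(axis=0), bp.mean(axis=0)
    xc, bc = xp - cx, bp - cb
    m = xc.T @ bc
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    if s[-1] < 1e-12 * max(s[0], 1.0):
        warnings.warn("rank-deficient cross-covariance: rotation about the "
                      "degenerate axis is ambiguous; smallest-singular-axis "
                      "tie-break applied", stacklevel=2)
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    t = cb - cx @ r
    return r, t


def _objective(aligned: list[np.ndarray], mean: np.ndarray) -> float:
    return float(sum(np.sum((a - mean) ** 2) for a in aligned))


def mean_shape(corresponded: CorrespondedSet, tol: float = 1e-6,
               max_iter: int = 100) -> AlignmentResult:
    """Generalized Procrustes mean of corresponded clouds.

    Iterates alignment-to-mean and point-wise re-averaging until the
    relative change of Σ_g ‖X_g R_g + t_g − X̄‖²_F drops below ``tol``.
    The mean is reported in the base cloud's frame (the iteration starts
    from the base and never re-poses the mean). Deterministic; no
    randomness involved.
    """
    clouds = [np.asarray(c.points, dtype=float) for c in corresponded.clouds]
    if len(clouds) < 2:
        raise InvariantError("need at least 2 clouds to average")
    mean = clouds[0].copy()
    trace: list[float] = []
    converged = False
    rotations: list[np.ndarray] = [np.eye(3)] * len(clouds)
    translations: list[np.ndarray] = [np.zeros(3)] * len(clouds)
    for _ in range(max_iter):
        rotations, translations, aligned = [], [], []
        for c in clouds:
            r, t = orthogonal_align(c, mean)
            rotations.append(r)
            translations.append(t)
            aligned.append(c @ r + t)
        mean = np.mean(aligned, axis=0)
        obj = _objective(aligned, mean)
        trace.append(obj)
        if obj == 0.0:
            converged = True
            break
        if len(trace) >= 2:
            prev = trace[-2]
            if (prev - obj) / max(prev, 1e-300) < tol:
                converged = True
                break
    if not converged:
        warnings.warn(f"mean shape did not converge in {max_iter} iterations",
                      stacklevel=2)
    return AlignmentResult(
        rotations=tuple(rotations),
        translations=tuple(translations),
        mean_shape=PointCloud(mean, corresponded.base.faces),
        objective_trace=tuple(trace),
        converged=converged,
    )
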