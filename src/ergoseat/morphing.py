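"""Landmark-driven smooth mesh deformation.

A deformation field is built from paired control → target landmarks as a
radial-basis interpolant with a first-degree polynomial (affine) drift —
the interpolant of universal Kriging with a linear trend. With zero
regularization the field reproduces every target exactly at its control
point, and any globally affine control→target configuration yields a
globally affine field (polynomial reproduction). The field is then applied
to every vertex of a template mesh; connectivity is untouched.

Kernels: ``thin_plate`` φ(r) = r² log r (default) and ``gaussian`` with a
width parameter. The system solved is the symmetric bordered system

    [ K + λI  P ] [w]   [t]
    [ Pᵀ      0 ] [a] = [0]

where K is the kernel matrix, P = [1 | controls], λ the regularization,
w the per-control 3-vector weights and a the 4×3 affine coefficients. The
side condition Pᵀw = 0 removes the affine nullspace and guarantees affine
reproduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import DegenerateGeometryError, InvariantError, LandmarkSet, PointCloud

__all__ = ["DeformationField", "build_field", "apply_field", "symmetry_check"]


def _kernel_matrix(a: np.ndarray, b: np.ndarray, kernel: str, width: float) -> np.ndarray:
    r = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    if kernel == "thin_plate":
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out
    if kernel == "gaussian":
        return np.exp(-((r / width) ** 2))
    raise InvariantError(f"unknown kernel {kernel!r} (use 'thin_plate' or 'gaussian')")


@dataclass(frozen=True)
class DeformationField:
    """RBF + affine deformation field taking control points to targets.

    The system is solved in centered, scale-normalized coordinates
    (``center``, ``scale``) for numerical conditioning; ``rbf_weights``
    and ``affine_part`` refer to that normalized frame, evaluation is in
    the original mm frame.
    """

    kernel: str
    width: float
    control_points: LandmarkSet
    rbf_weights: np.ndarray   # (n, 3)
    affine_part: np.ndarray   # (4, 3): row 0 = translation, rows 1..3 = linear
    center: np.ndarray
    scale: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = (pts - self.center) / self.scale
        cn = (self.control_points.coords - self.center) / self.scale
        k = _kernel_matrix(q, cn, self.kernel, self.width)
        poly = np.hstack([np.ones((len(q), 1)), q])
        return k @ self.rbf_weights + poly @ self.affine_part


def build_field(controls: LandmarkSet, targets: LandmarkSet,
                kernel: str = "thin_plate", width: float = 1.0,
                regularization: float = 0.0) -> DeformationField:
    """Solve for the deformation field mapping ``controls`` onto ``targets``.

    Control and target sets must share names. ``regularization`` ≥ 0 trades
    exactness at the controls for smoothness on noisy landmark sets
    (0 = exact interpolation).
    """
    if set(controls.names) != set(targets.names):
        raise InvariantError("control and target landmark names differ")
    if regularization < 0:
        raise InvariantError("regularization must be >= 0")
    tgt = targets.subset(controls.names)
    c = controls.coords
    t = tgt.coords
    n = len(c)
    if n < 4:
        raise DegenerateGeometryError("need at least 4 control points for a 3-D field")
    # duplicate controls make the interpolation system singular
    d2 = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    dup = np.argwhere(d2[iu] < 1e-12)
    if dup.size:
        pairs = [(controls.names[iu[0][i]], controls.names[iu[1][i]]) for i in dup.ravel()]
        raise DegenerateGeometryError(f"duplicate control points: {pairs}")
    # coplanar controls cannot pin down the affine drift
    if np.linalg.matrix_rank(c - c.mean(axis=0), tol=1e-9 * max(1.0, np.abs(c).max())) < 3:
        raise DegenerateGeometryError("control points are coplanar; affine drift is ill-posed")

    center = c.mean(axis=0)
    scale = float(np.mean(np.linalg.norm(c - center, axis=1))) or 1.0
    cn = (c - center) / scale
    kmat = _kernel_matrix(cn, cn, kernel, width) + regularization * np.eye(n)
    p = np.hstack([np.ones((n, 1)), cn])
    sys = np.zeros((n + 4, n + 4))
    sys[:n, :n] = kmat
    sys[:n, n:] = p
    sys[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = t
    try:
        cond = np.linalg.cond(sys)
        if cond > 1e12:
            warnings.warn(f"morphing system poorly conditioned (cond ~ {cond:.2e})",
                          stacklevel=2)
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(sys, rhs, rcond=None)  # pivoting fallback
    return DeformationField(kernel=kernel, width=float(width),
                            control_points=controls,
                            rbf_weights=sol[:n], affine_part=sol[n:],
                            center=center, scale=scale)


def apply_field(mesh: PointCloud, field: DeformationField) -> PointCloud:
    """Map every vertex through the field; faces are unchanged."""
    return mesh.with_points(field(mesh.points))


def symmetry_check(lm: LandmarkSet, pairing: dict[str, str],
                   plane_point: np.ndarray | None = None,
                   plane_normal: np.ndarray = (1.0, 0.0, 0.0)) -> float:
    """Worst left/right mismatch (mm) of a mirror-paired landmark set.

    ``pairing`` maps each landmark to its contralateral partner (midline
    landmarks pair with themselves). Each point is compared with the
    reflection of its partner through the sagittal plane.
    """
    normal = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise DegenerateGeometryError("plane normal must be non-zero")
    normal = normal / nn
    p0 = np.zeros(3) if plane_point is None else np.asarray(plane_point, dtype=float)
    missing = [n for n in lm.names if n not in pairing]
    if missing:
        raise InvariantError(f"unpaired landmarks: {missing}")
    worst = 0.0
    for name in lm.names:
        partner = pairing[name]
        if partner not in lm.names:
            raise InvariantError(f"pairing partner {partner!r} of {name!r} not in set")
        q = lm[partner]
        reflected = q - 2.0 * ((q - p0) @ normal) * normal
        worst = max(worst, float(np.linalg.norm(lm[name] - reflected)))
    return worst
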