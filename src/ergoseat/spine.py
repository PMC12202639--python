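"""Cobb-style sagittal spinal angles from vertebral endplate landmarks.

Cervical lordosis (CC), thoracic kyphosis (TTK) and lumbar lordosis (LL)
are each the Cobb angle between two endplate lines after projection onto
the sagittal plane. The default endplate choices follow standard
radiographic convention:

    CC  = inferior endplate of C2 vs inferior endplate of C7
    TTK = superior endplate of T1 vs inferior endplate of T12
    LL  = superior endplate of L1 vs superior endplate of S1

Signs are oriented so that anatomically normal lordosis (cervical,
lumbar) and kyphosis (thoracic) all come out positive; negating the
sagittal curvature of the whole spine flips all three signs. Angles are
invariant under rigid motion and uniform scaling of the landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    DegenerateGeometryError,
    InvariantError,
    SpineAngles,
    SpineLandmarks,
    Vertebra,
)

__all__ = [
    "DEFAULT_LEVELS",
    "LevelConfig",
    "sagittal_project",
    "endplate_line",
    "cobb_angle",
    "compute_spinal_angles",
]


@dataclass(frozen=True)
class LevelConfig:
    """Which endplate lines define one regional angle.

    Each end is (vertebra_label, which_endplate); ``sign`` orients the
    angle so the region's normal curvature is positive (+1 for lordosis
    measured upper-minus-lower, −1 for kyphosis).
    """

    upper: tuple[str, str]
    lower: tuple[str, str]
    sign: int


DEFAULT_LEVELS: dict[str, LevelConfig] = {
    "cc": LevelConfig(upper=("C2", "inferior"), lower=("C7", "inferior"), sign=+1),
    "ttk": LevelConfig(upper=("T1", "superior"), lower=("T12", "inferior"), sign=-1),
    "ll": LevelConfig(upper=("L1", "superior"), lower=("S1", "superior"), sign=+1),
}


def _fit_sagittal_frame(spine: SpineLandmarks,
                        plane_normal: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """In-plane right-handed frame (e_anterior, e_up) of the sagittal plane.

    With no explicit normal the plane is the least-squares plane of the
    vertebral corner midpoints; the in-plane axes are derived from the
    data itself (chain direction → up, mean endplate direction → anterior)
    so the frame — hence every angle — is rigid-motion and scale invariant.
    """
    pts = spine.all_points()
    if plane_normal is None:
        centered = pts - pts.mean(axis=0)
        # normal = least-variance direction of the landmark scatter
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1]
    else:
        normal = np.asarray(plane_normal, dtype=float)
        nn = np.linalg.norm(normal)
        if nn == 0:
            raise DegenerateGeometryError("plane normal must be non-zero")
        normal = normal / nn

    # data-derived axes: cranio-caudal chain → up, endplate mean → anterior
    centroids = np.array([v.corners().mean(axis=0) for v in spine.vertebrae])
    if len(centroids) >= 2:
        up_raw = centroids[0] - centroids[-1]  # caudal → cranial
    else:
        up_raw = np.array([0.0, 1.0, 0.0])
    ant_raw = np.mean(
        [(v.sup_ant - v.sup_post) + (v.inf_ant - v.inf_post) for v in spine.vertebrae],
        axis=0,
    )
    e_up = up_raw - normal * (up_raw @ normal)
    n_up = np.linalg.norm(e_up)
    if n_up < 1e-12:
        raise DegenerateGeometryError("spine chain is perpendicular to the sagittal plane")
    e_up = e_up / n_up
    # orient the normal so (anterior, up, normal) is right-handed
    e_ant = np.cross(e_up, normal)
    if e_ant @ ant_raw < 0:
        e_ant = -e_ant
    return e_ant, e_up


def sagittal_project(spine: SpineLandmarks,
                     plane_normal: np.ndarray | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Project endplate corners onto the sagittal plane.

    Returns {label: {role: (x_anterior, y_up)}} in a right-handed in-plane
    frame. Projection is orthogonal, hence idempotent; in-plane distances
    are preserved.
    """
    e_ant, e_up = _fit_sagittal_frame(spine, plane_normal)
    out: dict[str, dict[str, np.ndarray]] = {}
    for v in spine.vertebrae:
        out[v.label] = {
            role: np.array([getattr(v, role) @ e_ant, getattr(v, role) @ e_up])
            for role in ("sup_ant", "sup_post", "inf_ant", "inf_post")
        }
    return out


def endplate_line(vertebra_2d: dict[str, np.ndarray], which: str) -> np.ndarray:
    """Unit direction of one projected endplate, posterior → anterior corner."""
    if which == "superior":
        post, ant = vertebra_2d["sup_post"], vertebra_2d["sup_ant"]
    elif which == "inferior":
        post, ant = vertebra_2d["inf_post"], vertebra_2d["inf_ant"]
    else:
        raise InvariantError(f"endplate must be 'superior' or 'inferior', got {which!r}")
    d = np.asarray(ant, dtype=float) - np.asarray(post, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise DegenerateGeometryError("coincident endplate corners (zero-length endplate)")
    return d / n


def cobb_angle(line_a: np.ndarray, line_b: np.ndarray) -> float:
    """Signed in-plane angle (degrees) from line_b to line_a in (−180, 180]."""
    a = np.asarray(line_a, dtype=float)
    b = np.asarray(line_b, dtype=float)
    for v in (a, b):
        if np.linalg.norm(v) < 1e-12:
            raise DegenerateGeometryError("degenerate (zero) direction")
    ang = np.degrees(np.arctan2(b[0] * a[1] - b[1] * a[0], a @ b))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def compute_spinal_angles(spine: SpineLandmarks,
                          level_config: dict[str, LevelConfig] | None = None,
                          plane_normal: np.ndarray | None = None) -> SpineAngles:
    """Compute cervical lordosis, thoracic kyphosis and lumbar lordosis."""
    levels = DEFAULT_LEVELS if level_config is None else level_config
    proj = sagittal_project(spine, plane_normal)
    angles: dict[str, float] = {}
    for name, cfg in levels.items():
        for label, _ in (cfg.upper, cfg.lower):
            if label not in proj:
                raise InvariantError(
                    f"vertebra {label} required for angle '{name}' is missing"
                )
        upper = endplate_line(proj[cfg.upper[0]], cfg.upper[1])
        lower = endplate_line(proj[cfg.lower[0]], cfg.lower[1])
        angles[name] = cfg.sign * cobb_angle(upper, lower)
    return SpineAngles(**angles)


def spine_l1_row(spine: SpineLandmarks, n_rows: int, row_pitch_mm: float,
                 backrest_top_height_mm: float) -> int:
    """Project the superior endplate of L1 onto a backrest map row.

    Helper for the waist/back segmentation: heights are measured up the
    backrest plane from the seat pan, row 0 being the top of the mat.
    """
    v: Vertebra = spine["L1"]
    _, e_up = _fit_sagittal_frame(spine)
    h = float(((v.sup_ant + v.sup_post) / 2.0) @ e_up)
    row = int(round((backrest_top_height_mm - h) / row_pitch_mm))
    return int(np.clip(row, 0, n_rows - 1))
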