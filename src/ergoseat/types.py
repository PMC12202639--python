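"""Shared domain types for the seat-comfort pipeline.

All spatial coordinates are millimetres, interface pressures are kPa,
tissue stresses are MPa, angles are degrees, contact areas are cm².
Conversions happen at the boundary (readers/writers), never inside the
metric computations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Interface",
    "RegionName",
    "ConditionKind",
    "ComfortClass",
    "PressureMap",
    "RegionMask",
    "PressureMetrics",
    "LandmarkSet",
    "PointCloud",
    "Vertebra",
    "SpineLandmarks",
    "SpineAngles",
    "FoamParams",
    "UniaxialTest",
    "ConditionResult",
    "ErgoseatError",
    "DataFormatError",
    "InvariantError",
    "NoContactError",
    "DegenerateGeometryError",
    "ExtrapolationError",
]


class ErgoseatError(Exception):
    """Base class for all package errors."""


class DataFormatError(ErgoseatError):
    """Malformed external file (ragged CSV, bad mesh, unknown field)."""


class InvariantError(ErgoseatError):
    """A domain-type invariant is violated (negative pressure, dup name...)."""


class NoContactError(ErgoseatError):
    """Metric requested on a region with zero contact cells."""


class DegenerateGeometryError(ErgoseatError):
    """Coincident points / rank-deficient configuration."""


class ExtrapolationError(ErgoseatError):
    """Query outside a curve's tabulated domain."""


class Interface(str, enum.Enum):
    CUSHION = "cushion"
    BACKREST = "backrest"


class RegionName(str, enum.Enum):
    HIP = "hip"
    LEGS = "legs"
    WAIST = "waist"
    BACK = "back"
    WHOLE = "whole"


class ConditionKind(str, enum.Enum):
    WHOLE_CHAIR_FLIP = "whole_chair_flip"
    BACKREST_FLIP = "backrest_flip"


class ComfortClass(str, enum.Enum):
    BELOW_IDEAL = "below_ideal"
    WITHIN_IDEAL = "within_ideal"
    ABOVE_IDEAL = "above_ideal"


def _as_float_array(x, name: str, shape_tail=None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvariantError(f"{name} contains non-finite values")
    if shape_tail is not None and arr.shape[-len(shape_tail):] != shape_tail:
        raise InvariantError(f"{name} must have trailing shape {shape_tail}, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class PressureMap:
    """Rectangular grid of interface pressures from a capacitive mat.

    ``grid[r, c]`` is the pressure (kPa) of one sensing cell; 0 means no
    contact. ``cell_pitch`` is the physical (row, col) size of one cell in
    mm. Row 0 is the top of the mat as exported; orientation is metadata
    only (``origin_note``), the metrics are orientation-invariant.
    """

    grid: np.ndarray
    cell_pitch: tuple[float, float]
    interface: Interface
    origin_note: str = "row 0 = top of mat as exported"

    def __post_init__(self):
        grid = _as_float_array(self.grid, "pressure grid")
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise InvariantError(f"pressure grid must be 2-D non-empty, got shape {grid.shape}")
        if np.any(grid < 0):
            r, c = np.argwhere(grid < 0)[0]
            raise InvariantError(
                f"negative pressure {grid[r, c]} kPa at cell ({r}, {c}); pressures must be >= 0"
            )
        object.__setattr__(self, "grid", grid)
        pitch = (float(self.cell_pitch[0]), float(self.cell_pitch[1]))
        if pitch[0] <= 0 or pitch[1] <= 0:
            raise InvariantError(f"cell_pitch components must be > 0, got {pitch}")
        object.__setattr__(self, "cell_pitch", pitch)
        object.__setattr__(self, "interface", Interface(self.interface))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_cm2(self) -> float:
        """Physical area of one sensing cell in cm²."""
        return self.cell_pitch[0] * self.cell_pitch[1] / 100.0


@dataclass(frozen=True)
class RegionMask:
    """Named subset of pressure-map cells (e.g. waist vs back)."""

    name: RegionName
    member_cells: frozenset  # of (row, col)

    def __post_init__(self):
        object.__setattr__(self, "name", RegionName(self.name))
        object.__setattr__(self, "member_cells", frozenset(
            (int(r), int(c)) for r, c in self.member_cells
        ))

    def validate_for(self, pmap: PressureMap) -> None:
        rows, cols = pmap.shape
        for r, c in self.member_cells:
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvariantError(
                    f"region '{self.name.value}' cell ({r}, {c}) outside {rows}x{cols} grid"
                )

    @staticmethod
    def whole(pmap: PressureMap) -> "RegionMask":
        rows, cols = pmap.shape
        return RegionMask(RegionName.WHOLE,
                          frozenset((r, c) for r in range(rows) for c in range(cols)))


@dataclass(frozen=True)
class PressureMetrics:
    """Surface-comfort statistics of one region of one pressure map.

    ``spd`` is the seat-pressure-distribution uniformity index
    Σ(pᵢ−p̄)²/(4·n·p̄²) over contact cells; lower is more uniform.
    ``one_minus_spd`` is its comfort-oriented complement.
    """

    p_max: float
    p_ave: float
    contact_area: float
    n_contact: int
    spd: float
    one_minus_spd: float

    def __post_init__(self):
        if self.n_contact > 0:
            if not (self.p_max >= self.p_ave > 0):
                raise InvariantError(
                    f"need p_max >= p_ave > 0 with contact, got {self.p_max}, {self.p_ave}"
                )
            if self.spd < 0:
                raise InvariantError("SPD must be >= 0")
        if abs(self.one_minus_spd - (1.0 - self.spd)) > 1e-12:
            raise InvariantError("one_minus_spd must equal 1 - spd")


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3-D anatomical landmarks (mm)."""

    names: tuple[str, ...]
    coords: np.ndarray  # (n, 3)

    def __post_init__(self):
        names = tuple(str(n) for n in self.names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvariantError(f"duplicate landmark names: {dupes}")
        coords = _as_float_array(self.coords, "landmark coords", (3,))
        coords = coords.reshape(-1, 3)
        if coords.shape[0] != len(names):
            raise InvariantError(
                f"{len(names)} names but {coords.shape[0]} coordinate rows"
            )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        idx = [self.names.index(n) for n in names]
        return LandmarkSet(tuple(names), self.coords[idx])


@dataclass(frozen=True)
class PointCloud:
    """Ordered 3-D point set (mm); with triangle ``faces`` it is a surface mesh."""

    points: np.ndarray           # (n, 3)
    faces: np.ndarray | None = None  # (m, 3) int or None

    def __post_init__(self):
        pts = _as_float_array(self.points, "points", (3,)).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if self.faces is not None:
            faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
            if faces.size and (faces.min() < 0 or faces.max() >= len(pts)):
                raise InvariantError(
                    f"face index out of range: max {faces.max()} for {len(pts)} vertices"
                )
            object.__setattr__(self, "faces", faces)

    def __len__(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return PointCloud(points, self.faces)


#: canonical cranio-caudal ordering of the vertebrae this package understands
VERTEBRA_ORDER = tuple(
    [f"C{i}" for i in range(2, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["S1"]
)

ENDPLATE_ROLES = ("sup_ant", "sup_post", "inf_ant", "inf_post")


@dataclass(frozen=True)
class Vertebra:
    """One vertebral body's sagittal endplate corner points (mm)."""

    label: str
    sup_ant: np.ndarray
    sup_post: np.ndarray
    inf_ant: np.ndarray
    inf_post: np.ndarray

    def __post_init__(self):
        for role in ENDPLATE_ROLES:
            pt = _as_float_array(getattr(self, role), f"{self.label}.{role}")
            if pt.shape != (3,):
                raise InvariantError(f"{self.label}.{role} must be a 3-vector")
            object.__setattr__(self, role, pt)

    def corners(self) -> np.ndarray:
        return np.stack([self.sup_ant, self.sup_post, self.inf_ant, self.inf_post])


@dataclass(frozen=True)
class SpineLandmarks:
    """Cranio-caudally ordered vertebral endplate landmarks."""

    vertebrae: tuple[Vertebra, ...]

    def __post_init__(self):
        verts = tuple(self.vertebrae)
        labels = [v.label for v in verts]
        order = {lbl: i for i, lbl in enumerate(VERTEBRA_ORDER)}
        unknown = [lbl for lbl in labels if lbl not in order]
        if unknown:
            raise InvariantError(f"unknown vertebra labels: {unknown}")
        ranks = [order[lbl] for lbl in labels]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise InvariantError(
                f"vertebra labels must be strictly ordered cranio-caudally, got {labels}"
            )
        object.__setattr__(self, "vertebrae", verts)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.vertebrae)

    def __getitem__(self, label: str) -> Vertebra:
        for v in self.vertebrae:
            if v.label == label:
                return v
        raise KeyError(label)

    def all_points(self) -> np.ndarray:
        return np.concatenate([v.corners() for v in self.vertebrae])


@dataclass(frozen=True)
class SpineAngles:
    """Sagittal curvature angles (degrees): cervical lordosis (cc),
    thoracic kyphosis (ttk), lumbar lordosis (ll). Lordosis and kyphosis
    are both positive for anatomically normal curves."""

    cc: float
    ttk: float
    ll: float

    def __post_init__(self):
        for nm in ("cc", "ttk", "ll"):
            v = float(getattr(self, nm))
            if not (-90.0 < v < 180.0):
                raise InvariantError(f"{nm} = {v} degrees outside (-90, 180)")
            object.__setattr__(self, nm, v)


@dataclass(frozen=True)
class FoamParams:
    """Low-density seat-foam material parameters.

    ``load_curve`` is the monotone compressive loading curve as
    (engineering strain, stress MPa) knots through (0, 0). ``hu`` is the
    hysteretic unloading coefficient (1 = no hysteresis), ``shape`` the
    unloading shape factor, ``beta`` a creep decay constant stored for
    completeness but unused in quasi-static analysis.
    """

    ro: float
    e: float
    load_curve: np.ndarray  # (k, 2): strain, stress
    hu: float
    shape: float
    beta: float = 0.0

    def __post_init__(self):
        curve = _as_float_array(self.load_curve, "load_curve").reshape(-1, 2)
        if curve.shape[0] < 2:
            raise InvariantError("load_curve needs at least 2 knots")
        if abs(curve[0, 0]) > 1e-12 or abs(curve[0, 1]) > 1e-12:
            raise InvariantError("load_curve must pass through (0, 0)")
        if np.any(np.diff(curve[:, 0]) <= 0) or np.any(np.diff(curve[:, 1]) < 0):
            raise InvariantError("load_curve must be non-decreasing in both coordinates")
        object.__setattr__(self, "load_curve", curve)
        if not (0.0 < self.hu <= 1.0):
            raise InvariantError(f"hu must be in (0, 1], got {self.hu}")
        if self.shape <= 0:
            raise InvariantError(f"shape must be > 0, got {self.shape}")
        if self.beta < 0:
            raise InvariantError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class UniaxialTest:
    """One load-to-ε_max-then-unload uniaxial foam test (engineering
    strain vs stress in MPa)."""

    strain: np.ndarray
    stress: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        strain = _as_float_array(self.strain, "strain").ravel()
        stress = _as_float_array(self.stress, "stress").ravel()
        if strain.shape != stress.shape:
            raise InvariantError("strain and stress must have equal length")
        if np.any(stress < 0):
            raise InvariantError("stresses must be >= 0")
        d = np.diff(strain)
        turn = int(np.argmax(strain))
        if np.any(d[:turn] <= 0) or np.any(d[turn:] >= 0):
            raise InvariantError(
                "strain path must rise monotonically to its peak then fall monotonically"
            )
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)

    @property
    def eps_max(self) -> float:
        return float(self.strain.max())

    def branches(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays of the loading and unloading samples."""
        turn = int(np.argmax(self.strain))
        return np.arange(turn + 1), np.arange(turn, len(self.strain))


@dataclass(frozen=True)
class ConditionResult:
    """Per-seat-angle analysis result: per-region surface metrics plus
    optional spinal angles and externally computed internal responses."""

    condition_kind: ConditionKind
    angle: float
    region_metrics: dict = field(default_factory=dict)       # RegionName -> PressureMetrics
    comfort: dict = field(default_factory=dict)              # RegionName -> ComfortClass
    spine_angles: SpineAngles | None = None
    vertebra_max_stress: float | None = None   # MPa
    disc_max_stress: float | None = None       # MPa
    disc_max_strain: float | None = None       # dimensionless

    def __post_init__(self):
        object.__setattr__(self, "condition_kind", ConditionKind(self.condition_kind))
        object.__setattr__(self, "angle", float(self.angle))
        object.__setattr__(
            self, "region_metrics",
            {RegionName(k): v for k, v in self.region_metrics.items()},
        )
        object.__setattr__(
            self, "comfort",
            {RegionName(k): ComfortClass(v) for k, v in self.comfort.items()},
        )
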