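"""Surface-comfort statistics for body-pressure maps.

The central quantity is the seat-pressure-distribution uniformity index

    SPD = Σᵢ (pᵢ − p̄)² / (4 · n · p̄²)

taken over the n cells in contact (pressure strictly above the contact
threshold), where p̄ is their mean pressure. SPD is zero for a perfectly
uniform distribution and grows with non-uniformity; it is invariant under
uniform pressure scaling. 1 − SPD is the comfort-oriented complement.

Region segmentation follows the study convention: the backrest map splits
into waist (below the projection of the superior endplate of L1) and back
(above it); the cushion splits into hip and legs at a user-chosen row.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    ComfortClass,
    InvariantError,
    NoContactError,
    PressureMap,
    PressureMetrics,
    RegionMask,
    RegionName,
)

__all__ = [
    "contact_cells",
    "compute_spd",
    "compute_metrics",
    "bin_histogram",
    "partition_backrest",
    "partition_cushion",
    "classify_comfort",
    "DEFAULT_IDEAL_RANGES",
]

#: ideal peak-pressure windows (kPa, closed intervals) for seated comfort:
#: buttocks 7–11 kPa, lower back 4–8 kPa
DEFAULT_IDEAL_RANGES: dict[RegionName, tuple[float, float]] = {
    RegionName.HIP: (7.0, 11.0),
    RegionName.WAIST: (4.0, 8.0),
}


def _region_pressures(pmap: PressureMap, region: RegionMask | None,
                      threshold: float) -> np.ndarray:
    if region is None:
        region = RegionMask.whole(pmap)
    region.validate_for(pmap)
    if not region.member_cells:
        return np.empty(0)
    idx = np.array(sorted(region.member_cells))
    vals = pmap.grid[idx[:, 0], idx[:, 1]]
    return vals[vals > threshold]


def contact_cells(pmap: PressureMap, region: RegionMask | None = None,
                  threshold: float = 0.0) -> set[tuple[int, int]]:
    """Cells of ``region`` whose pressure is strictly above ``threshold``."""
    if region is None:
        region = RegionMask.whole(pmap)
    region.validate_for(pmap)
    return {(r, c) for (r, c) in region.member_cells if pmap.grid[r, c] > threshold}


def compute_spd(pmap: PressureMap, region: RegionMask | None = None,
                threshold: float = 0.0) -> float:
    """Seat-pressure-distribution uniformity over the region's contact cells."""
    p = _region_pressures(pmap, region, threshold)
    if p.size == 0:
        raise NoContactError("SPD is undefined on a region with no contact cells")
    p_ave = p.mean()
    return float(np.sum((p - p_ave) ** 2) / (4.0 * p.size * p_ave**2))


def compute_metrics(pmap: PressureMap, region: RegionMask | None = None,
                    threshold: float = 0.0) -> PressureMetrics:
    """Peak/average pressure, contact area, and SPD for one region.

    Averages run over contact cells only (cells at or below the threshold
    carry no load information); contact area is the contact-cell count
    times the physical cell area.
    """
    p = _region_pressures(pmap, region, threshold)
    if p.size == 0:
        raise NoContactError(
            "no contact cells in region; metrics undefined (this is an empty-"
            "contact condition, not a computation failure)"
        )
    n = int(p.size)
    p_ave = float(p.mean())
    spd = float(np.sum((p - p_ave) ** 2) / (4.0 * n * p_ave**2))
    return PressureMetrics(
        p_max=float(p.max()),
        p_ave=p_ave,
        contact_area=n * pmap.cell_area_cm2,
        n_contact=n,
        spd=spd,
        one_minus_spd=1.0 - spd,
    )


def bin_histogram(pmap: PressureMap, region: RegionMask | None = None,
                  bin_width: float = 4.0, threshold: float = 0.0) -> np.ndarray:
    """Counts of contact cells per half-open pressure bin [k·w, (k+1)·w).

    The default 4 kPa width mirrors the standard mat-report binning. The
    returned counts always sum to the number of contact cells.
    """
    if bin_width <= 0:
        raise InvariantError(f"bin_width must be > 0, got {bin_width}")
    p = _region_pressures(pmap, region, threshold)
    if p.size == 0:
        return np.zeros(1, dtype=int)
    k = np.floor(p / bin_width).astype(int)
    return np.bincount(k)


def _row_split(pmap: PressureMap, row: int, lower_name: RegionName,
               upper_name: RegionName) -> dict[RegionName, RegionMask]:
    rows, cols = pmap.shape
    if not (0 <= row < rows):
        raise InvariantError(f"division row {row} outside 0..{rows - 1}")
    upper = frozenset((r, c) for r in range(0, row + 1) for c in range(cols))
    lower = frozenset((r, c) for r in range(row + 1, rows) for c in range(cols))
    if not lower:
        warnings.warn(
            f"division at row {row} leaves region '{lower_name.value}' empty",
            stacklevel=3,
        )
    return {
        lower_name: RegionMask(lower_name, lower),
        upper_name: RegionMask(upper_name, upper),
    }


def partition_backrest(pmap: PressureMap, l1_row: int) -> dict[RegionName, RegionMask]:
    """Split a backrest map into waist and back at the L1 projection row.

    Rows 0..l1_row (top of mat, toward the head) form the back; rows below
    the division line (toward the seat cushion) form the waist. The two
    masks are disjoint and together cover the map.
    """
    if pmap.interface.value != "backrest":
        raise InvariantError("waist/back partition applies to backrest maps")
    return _row_split(pmap, l1_row, RegionName.WAIST, RegionName.BACK)


def partition_cushion(pmap: PressureMap, split_row: int) -> dict[RegionName, RegionMask]:
    """Split a cushion map into hip (rows 0..split_row−1, toward the
    backrest) and legs (rows split_row..end). The division row is a user
    choice — mat geometry and sitter anthropometry decide it, there is no
    universal default."""
    if pmap.interface.value != "cushion":
        raise InvariantError("hip/legs partition applies to cushion maps")
    rows, cols = pmap.shape
    if not (0 <= split_row < rows):
        raise InvariantError(f"division row {split_row} outside 0..{rows - 1}")
    hip = frozenset((r, c) for r in range(0, split_row) for c in range(cols))
    legs = frozenset((r, c) for r in range(split_row, rows) for c in range(cols))
    if not hip:
        warnings.warn(f"division at row {split_row} leaves region 'hip' empty",
                      stacklevel=2)
    return {
        RegionName.HIP: RegionMask(RegionName.HIP, hip),
        RegionName.LEGS: RegionMask(RegionName.LEGS, legs),
    }


def classify_comfort(metrics: PressureMetrics, region: RegionName | str,
                     ideal_ranges: dict | None = None) -> ComfortClass:
    """Classify a region's peak pressure against its ideal window.

    Defaults: buttocks (hip) 7–11 kPa, lower back (waist) 4–8 kPa, both
    closed intervals. Regions without a configured window raise.
    """
    region = RegionName(region)
    ranges = DEFAULT_IDEAL_RANGES if ideal_ranges is None else {
        RegionName(k): tuple(v) for k, v in ideal_ranges.items()
    }
    if region not in ranges:
        raise InvariantError(f"no ideal pressure range configured for region '{region.value}'")
    lo, hi = ranges[region]
    if metrics.p_max < lo:
        return ComfortClass.BELOW_IDEAL
    if metrics.p_max > hi:
        return ComfortClass.ABOVE_IDEAL
    return ComfortClass.WITHIN_IDEAL
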