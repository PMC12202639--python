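"""Readers and writers for every external format the pipeline touches.

Pressure maps: plain numeric CSV grids (one file per interface), emulating
capacitive-mat exports; cell pitch is always user-supplied metadata because
mat resolution is hardware-specific. Landmarks: ``name,x,y,z`` CSV or a
JSON name→[x,y,z] object. Clouds/meshes: OBJ and PLY via trimesh (writes
are ASCII OBJ at full double precision). Spine tables: CSV with columns
``label,point_role,x,y,z`` where ``point_role`` is one of sup_ant,
sup_post, inf_ant, inf_post. Reports: JSON.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from pathlib import Path

import numpy as np
import trimesh

from .types import (
    ENDPLATE_ROLES,
    DataFormatError,
    Interface,
    InvariantError,
    LandmarkSet,
    PointCloud,
    PressureMap,
    SpineLandmarks,
    Vertebra,
)

__all__ = [
    "read_pressure_map",
    "write_pressure_map",
    "read_landmarks",
    "write_landmarks",
    "read_cloud",
    "write_cloud",
    "read_spine",
    "write_spine",
    "read_report",
    "write_report",
]

_FMT = "%.17g"  # lossless for float64 round-trips


def read_pressure_map(path, cell_pitch, interface) -> PressureMap:
    """Read a rectangular numeric CSV grid of cell pressures (kPa).

    ``cell_pitch`` is the (row_mm, col_mm) size of one cell;
    ``interface`` is ``"cushion"`` or ``"backrest"``.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec or all(not f.strip() for f in rec):
                continue
            try:
                rows.append([float(f) for f in rec])
            except ValueError as exc:
                raise InvariantError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise DataFormatError(f"{path}: empty pressure grid")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise DataFormatError(f"{path}: ragged rows, widths {sorted(widths)}")
    return PressureMap(np.array(rows), cell_pitch, Interface(interface))


def write_pressure_map(pmap: PressureMap, path) -> None:
    np.savetxt(path, pmap.grid, delimiter=",", fmt=_FMT)


def read_landmarks(path) -> LandmarkSet:
    """Read named landmarks from ``name,x,y,z`` CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        names = list(data.keys())
        coords = np.array([data[n] for n in names], dtype=float)
        return LandmarkSet(tuple(names), coords)
    names, coords = [], []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec or all(not f.strip() for f in rec):
                continue
            if lineno == 1 and rec[0].strip().lower() == "name":
                continue  # header
            if len(rec) != 4:
                raise DataFormatError(f"{path}:{lineno}: expected name,x,y,z, got {len(rec)} fields")
            try:
                xyz = [float(f) for f in rec[1:]]
            except ValueError:
                raise DataFormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            names.append(rec[0].strip())
            coords.append(xyz)
    return LandmarkSet(tuple(names), np.array(coords, dtype=float))


def write_landmarks(lm: LandmarkSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {n: [float(c) for c in xyz] for n, xyz in zip(lm.names, lm.coords)}
        path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for n, xyz in zip(lm.names, lm.coords):
            w.writerow([n] + [_FMT % c for c in xyz])


def read_cloud(path) -> PointCloud:
    """Read a point cloud or triangle mesh from OBJ or PLY."""
    path = Path(path)
    try:
        obj = trimesh.load(str(path), process=False, maintain_order=True)
    except Exception as exc:  # trimesh raises many concrete types
        raise DataFormatError(f"{path}: cannot parse mesh ({exc})") from exc
    if isinstance(obj, trimesh.points.PointCloud):
        return PointCloud(np.asarray(obj.vertices, dtype=float))
    if isinstance(obj, trimesh.Trimesh):
        faces = np.asarray(obj.faces, dtype=int)
        return PointCloud(np.asarray(obj.vertices, dtype=float),
                          faces if len(faces) else None)
    raise DataFormatError(f"{path}: unsupported mesh content {type(obj).__name__}")


def write_cloud(cloud: PointCloud, path) -> None:
    """Write as ASCII OBJ (full double precision)."""
    path = Path(path)
    if path.suffix.lower() != ".obj":
        raise DataFormatError(f"{path}: clouds are written as .obj (ASCII, lossless)")
    if cloud.faces is None or len(cloud.faces) == 0:
        buf = _stdio.StringIO()
        for p in cloud.points:
            buf.write("v %s %s %s\n" % tuple(_FMT % c for c in p))
        path.write_text(buf.getvalue())
        return
    mesh = trimesh.Trimesh(vertices=cloud.points, faces=cloud.faces, process=False)
    path.write_text(trimesh.exchange.obj.export_obj(mesh, digits=17, include_color=False))


def read_spine(path) -> SpineLandmarks:
    """Read a vertebral endplate-corner table.

    CSV columns: ``label,point_role,x,y,z`` with one row per corner and
    ``point_role`` in {sup_ant, sup_post, inf_ant, inf_post}. Every
    vertebra must have all four corners.
    """
    path = Path(path)
    table: dict[str, dict[str, np.ndarray]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec or all(not f.strip() for f in rec):
                continue
            if lineno == 1 and rec[0].strip().lower() == "label":
                continue
            if len(rec) != 5:
                raise DataFormatError(
                    f"{path}:{lineno}: expected label,point_role,x,y,z"
                )
            label, role = rec[0].strip(), rec[1].strip()
            if role not in ENDPLATE_ROLES:
                raise DataFormatError(
                    f"{path}:{lineno}: unknown point_role '{role}' for {label}"
                )
            try:
                xyz = np.array([float(f) for f in rec[2:]])
            except ValueError:
                raise DataFormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            if label not in table:
                table[label] = {}
                order.append(label)
            if role in table[label]:
                raise DataFormatError(f"{path}: duplicate corner {role} for {label}")
            table[label][role] = xyz
    vertebrae = []
    for label in order:
        missing = [r for r in ENDPLATE_ROLES if r not in table[label]]
        if missing:
            raise DataFormatError(
                f"{path}: vertebra {label} missing corner(s) {missing}"
            )
        vertebrae.append(Vertebra(label, **table[label]))
    return SpineLandmarks(tuple(vertebrae))


def write_spine(spine: SpineLandmarks, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "point_role", "x", "y", "z"])
        for v in spine.vertebrae:
            for role in ENDPLATE_ROLES:
                pt = getattr(v, role)
                w.writerow([v.label, role] + [_FMT % c for c in pt])


def write_report(report: dict, path) -> None:
    """Write a report dict as deterministic JSON (sorted keys)."""
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
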