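"""Landmark-driven template morphing (thin-plate spline + affine drift).

Morphs a torso template so that its control landmarks land exactly on
target landmarks — the desk-scale analogue of scaling a generic body
model to a population-specific surface.
"""

import numpy as np
import trimesh

import ergoseat as es

sphere = trimesh.creation.icosphere(subdivisions=3)
mesh = es.PointCloud(np.asarray(sphere.vertices) * [150.0, 110.0, 300.0],
                     np.asarray(sphere.faces))
pts = mesh.points
idx, d = [0], np.linalg.norm(pts - pts[0], axis=1)
for _ in range(15):
    idx.append(int(np.argmax(d)))
    d = np.minimum(d, np.linalg.norm(pts - pts[idx[-1]], axis=1))
controls = es.LandmarkSet(tuple(f"c{i}" for i in range(16)), pts[idx])

# target anthropometry: 8% wider, 5% shallower, 3% taller, plus a local tweak
scale = np.diag([1.08, 0.95, 1.03])
target_coords = controls.coords @ scale
target_coords[3] += [0.0, 12.0, 0.0]
targets = es.LandmarkSet(controls.names, target_coords)

field = es.build_field(controls, targets)
morphed = es.apply_field(mesh, field)

resid = np.linalg.norm(field(controls.coords) - targets.coords, axis=1).max()
print(f"vertices morphed: {len(morphed)}")
print(f"max control-point residual: {resid:.2e} mm (exact interpolation)")
moved = np.linalg.norm(morphed.points - mesh.points, axis=1)
print(f"vertex displacement: median {np.median(moved):.1f} mm, max {moved.max():.1f} mm")
# The field is smooth: far from the tweaked landmark it behaves like the
# global affine scaling, near it the local 12 mm adjustment dominates.
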