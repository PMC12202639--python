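"""Mean body shape from simulated scanned subjects.

Four subject scans are simulated around a known torso template (smooth
zero-mean shape variation + rigid rotation + 1 mm scanner noise); the
generalized Procrustes iteration recovers the template to sub-millimetre
RMSD. With real scans, `correspond` first brings each subject into
point-to-point correspondence with the base scan via shared landmarks.
"""

import numpy as np
import trimesh

import ergoseat as es

sphere = trimesh.creation.icosphere(subdivisions=3)
template = es.PointCloud(np.asarray(sphere.vertices) * [150.0, 110.0, 300.0],
                         np.asarray(sphere.faces))
# deterministic, well-spread landmarks on the template
pts = template.points
idx, d = [0], np.linalg.norm(pts - pts[0], axis=1)
for _ in range(23):
    idx.append(int(np.argmax(d)))
    d = np.minimum(d, np.linalg.norm(pts - pts[idx[-1]], axis=1))
landmarks = es.LandmarkSet(tuple(f"lm{i}" for i in range(24)), pts[idx])

clouds, _, truth = es.gen_body_clouds(template, landmarks, n_subjects=4,
                                      deform_amp=10.0, rot_amp=20.0,
                                      noise_sd=1.0, seed=42)
result = es.mean_shape(es.CorrespondedSet(clouds[0], tuple(clouds[1:])))

r, t = es.orthogonal_align(result.mean_shape.points, truth.points)
rmsd = np.sqrt(np.mean(np.sum((result.mean_shape.points @ r + t
                               - truth.points) ** 2, axis=1)))
print(f"subjects: 4, points per cloud: {len(template)}")
print(f"iterations: {len(result.objective_trace)}, converged: {result.converged}")
print(f"objective trace: {[round(v, 1) for v in result.objective_trace[:5]]} ...")
print(f"RMSD of recovered mean to true template: {rmsd:.3f} mm")
# RMSD < 1 mm: the averaging removes rotation and shape noise, so the mean
# is a faithful representative body surface.
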