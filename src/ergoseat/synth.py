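"""Seeded synthetic generators for every input the pipeline consumes.

These emulate the statistical structure of the study's instruments — a
capacitive pressure mat, a body-surface scanner, a uniaxial foam test rig
and an external solver's internal-response tables — not their physics:

* cushion maps peak at the two ischial-tuberosity loci and decay along the
  thighs; backrest maps peak mid-waist and decay to the periphery
  (exponential-decay bumps clipped to a contact ellipse, plus
  truncated-at-zero Gaussian sensor noise);
* spines are sagittal chains of parallel-endplate vertebral quadrilaterals
  whose regional tilt ramps realize exactly the requested cervical
  lordosis / thoracic kyphosis / lumbar lordosis Cobb angles;
* subject point clouds derive from a template by smooth random RBF warps
  that are constrained zero-mean across subjects (so the template is the
  exact true mean), followed by random rigid rotation and Gaussian noise;
* foam tests sample the constitutive loading/unloading laws plus noise;
* condition series sweep seat angles, moving pressure from cushion to
  backrest, with configurable monotone or U-shaped internal responses.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .foam import loading_stress, unloading_stress
from .morphing import build_field
from .types import (
    ConditionKind,
    FoamParams,
    Interface,
    InvariantError,
    LandmarkSet,
    PointCloud,
    PressureMap,
    SpineLandmarks,
    UniaxialTest,
    Vertebra,
    VERTEBRA_ORDER,
)

__all__ = [
    "PressureScenario",
    "gen_pressure_map",
    "gen_spine",
    "gen_body_clouds",
    "gen_foam_test",
    "gen_condition_series",
    "cushion_scenario",
    "backrest_scenario",
]


@dataclass(frozen=True)
class PressureScenario:
    """Recipe for one synthetic pressure map.

    ``peak_centers`` are (row, col) loci of the pressure bumps (ischial
    tuberosities on a cushion, mid-waist on a backrest), each with an
    amplitude in kPa; pressure decays exponentially with cell distance
    over ``decay_length`` cells and is clipped to an elliptical contact
    patch (center, semi-axes in cells).
    """

    interface: Interface
    shape: tuple[int, int]
    peak_centers: tuple[tuple[float, float], ...]
    peak_amplitudes: tuple[float, ...]
    decay_length: float
    contact_center: tuple[float, float]
    contact_semiaxes: tuple[float, float]
    noise_sd: float
    seed: int
    cell_pitch: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self):
        if any(a <= 0 for a in self.peak_amplitudes):
            raise InvariantError("peak amplitudes must be > 0")
        if self.decay_length <= 0:
            raise InvariantError("decay_length must be > 0")
        if len(self.peak_centers) != len(self.peak_amplitudes):
            raise InvariantError("one amplitude per peak center required")
        rows, cols = self.shape
        for r, c in self.peak_centers:
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvariantError(f"peak center ({r}, {c}) outside {rows}x{cols} grid")


def cushion_scenario(seed: int, shape: tuple[int, int] = (32, 32),
                     peak_kpa: float = 9.5, noise_sd: float = 0.3) -> PressureScenario:
    """Default cushion: two ischial peaks in the hip zone, thighs decaying
    down-map; peak amplitude sits inside the 7–11 kPa ideal buttock window."""
    rows, cols = shape
    decay = rows * 0.22
    d12 = cols * 0.24  # ischial peak separation in cells
    # normalize for bump overlap so the rendered maximum is ~peak_kpa
    amp = peak_kpa / (1.0 + 0.97 * np.exp(-d12 / decay))
    return PressureScenario(
        interface=Interface.CUSHION,
        shape=shape,
        peak_centers=((rows * 0.28, cols * 0.38), (rows * 0.28, cols * 0.62)),
        peak_amplitudes=(amp, amp * 0.97),
        decay_length=decay,
        contact_center=(rows * 0.45, cols * 0.5),
        contact_semiaxes=(rows * 0.48, cols * 0.32),
        noise_sd=noise_sd,
        seed=seed,
    )


def backrest_scenario(seed: int, shape: tuple[int, int] = (40, 32),
                      peak_kpa: float = 6.0, noise_sd: float = 0.25) -> PressureScenario:
    """Default backrest: single mid-waist peak decaying to the periphery."""
    rows, cols = shape
    return PressureScenario(
        interface=Interface.BACKREST,
        shape=shape,
        peak_centers=((rows * 0.70, cols * 0.5),),  # waist = lower part of mat
        peak_amplitudes=(peak_kpa,),
        decay_length=rows * 0.25,
        contact_center=(rows * 0.55, cols * 0.5),
        contact_semiaxes=(rows * 0.5, cols * 0.38),
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_pressure_map(scenario: PressureScenario) -> PressureMap:
    """Render a scenario to a pressure map. Deterministic given the seed."""
    rows, cols = scenario.shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=float),
                         np.arange(cols, dtype=float), indexing="ij")
    grid = np.zeros((rows, cols))
    for (pr, pc), amp in zip(scenario.peak_centers, scenario.peak_amplitudes):
        d = np.hypot(rr - pr, cc - pc)
        grid += amp * np.exp(-d / scenario.decay_length)
    (ecr, ecc), (sr, sc) = scenario.contact_center, scenario.contact_semiaxes
    inside = ((rr - ecr) / sr) ** 2 + ((cc - ecc) / sc) ** 2 <= 1.0
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        grid = grid + rng.normal(0.0, scenario.noise_sd, grid.shape)
    grid = np.clip(grid, 0.0, None)
    grid[~inside] = 0.0
    return PressureMap(grid, scenario.cell_pitch, scenario.interface)


# ---------------------------------------------------------------------------
# spines


def _default_heights() -> dict[str, float]:
    """Nominal vertebral body heights (mm), cervical < thoracic < lumbar."""
    h = {}
    for lbl in VERTEBRA_ORDER:
        if lbl.startswith("C"):
            h[lbl] = 13.0
        elif lbl.startswith("T"):
            h[lbl] = 20.0
        else:
            h[lbl] = 27.0
    return h


def _tilt_schedule(cc: float, ttk: float, ll: float) -> dict[str, float]:
    """Per-vertebra endplate tilt (deg, anterior-up positive) realizing the
    requested regional Cobb angles with linear ramps inside each region."""
    tilts: dict[str, float] = {}
    cerv = [f"C{i}" for i in range(2, 8)]
    thor = [f"T{i}" for i in range(1, 13)]
    lumb = [f"L{i}" for i in range(1, 6)] + ["S1"]
    for i, lbl in enumerate(cerv):            # CC = tilt(C2) − tilt(C7)
        tilts[lbl] = cc / 2.0 - cc * i / (len(cerv) - 1)
    for i, lbl in enumerate(thor):            # TTK = tilt(T12) − tilt(T1)
        tilts[lbl] = -ttk / 2.0 + ttk * i / (len(thor) - 1)
    for i, lbl in enumerate(lumb):            # LL = tilt(L1) − tilt(S1)
        tilts[lbl] = ll / 2.0 - ll * i / (len(lumb) - 1)
    return tilts


def gen_spine(cc: float, ttk: float, ll: float,
              vertebra_heights: dict[str, float] | None = None,
              depth: float = 32.0, disc_gap: float = 5.0,
              jitter_sd: float = 0.0, seed: int = 0) -> SpineLandmarks:
    """Synthesize a sagittal vertebral chain with exact regional angles.

    Vertebrae are parallel-endplate quadrilaterals (depth mm anterior–
    posterior) stacked caudal→cranial with ``disc_gap`` between bodies;
    the per-region tilt ramps make the default endplate-line choices
    return exactly (cc, ttk, ll). Optional Gaussian ``jitter_sd`` (mm)
    perturbs every corner, seeded.
    """
    for name, v in (("cc", cc), ("ttk", ttk), ("ll", ll)):
        if abs(v) >= 90:
            raise InvariantError(f"|{name}| must be < 90 degrees, got {v}")
    heights = _default_heights() if vertebra_heights is None else dict(vertebra_heights)
    tilts = _tilt_schedule(cc, ttk, ll)
    labels = list(VERTEBRA_ORDER)
    # consecutive tilt jumps beyond 45° would interpenetrate the bodies
    seq = [tilts[lbl] for lbl in labels]
    if any(abs(b - a) > 45.0 for a, b in zip(seq, seq[1:])):
        raise InvariantError("requested angles produce overlapping vertebrae")

    rng = np.random.default_rng(seed)
    vertebrae: list[Vertebra] = []
    center = np.zeros(2)  # sagittal plane: x = anterior, y = up; build caudal→cranial
    prev_up = None
    prev_h = None
    for lbl in reversed(labels):  # S1 first at the origin
        th = np.radians(tilts[lbl])
        direction = np.array([np.cos(th), np.sin(th)])      # posterior→anterior
        up = np.array([-np.sin(th), np.cos(th)])
        h = heights[lbl]
        if prev_up is not None:
            center = center + prev_up * (prev_h / 2.0) + (prev_up + up) / 2.0 * disc_gap + up * (h / 2.0)
        half_d, half_h = depth / 2.0, h / 2.0
        c3 = lambda p2: np.array([p2[0], p2[1], 0.0])
        corners = {
            "sup_ant": c3(center + up * half_h + direction * half_d),
            "sup_post": c3(center + up * half_h - direction * half_d),
            "inf_ant": c3(center - up * half_h + direction * half_d),
            "inf_post": c3(center - up * half_h - direction * half_d),
        }
        if jitter_sd > 0:
            for k in corners:
                corners[k] = corners[k] + rng.normal(0.0, jitter_sd, 3)
        vertebrae.append(Vertebra(lbl, **corners))
        prev_up, prev_h = up, h
    vertebrae.reverse()  # back to cranio-caudal order
    return SpineLandmarks(tuple(vertebrae))


# ---------------------------------------------------------------------------
# body clouds


def gen_body_clouds(template: PointCloud, template_lm: LandmarkSet,
                    n_subjects: int = 4, deform_amp: float = 10.0,
                    rot_amp: float = 20.0, noise_sd: float = 1.0,
                    seed: int = 0) -> tuple[list[PointCloud], list[LandmarkSet], PointCloud]:
    """Simulate scanned subjects around a known template mean shape.

    Each subject is the template warped by a random smooth RBF field
    (anchor displacements drawn at the landmarks, then recentred to
    zero-mean across subjects so the template is the exact pre-rotation
    mean), rotated rigidly by a random rotation of at most ``rot_amp``
    degrees and perturbed with isotropic Gaussian noise. Landmarks ride
    through the same maps. Returns (clouds, landmark sets, true mean).
    """
    if n_subjects < 2:
        raise InvariantError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    n_lm = len(template_lm)
    # zero-mean anchor displacements at the landmarks
    disp = rng.normal(0.0, 1.0, (n_subjects, n_lm, 3))
    disp -= disp.mean(axis=0, keepdims=True)
    scale = np.abs(disp).max() or 1.0
    disp *= deform_amp / scale

    clouds, lm_sets = [], []
    for s in range(n_subjects):
        if deform_amp > 0:
            targets = LandmarkSet(template_lm.names, template_lm.coords + disp[s])
            fld = build_field(template_lm, targets)
            pts = fld(template.points)
            lm_pts = fld(template_lm.coords)
        else:
            pts = template.points.copy()
            lm_pts = template_lm.coords.copy()
        # random rotation with angle <= rot_amp about a random axis
        if rot_amp > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.radians(rng.uniform(0.0, rot_amp))
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
            pts = pts @ rot.T
            lm_pts = lm_pts @ rot.T
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd, pts.shape)
        clouds.append(PointCloud(pts, template.faces))
        lm_sets.append(LandmarkSet(template_lm.names, lm_pts))
    return clouds, lm_sets, template


# ---------------------------------------------------------------------------
# foam tests


def gen_foam_test(params: FoamParams, eps_max: float, n_points: int = 60,
                  noise_sd: float = 0.0, seed: int = 0) -> UniaxialTest:
    """Sample one load-to-eps_max-then-unload cycle of the foam model."""
    if not (params.load_curve[0, 0] < eps_max <= params.load_curve[-1, 0]):
        raise InvariantError("eps_max outside the loading-curve domain")
    up = np.linspace(0.0, eps_max, n_points)
    down = np.linspace(eps_max, 0.0, n_points)[1:]
    strain = np.concatenate([up, down])
    stress = np.concatenate([
        np.atleast_1d(loading_stress(up, params.load_curve)),
        np.atleast_1d(unloading_stress(down, eps_max, params.load_curve,
                                       params.hu, params.shape)),
    ])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = np.clip(stress + rng.normal(0.0, noise_sd, stress.shape), 0.0, None)
    return UniaxialTest(strain, stress, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# condition series


@dataclass(frozen=True)
class EffectModel:
    """Internal-response curve over the swept angle: 'linear' (monotone)
    or 'u_shaped' (minimum at ``u_min_angle``), scaled to [base, base+span]."""

    kind: str = "linear"
    base: float = 1.0
    span: float = 1.0
    u_min_angle: float = 10.0
    noise_sd: float = 0.0

    def evaluate(self, angles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        a = np.asarray(angles, dtype=float)
        lo, hi = a.min(), a.max()
        width = max(hi - lo, 1e-12)
        if self.kind == "linear":
            y = (a - lo) / width
        elif self.kind == "u_shaped":
            y = ((a - self.u_min_angle) / width) ** 2
            y = (y - y.min()) / max(y.max() - y.min(), 1e-12)
        else:
            raise InvariantError(f"unknown effect model kind {self.kind!r}")
        out = self.base + self.span * y
        if self.noise_sd > 0:
            out = out + rng.normal(0.0, self.noise_sd, out.shape)
        return out


DEFAULT_EFFECTS = {
    # disc stress rises with recline; lumbar vertebral stress dips mid-range
    "vertebra_max_stress": EffectModel(kind="u_shaped", base=2.0, span=1.5, u_min_angle=10.0),
    "disc_max_stress": EffectModel(kind="linear", base=0.4, span=0.5),
    "disc_max_strain": EffectModel(kind="linear", base=0.10, span=0.15),
}


def gen_condition_series(kind: ConditionKind | str, angles: list[float],
                         effect_models: dict[str, EffectModel] | None = None,
                         seed: int = 0,
                         cushion_shape: tuple[int, int] = (32, 32),
                         backrest_shape: tuple[int, int] = (40, 32),
                         noise_sd: float = 0.25):
    """Per-angle (cushion map, backrest map, internal responses) tuples.

    With increasing recline angle, load migrates from the cushion to the
    backrest: the ischial peak amplitude falls and the waist peak rises,
    mirroring the qualitative behaviour of reclined sitting. Internal
    responses come from the effect models. Deterministic given the seed.
    """
    kind = ConditionKind(kind)
    angles_arr = np.asarray(angles, dtype=float)
    if angles_arr.size < 3:
        raise InvariantError("need at least 3 angles for a condition series")
    effects = DEFAULT_EFFECTS if effect_models is None else effect_models
    rng = np.random.default_rng(seed)
    responses = {name: m.evaluate(angles_arr, rng) for name, m in effects.items()}
    lo, hi = angles_arr.min(), angles_arr.max()
    width = max(hi - lo, 1e-12)
    series = []
    for i, ang in enumerate(angles_arr):
        f = (ang - lo) / width  # 0 = most upright, 1 = most reclined
        cush = cushion_scenario(seed=seed + 101 * i, shape=cushion_shape,
                                peak_kpa=9.5 - 3.5 * f, noise_sd=noise_sd)
        back = backrest_scenario(seed=seed + 101 * i + 50, shape=backrest_shape,
                                 peak_kpa=4.5 + 4.5 * f, noise_sd=noise_sd)
        series.append({
            "kind": kind,
            "angle": float(ang),
            "cushion": gen_pressure_map(cush),
            "backrest": gen_pressure_map(back),
            "internal": {name: float(vals[i]) for name, vals in responses.items()},
        })
    return series
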