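"""Quasi-static point model of hysteretic low-density seat foam.

Loading follows a tabulated monotone engineering stress–strain curve.
Unloading from a peak strain ε_max is modelled phenomenologically by
scaling the loading stress with an energy-based recovery factor governed
by the hysteretic unloading coefficient HU ∈ (0, 1] and the unloading
shape factor SHAPE > 0:

    σ_unload(ε) = σ_load(ε) · [ HU + (1 − HU) · (W(ε) / W(ε_max))^SHAPE ]

where W(ε) = ∫₀^ε σ_load dε′ is the stored loading energy density. The
factor equals 1 at ε = ε_max (continuity at the reversal point) and HU at
ε = 0, so HU = 1 means no hysteresis and smaller HU means more dissipated
energy. This is a documented stand-in for solver-internal hysteretic
unloading laws that are parameterized the same way but whose exact
equations are not public; equivalence with any particular commercial
material model is not claimed. The creep decay constant BETA is carried
in :class:`~ergoseat.types.FoamParams` but plays no role quasi-statically.

Parameter identification (``fit_foam_params``) recovers (HU, SHAPE) from
measured load–unload test curves by bounded nonlinear least squares on the
unloading branch, multi-started from a seeded Latin-style grid to avoid
local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .types import (
    ErgoseatError,
    ExtrapolationError,
    InvariantError,
    UniaxialTest,
)

__all__ = ["loading_stress", "loading_energy", "unloading_stress",
           "dissipated_energy", "FoamFit", "fit_foam_params"]


def _curve(load_curve) -> np.ndarray:
    c = np.asarray(load_curve, dtype=float).reshape(-1, 2)
    return c


def loading_stress(strain, load_curve) -> np.ndarray | float:
    """Piecewise-linear loading stress (MPa) at the given strain(s).

    Strains beyond the last tabulated knot raise — the tails of a foam
    curve steepen sharply and silent linear extrapolation would be wrong.
    """
    c = _curve(load_curve)
    eps = np.asarray(strain, dtype=float)
    if np.any(eps < c[0, 0] - 1e-15) or np.any(eps > c[-1, 0] + 1e-15):
        raise ExtrapolationError(
            f"strain outside tabulated domain [{c[0, 0]}, {c[-1, 0]}]"
        )
    out = np.interp(eps, c[:, 0], c[:, 1])
    return float(out) if np.isscalar(strain) else out


def loading_energy(strain, load_curve) -> np.ndarray | float:
    """W(ε) = ∫₀^ε σ_load dε′, exact for the piecewise-linear curve."""
    c = _curve(load_curve)
    # cumulative exact trapezoid at the knots
    seg = 0.5 * (c[1:, 1] + c[:-1, 1]) * np.diff(c[:, 0])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    eps = np.atleast_1d(np.asarray(strain, dtype=float))
    if np.any(eps < c[0, 0] - 1e-15) or np.any(eps > c[-1, 0] + 1e-15):
        raise ExtrapolationError(
            f"strain outside tabulated domain [{c[0, 0]}, {c[-1, 0]}]"
        )
    idx = np.clip(np.searchsorted(c[:, 0], eps, side="right") - 1, 0, len(c) - 2)
    e0, s0 = c[idx, 0], c[idx, 1]
    slope = (c[idx + 1, 1] - s0) / (c[idx + 1, 0] - e0)
    d = eps - e0
    w = cum[idx] + s0 * d + 0.5 * slope * d**2
    return float(w[0]) if np.isscalar(strain) else w


def unloading_stress(strain, eps_max: float, load_curve,
                     hu: float, shape: float) -> np.ndarray | float:
    """Hysteretic unloading stress at strain(s) after loading to ``eps_max``."""
    if eps_max <= 0:
        raise InvariantError("degenerate loading history: eps_max must be > 0")
    if not (0.0 < hu <= 1.0):
        raise InvariantError(f"hu must be in (0, 1], got {hu}")
    if shape <= 0:
        raise InvariantError(f"shape must be > 0, got {shape}")
    eps = np.asarray(strain, dtype=float)
    if np.any(eps < -1e-15) or np.any(eps > eps_max + 1e-12):
        raise InvariantError("unloading strain must lie in [0, eps_max]")
    w = np.atleast_1d(loading_energy(eps, load_curve))
    wmax = loading_energy(eps_max, load_curve)
    factor = hu + (1.0 - hu) * (w / wmax) ** shape
    out = np.atleast_1d(loading_stress(eps, load_curve)) * factor
    return float(out[0]) if np.isscalar(strain) else out


def dissipated_energy(load_curve, eps_max: float, hu: float, shape: float,
                      n_points: int = 2001) -> float:
    """Hysteresis-loop area (MPa = MJ/m³) of one load–unload cycle.

    Trapezoidal quadrature of σ_load − σ_unload over [0, ε_max]; zero iff
    HU = 1.
    """
    if eps_max <= 0:
        raise InvariantError("incomplete cycle: eps_max must be > 0")
    eps = np.linspace(0.0, eps_max, n_points)
    gap = np.asarray(loading_stress(eps, load_curve)) - np.asarray(
        unloading_stress(eps, eps_max, load_curve, hu, shape))
    return float(np.trapezoid(gap, eps))


@dataclass(frozen=True)
class FoamFit:
    """Identified unloading parameters and fit diagnostics."""

    hu: float
    shape: float
    residual_norm: float
    converged: bool
    n_starts: int


def fit_foam_params(tests: list[UniaxialTest], load_curve,
                    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-4, 1.0), (1e-2, 10.0)),
                    seed: int = 0, n_starts: int = 8) -> FoamFit:
    """Identify (HU, SHAPE) from the unloading branches of test curves.

    Bounded least squares on stacked unloading-branch residuals,
    multi-started from a seeded log/linear grid over the bounds; the best
    converged start wins.
    """
    if not tests:
        raise ErgoseatError("no tests supplied")
    samples: list[tuple[float, float, float]] = []  # (strain, eps_max, stress)
    for test in tests:
        _, unload_idx = test.branches()
        if len(unload_idx) < 2:
            continue
        emax = test.eps_max
        for i in unload_idx:
            samples.append((float(test.strain[i]), emax, float(test.stress[i])))
    if not samples:
        raise ErgoseatError("no unloading samples in any test")
    eps = np.array([s[0] for s in samples])
    emaxs = np.array([s[1] for s in samples])
    meas = np.array([s[2] for s in samples])

    def residuals(theta):
        hu, shape = theta
        pred = np.empty_like(meas)
        for em in np.unique(emaxs):
            sel = emaxs == em
            pred[sel] = unloading_stress(eps[sel], em, load_curve, hu, shape)
        return pred - meas

    (hu_lo, hu_hi), (sh_lo, sh_hi) = bounds
    rng = np.random.default_rng(seed)
    starts = np.column_stack([
        rng.uniform(hu_lo, hu_hi, n_starts),
        np.exp(rng.uniform(np.log(sh_lo), np.log(sh_hi), n_starts)),
    ])
    starts[0] = [min(max(0.5, hu_lo), hu_hi), min(max(1.0, sh_lo), sh_hi)]

    best = None
    any_converged = False
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=([hu_lo, sh_lo], [hu_hi, sh_hi]))
        except Exception:
            continue
        any_converged = any_converged or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ErgoseatError("foam fit failed from every start")
    return FoamFit(hu=float(best.x[0]), shape=float(best.x[1]),
                   residual_norm=float(np.linalg.norm(best.fun)),
                   converged=bool(any_converged), n_starts=n_starts)
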