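"""Per-condition analysis, sim-vs-experiment comparison and trend tables.

``analyze_condition`` turns one condition's pressure maps (plus optional
spinal landmarks and externally computed internal responses) into a
:class:`~ergoseat.types.ConditionResult` with per-region surface metrics
and comfort classifications. ``run_pipeline`` sweeps a whole condition
series, cross-tabulating how each surface metric (peak pressure, average
pressure, contact area, 1−SPD) co-varies with each internal response
(vertebral / disc stress, disc strain) via rank correlation, and writes a
deterministic JSON report plus CSV tables.

Validation helpers implement the study-style discrepancy measures:
``percent_deviation`` (100·|sim − exp|/|exp|) and a binned pressure-count
comparison with total-variation distance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from scipy.stats import spearmanr, pearsonr

from . import pressure as pm
from .spine import compute_spinal_angles
from .synth import gen_condition_series
from .types import (
    ConditionKind,
    ConditionResult,
    ErgoseatError,
    InvariantError,
    PressureMap,
    RegionName,
    SpineLandmarks,
)

__all__ = [
    "percent_deviation",
    "compare_histograms",
    "trend_similarity",
    "analyze_condition",
    "run_pipeline",
    "SURFACE_METRICS",
]

SURFACE_METRICS = ("p_max", "p_ave", "contact_area", "one_minus_spd")


def percent_deviation(sim: float, exp: float) -> float:
    """100 · |sim − exp| / |exp| — scale-invariant discrepancy in percent."""
    if exp == 0:
        raise InvariantError("percent deviation undefined for experimental value 0")
    return 100.0 * abs(sim - exp) / abs(exp)


def compare_histograms(sim_counts, exp_counts) -> dict:
    """Per-bin absolute differences and total-variation distance.

    TV = ½ Σ |p̂_sim − p̂_exp| over the count-normalized histograms;
    0 for identical shapes, 1 for disjoint support.
    """
    sim = np.asarray(sim_counts, dtype=float)
    exp = np.asarray(exp_counts, dtype=float)
    if sim.shape != exp.shape:
        raise InvariantError(f"histograms have different binning: {sim.shape} vs {exp.shape}")
    if sim.sum() == 0 or exp.sum() == 0:
        raise InvariantError("cannot compare an empty histogram")
    tv = 0.5 * float(np.abs(sim / sim.sum() - exp / exp.sum()).sum())
    return {"per_bin_abs_diff": np.abs(sim - exp), "tv_distance": tv}


def trend_similarity(a, b, method: str = "spearman") -> float:
    """Rank correlation of two per-condition series (ties mid-ranked).

    Quantifies whether two indicators move together across seat angles
    regardless of units or nonlinearity; a ``pearson`` option is exposed
    for strictly linear co-variation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvariantError("series must be 1-D and equally long")
    if a.size < 3:
        raise InvariantError("need at least 3 conditions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvariantError("trend similarity undefined for a constant series")
    if method == "spearman":
        return float(spearmanr(a, b).statistic)
    if method == "pearson":
        return float(pearsonr(a, b).statistic)
    raise InvariantError(f"unknown method {method!r}")


def analyze_condition(kind: ConditionKind | str, angle: float,
                      cushion: PressureMap | None = None,
                      backrest: PressureMap | None = None,
                      cushion_split_row: int | None = None,
                      backrest_l1_row: int | None = None,
                      spine: SpineLandmarks | None = None,
                      internal: dict | None = None,
                      threshold: float = 0.0,
                      ideal_ranges: dict | None = None) -> ConditionResult:
    """Full surface-comfort analysis of one seat-angle condition."""
    if cushion is None and backrest is None:
        raise ErgoseatError("at least one pressure map is required")
    metrics: dict = {}
    comfort: dict = {}
    if cushion is not None:
        regions = ({RegionName.WHOLE: pm.RegionMask.whole(cushion)}
                   if cushion_split_row is None
                   else pm.partition_cushion(cushion, cushion_split_row))
        for name, mask in regions.items():
            metrics[name] = pm.compute_metrics(cushion, mask, threshold)
    if backrest is not None:
        regions = ({RegionName.WHOLE: pm.RegionMask.whole(backrest)}
                   if backrest_l1_row is None
                   else pm.partition_backrest(backrest, backrest_l1_row))
        for name, mask in regions.items():
            metrics[name] = pm.compute_metrics(backrest, mask, threshold)
    for name in (RegionName.HIP, RegionName.WAIST):
        if name in metrics:
            comfort[name] = pm.classify_comfort(metrics[name], name, ideal_ranges)
    internal = internal or {}
    return ConditionResult(
        condition_kind=ConditionKind(kind),
        angle=angle,
        region_metrics=metrics,
        comfort=comfort,
        spine_angles=compute_spinal_angles(spine) if spine is not None else None,
        vertebra_max_stress=internal.get("vertebra_max_stress"),
        disc_max_stress=internal.get("disc_max_stress"),
        disc_max_strain=internal.get("disc_max_strain"),
    )


# --------------------------------------------------------------------------
# report schema (pydantic) and serialization


class MetricsBlock(BaseModel):
    p_max: float = Field(ge=0)
    p_ave: float = Field(gt=0)
    contact_area: float = Field(ge=0)
    n_contact: int = Field(ge=1)
    spd: float = Field(ge=0)
    one_minus_spd: float


class ConditionBlock(BaseModel):
    condition_kind: str
    angle: float
    regions: dict[str, MetricsBlock]
    comfort: dict[str, str]
    spine_angles: dict[str, float] | None = None
    internal: dict[str, float] = {}


class ReportSchema(BaseModel):
    config: dict
    conditions: list[ConditionBlock]
    trend_matrix: dict[str, dict[str, dict[str, float]]]
    comparisons: list[dict] = []


def _fmt(x: float) -> float:
    """Fixed float formatting for byte-stable reports."""
    return float(f"{x:.10g}")


def _condition_to_block(res: ConditionResult) -> dict:
    block = {
        "condition_kind": res.condition_kind.value,
        "angle": _fmt(res.angle),
        "regions": {
            name.value: {
                "p_max": _fmt(m.p_max), "p_ave": _fmt(m.p_ave),
                "contact_area": _fmt(m.contact_area), "n_contact": m.n_contact,
                "spd": _fmt(m.spd), "one_minus_spd": _fmt(m.one_minus_spd),
            }
            for name, m in sorted(res.region_metrics.items(), key=lambda kv: kv[0].value)
        },
        "comfort": {k.value: v.value for k, v in sorted(res.comfort.items(),
                                                        key=lambda kv: kv[0].value)},
        "internal": {},
    }
    if res.spine_angles is not None:
        block["spine_angles"] = {"cc": _fmt(res.spine_angles.cc),
                                 "ttk": _fmt(res.spine_angles.ttk),
                                 "ll": _fmt(res.spine_angles.ll)}
    else:
        block["spine_angles"] = None
    for key in ("vertebra_max_stress", "disc_max_stress", "disc_max_strain"):
        v = getattr(res, key)
        if v is not None:
            block["internal"][key] = _fmt(float(v))
    return block


def _trend_matrix(results: list[ConditionResult]) -> dict:
    """Rank correlation of every per-region surface metric against every
    available internal response, across conditions."""
    internal_series: dict[str, list[float]] = {}
    for key in ("vertebra_max_stress", "disc_max_stress", "disc_max_strain"):
        vals = [getattr(r, key) for r in results]
        if all(v is not None for v in vals):
            internal_series[key] = [float(v) for v in vals]
    matrix: dict[str, dict[str, dict[str, float]]] = {}
    if len(results) < 3:
        return matrix
    region_names = sorted({n for r in results for n in r.region_metrics},
                          key=lambda n: n.value)
    for region in region_names:
        if not all(region in r.region_metrics for r in results):
            continue
        matrix[region.value] = {}
        for metric in SURFACE_METRICS:
            surface = [getattr(r.region_metrics[region], metric) for r in results]
            row: dict[str, float] = {}
            for iname, ivals in internal_series.items():
                try:
                    row[iname] = _fmt(trend_similarity(surface, ivals))
                except InvariantError:
                    continue  # constant series: correlation undefined, omitted
            matrix[region.value][metric] = row
    return matrix


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run a whole study configuration and write the report bundle.

    ``config`` is a dict or a YAML path with blocks::

        conditions:            # either synthetic or file-based
          kind: whole_chair_flip
          angles: [0, 10, 20, 30, 40]
          synthetic: {seed: 7}            # or per-angle file entries
        partitions: {cushion_split_row: 14, backrest_l1_row: 24}
        threshold: 0.0
        ideal_ranges: {hip: [7, 11], waist: [4, 8]}

    Writes ``report.json`` (schema-validated, sorted keys, fixed float
    formatting — byte-identical on reruns) and per-region ``metrics.csv``
    / ``trends.csv`` tables. Returns the report dict.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cond_cfg = config.get("conditions", {})
    kind = ConditionKind(cond_cfg.get("kind", "whole_chair_flip"))
    parts = config.get("partitions", {})
    threshold = float(config.get("threshold", 0.0))
    ideal = config.get("ideal_ranges")

    results: list[ConditionResult] = []
    if "synthetic" in cond_cfg:
        angles = list(cond_cfg.get("angles", [0, 10, 20, 30, 40]))
        seed = int(cond_cfg["synthetic"].get("seed", 0))
        series = gen_condition_series(kind, angles, seed=seed)
        for entry in series:
            results.append(analyze_condition(
                kind, entry["angle"],
                cushion=entry["cushion"], backrest=entry["backrest"],
                cushion_split_row=parts.get("cushion_split_row", 14),
                backrest_l1_row=parts.get("backrest_l1_row", 24),
                internal=entry["internal"],
                threshold=threshold, ideal_ranges=ideal,
            ))
    else:
        from .io import read_pressure_map, read_spine
        for entry in cond_cfg.get("files", []):
            cushion = backrest = spine = None
            if "cushion" in entry:
                cushion = read_pressure_map(entry["cushion"],
                                            tuple(entry.get("cushion_pitch", (10, 10))),
                                            "cushion")
            if "backrest" in entry:
                backrest = read_pressure_map(entry["backrest"],
                                             tuple(entry.get("backrest_pitch", (10, 10))),
                                             "backrest")
            if "spine" in entry:
                spine = read_spine(entry["spine"])
            results.append(analyze_condition(
                kind, float(entry["angle"]),
                cushion=cushion, backrest=backrest,
                cushion_split_row=parts.get("cushion_split_row"),
                backrest_l1_row=parts.get("backrest_l1_row"),
                spine=spine, internal=entry.get("internal"),
                threshold=threshold, ideal_ranges=ideal,
            ))
    if not results:
        raise ErgoseatError("configuration produced no conditions")

    comparisons = []
    for comp in config.get("comparisons", []):
        comparisons.append({
            "metric": comp["metric"],
            "simulated": _fmt(float(comp["simulated"])),
            "experimental": _fmt(float(comp["experimental"])),
            "percent_deviation": _fmt(percent_deviation(float(comp["simulated"]),
                                                        float(comp["experimental"]))),
        })

    report = {
        "config": {
            "kind": kind.value,
            "threshold": threshold,
            "partitions": {k: int(v) for k, v in parts.items()},
            "ideal_ranges": {str(k): [float(x) for x in v]
                             for k, v in (ideal or pm.DEFAULT_IDEAL_RANGES).items()},
        },
        "conditions": [_condition_to_block(r) for r in results],
        "trend_matrix": _trend_matrix(results),
        "comparisons": comparisons,
    }
    ReportSchema.model_validate(report)  # schema check before anything hits disk

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")

    rows = []
    for block in report["conditions"]:
        for region, m in block["regions"].items():
            rows.append({"angle": block["angle"], "region": region, **m})
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False,
                              float_format="%.10g")
    trows = []
    for region, metrics in report["trend_matrix"].items():
        for metric, row in metrics.items():
            for iname, val in row.items():
                trows.append({"region": region, "surface_metric": metric,
                              "internal_response": iname, "rank_correlation": val})
    pd.DataFrame(trows).to_csv(out_dir / "trends.csv", index=False,
                               float_format="%.10g")
    return report
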