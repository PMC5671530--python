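"""Four-stage pipeline: macro solve -> ROI modal stresses -> capillary
structural + diffusion solves -> oxygenation report.

The pressure stress factor K_P of the extended Fick's law has no literature
value; unless fixed in the config it is calibrated once so that a chosen
reference layer (default: the 0 mm beneath-wound layer at 125 mmHg)
reproduces a prescribed oxygenated-area decrease (default 73%), and then held
fixed for every other layer and suction level (calibrate-on-one,
predict-the-rest).

At zero suction the macro stress field vanishes; the coupled state then
coincides with the uncoupled reference by definition and all area changes are
reported as exactly 0%.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .capillary import (
    CapillaryGeometry,
    CapillaryLoadCase,
    build_capillary_mesh,
    solve_capillary,
)
from .diffusion import ConcentrationField, DiffusionParams, DiffusionSystem, area_change
from .geometry import LimbGeometryParams, MeshOptions, ROILayerSpec, build_limb_geometry, define_roi_layers
from .macro import NPWTLoadCase, max_deformation, solve_macro, wound_area_change
from .roi import roi_modal_pairs

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationSpec",
    "PipelineConfig",
    "run_pipeline",
    "run_parametric_study",
    "default_roi_specs",
]


def default_roi_specs() -> tuple[ROILayerSpec, ...]:
    """Beneath-wound layers at 0/10/15 mm and beside-wound at 0/5/10 mm."""
    return tuple(
        [ROILayerSpec("beneath_wound", off) for off in (0.0, 10.0, 15.0)]
        + [ROILayerSpec("beside_wound", off) for off in (0.0, 5.0, 10.0)]
    )


@dataclass(frozen=True)
class CalibrationSpec:
    """Reference case pinning K_P: layer label, suction level, target decrease (%)."""

    layer: str = "beneath_wound:0mm"
    suction: float = 125.0
    target_decrease_pct: float = 73.0


@dataclass(frozen=True)
class PipelineConfig:
    """Complete configuration of one pipeline run (YAML-serialisable)."""

    geometry: LimbGeometryParams = field(default_factory=LimbGeometryParams)
    mesh: MeshOptions = field(default_factory=MeshOptions)
    suction_levels: tuple = (70.0, 125.0, 150.0)
    roi_specs: tuple = field(default_factory=default_roi_specs)
    histogram_rule: str | int = "fd"
    area_weighted: bool = False
    capillary: CapillaryGeometry = field(default_factory=CapillaryGeometry)
    luminal_pressure_kpa: float = 0.5
    capillary_n_theta: int = 48
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    k_p: float | None = None  # None -> calibrate
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    classify: bool = True
    pattern_threshold_pct: float = 5.0
    macro_steps: int = 10
    random_seed: int = 0
    output_dir: str | None = None

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_specs"] = [dataclasses.asdict(s) for s in self.roi_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("geometry", LimbGeometryParams),
            ("mesh", MeshOptions),
            ("capillary", CapillaryGeometry),
            ("diffusion", DiffusionParams),
            ("calibration", CalibrationSpec),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "roi_specs" in d:
            d["roi_specs"] = tuple(
                ROILayerSpec(**s) if isinstance(s, dict) else s for s in d["roi_specs"]
            )
        if "suction_levels" in d:
            d["suction_levels"] = tuple(float(s) for s in d["suction_levels"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            random_seed=int(seed),
            mesh=replace(self.mesh, seed=int(seed)),
        )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _spec_by_label(config: PipelineConfig) -> dict:
    return {s.label: s for s in config.roi_specs}


def run_pipeline(config: PipelineConfig | None = None):
    """Run the full multiscale chain; returns an :class:`~npwtox.model.NPWTResults`."""
    from .model import NPWTResults

    cfg = config or PipelineConfig()
    log.info("pipeline start: suction levels %s", cfg.suction_levels)
    mesh = build_limb_geometry(cfg.geometry, cfg.mesh)
    roi_map = define_roi_layers(mesh, cfg.roi_specs)
    cap_mesh = build_capillary_mesh(cfg.capillary, n_theta=cfg.capillary_n_theta)
    dsys = DiffusionSystem(cap_mesh, cfg.diffusion)

    macro = {}
    deformation_rows = []
    modal_rows = []
    for s in cfg.suction_levels:
        res = solve_macro(mesh, NPWTLoadCase(s), n_steps=cfg.macro_steps)
        pairs = roi_modal_pairs(res, roi_map, cfg.histogram_rule, cfg.area_weighted)
        macro[s] = (res, pairs)
        deformation_rows.append(
            {
                "suction_mmHg": s,
                "max_deformation_mm": max_deformation(res),
                "wound_area_change_pct": wound_area_change(res),
            }
        )
        for label, p in pairs.items():
            modal_rows.append(
                {
                    "suction_mmHg": s,
                    "layer": label,
                    "sigma_max_MPa": p["sigma_max"],
                    "sigma_min_MPa": p["sigma_min"],
                    "n_elements": p["n"],
                }
            )
        log.info("macro %.0f mmHg done (max deformation %.3f mm)", s, deformation_rows[-1]["max_deformation_mm"])

    # capillary structural solves per (suction, layer)
    p_fields = {}
    for s, (res, pairs) in macro.items():
        for label, p in pairs.items():
            if s == 0.0:
                continue
            load = CapillaryLoadCase(
                p["sigma_max"], p["sigma_min"], cfg.luminal_pressure_kpa
            )
            capres = solve_capillary(cap_mesh, load)
            p_fields[(s, label)] = capres.pressure()

    baseline = dsys.solve(None, 0.0)
    f_base = dsys.oxygenated_area(baseline)

    # K_P: fixed or calibrated on the reference case
    if cfg.k_p is not None:
        k_p = float(cfg.k_p)
        calibrated = False
    else:
        cal = cfg.calibration
        key = (cal.suction, cal.layer)
        if key not in p_fields:
            raise ValueError(
                f"calibration case {key} not among the computed cases; "
                "add the suction level and ROI layer to the config"
            )
        k_p = calibrate_k_p(dsys, p_fields[key], cal.target_decrease_pct)
        calibrated = True
        log.info("calibrated K_P = %.4g cm^2/s on %s @ %.0f mmHg", k_p, cal.layer, cal.suction)

    # classification machinery (linearised unit responses)
    unit = _unit_responses(cap_mesh, dsys, cfg) if cfg.classify else None

    specs = _spec_by_label(cfg)
    oxy_rows = []
    fields = {}
    for s, (res, pairs) in macro.items():
        for label, pr in pairs.items():
            spec = specs[label]
            if s == 0.0:
                row = {
                    "suction_mmHg": s,
                    "layer": label,
                    "direction": spec.direction,
                    "offset_mm": spec.offset,
                    "baseline_frac": f_base,
                    "coupled_frac": f_base,
                    "change_pct": 0.0,
                    "decrease_pct": 0.0,
                    "pattern": "homogeneous",
                    "increase_component_pct": 0.0,
                    "decrease_component_pct": 0.0,
                }
                oxy_rows.append(row)
                continue
            coupled = dsys.solve(p_fields[(s, label)], k_p)
            f_c = dsys.oxygenated_area(coupled)
            ch = area_change(f_c, f_base)
            row = {
                "suction_mmHg": s,
                "layer": label,
                "direction": spec.direction,
                "offset_mm": spec.offset,
                "baseline_frac": f_base,
                "coupled_frac": f_c,
                "change_pct": ch,
                "decrease_pct": -ch,
            }
            if unit is not None:
                smax, _, smin = res.principal()
                ids = roi_map[label]
                row.update(
                    _classify_layer(
                        dsys, unit, baseline, f_base, k_p,
                        smax[ids], smin[ids], cfg.pattern_threshold_pct,
                    )
                )
            else:
                row.update(
                    {
                        "pattern": "homogeneous",
                        "increase_component_pct": max(ch, 0.0),
                        "decrease_component_pct": max(-ch, 0.0),
                    }
                )
            oxy_rows.append(row)
            fields[(s, label)] = coupled

    results = NPWTResults(
        config=cfg,
        k_p=k_p,
        k_p_calibrated=calibrated,
        deformation=pd.DataFrame(deformation_rows),
        modal_stresses=pd.DataFrame(modal_rows),
        oxygenation=pd.DataFrame(oxy_rows),
        baseline_fraction=f_base,
        _macro={s: r for s, (r, _) in macro.items()},
        _mesh=mesh,
        _cap_mesh=cap_mesh,
        _baseline_field=baseline,
        _coupled_fields=fields,
        _roi_map=roi_map,
    )
    if cfg.output_dir:
        results.save(cfg.output_dir)
    return results


def calibrate_k_p(
    dsys: DiffusionSystem, p_field: np.ndarray, target_decrease_pct: float
) -> float:
    """K_P (cm²/s) whose coupled run loses ``target_decrease_pct`` of the
    baseline oxygenated area, by superposition + Brent root finding."""
    base, unit = dsys.baseline_and_unit_drift(p_field)
    f_base = dsys.oxygenated_area(base)

    def decrease(kp: float) -> float:
        c = ConcentrationField(dsys.mesh, base.values + kp * unit.values, dsys.params, base.tau)
        return -area_change(dsys.oxygenated_area(c), f_base)

    lo, hi = 0.0, 1.0e-7
    for _ in range(60):
        if decrease(hi) >= target_decrease_pct:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"target decrease {target_decrease_pct}% unreachable "
            f"(max {decrease(hi):.1f}% at K_P={hi:g})"
        )
    return float(brentq(lambda k: decrease(k) - target_decrease_pct, lo, hi, xtol=1e-14, rtol=1e-10))


# ---------------------------------------------------------------------------
# heterogeneity classification (linearised)
# ---------------------------------------------------------------------------


def _unit_responses(cap_mesh, dsys: DiffusionSystem, cfg: PipelineConfig):
    """Unit capillary p fields and their unit-drift concentration responses.

    Linearises the capillary chain around zero load: p(sigma1, sigma3) ≈
    sigma1*pA + sigma3*pB + pL, and the drift response inherits the same
    superposition. Unit loads are 0.01 MPa (small enough for linearity).
    """
    u0 = 0.01
    pA = solve_capillary(cap_mesh, CapillaryLoadCase(u0, 0.0, 0.0)).pressure() / u0
    pB = solve_capillary(cap_mesh, CapillaryLoadCase(0.0, u0, 0.0)).pressure() / u0
    pL = solve_capillary(
        cap_mesh, CapillaryLoadCase(0.0, 0.0, cfg.luminal_pressure_kpa)
    ).pressure()
    out = {}
    for name, pf in (("A", pA), ("B", pB), ("L", pL)):
        b = dsys.drift_source(dsys.project_pressure(pf), 1.0)
        cu, _, _ = dsys._march(np.zeros(dsys.nn), b, 0.0, dsys.params.tau_end, dsys.params.dtau)
        out[name] = cu
    return out


def _classify_layer(dsys, unit, baseline, f_base, k_p, smax, smin, thr_pct):
    """Per-element linearised area changes -> pattern label + signed components."""
    changes = np.empty(len(smax))
    for i, (s1, s3) in enumerate(zip(smax, smin)):
        c = baseline.values + k_p * (s1 * unit["A"] + s3 * unit["B"] + unit["L"])
        f = dsys.oxygenated_area(
            ConcentrationField(dsys.mesh, c, dsys.params, baseline.tau)
        )
        changes[i] = area_change(f, f_base)
    pos = changes[changes > thr_pct]
    neg = changes[changes < -thr_pct]
    pattern = "heterogeneous" if (len(pos) and len(neg)) else "homogeneous"
    return {
        "pattern": pattern,
        "increase_component_pct": float(pos.mean()) if len(pos) else 0.0,
        "decrease_component_pct": float(-neg.mean()) if len(neg) else 0.0,
    }


# ---------------------------------------------------------------------------
# Parametric study
# ---------------------------------------------------------------------------


def run_parametric_study(
    base: PipelineConfig | None = None,
    aspect_ratios=None,
    edge_shapes=None,
    suctions=None,
) -> pd.DataFrame:
    """Macro-only sweep over wound aspect ratio, edge shape and suction.

    ``aspect_ratios`` are wound radius-to-depth ratios realised at constant
    cavity volume (the base config's pi*r^2*d). Relative differences in
    maximum deformation are reported against the first variant at the same
    suction. Per-variant failures are recorded and the study continues.
    """
    cfg = base or PipelineConfig()
    g0 = cfg.geometry
    vol = np.pi * g0.wound_radius**2 * g0.wound_depth
    aspect_ratios = list(aspect_ratios) if aspect_ratios else [None]
    edge_shapes = list(edge_shapes) if edge_shapes else [g0.edge_shape]
    suctions = list(suctions) if suctions else list(cfg.suction_levels)

    rows = []
    for s in suctions:
        ref_def = None
        for ar, shape in itertools.product(aspect_ratios, edge_shapes):
            if ar is None:
                r_w, d_w = g0.wound_radius, g0.wound_depth
                ar_label = g0.wound_radius / g0.wound_depth
            else:
                d_w = (vol / (np.pi * ar**2)) ** (1.0 / 3.0)
                r_w = ar * d_w
                ar_label = ar
            row = {
                "suction_mmHg": s,
                "aspect_ratio": ar_label,
                "edge_shape": shape,
                "wound_radius_cm": r_w,
                "wound_depth_cm": d_w,
            }
            try:
                geom = replace(g0, wound_radius=r_w, wound_depth=d_w, edge_shape=shape)
                mesh = build_limb_geometry(geom, cfg.mesh)
                res = solve_macro(mesh, NPWTLoadCase(s), n_steps=cfg.macro_steps)
                row["max_deformation_mm"] = max_deformation(res)
                row["wound_area_change_pct"] = wound_area_change(res)
                row["error"] = ""
            except Exception as exc:  # study continues past failed variants
                row["max_deformation_mm"] = np.nan
                row["wound_area_change_pct"] = np.nan
                row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                continue
            if ref_def is None:
                ref_def = row["max_deformation_mm"]
                row["rel_diff_vs_first_pct"] = 0.0
            else:
                row["rel_diff_vs_first_pct"] = 100.0 * (
                    row["max_deformation_mm"] - ref_def
                ) / ref_def
            rows.append(row)
    return pd.DataFrame(rows)
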