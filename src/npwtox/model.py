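"""Model/results objects: the user-facing surface of the package.

``NPWTModel`` holds a validated :class:`~npwtox.pipeline.PipelineConfig` and
its ``fit()`` executes the multiscale chain, returning an ``NPWTResults``
carrying the deformation, modal-stress and oxygenation tables, the calibrated
pressure stress factor, and plotting/export helpers — in the spirit of
statsmodels' Model/Results split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, run_pipeline, run_parametric_study

__all__ = ["NPWTModel", "NPWTResults"]


class NPWTModel:
    """Multiscale NPWT model of a residual limb.

    Parameters
    ----------
    config : PipelineConfig, optional
        Full configuration; keyword overrides are applied on top of it
        (e.g. ``NPWTModel(suction_levels=(125.0,))``).
    """

    def __init__(self, config: PipelineConfig | None = None, **overrides):
        cfg = config or PipelineConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg

    @classmethod
    def from_yaml(cls, path) -> "NPWTModel":
        return cls(PipelineConfig.from_yaml(path))

    def fit(self) -> "NPWTResults":
        """Run macro FE, ROI extraction, capillary and diffusion stages."""
        return run_pipeline(self.config)

    def parametric_study(self, aspect_ratios=None, edge_shapes=None, suctions=None):
        """Macro-only sweep; see :func:`npwtox.pipeline.run_parametric_study`."""
        return run_parametric_study(self.config, aspect_ratios, edge_shapes, suctions)


@dataclass
class NPWTResults:
    """Fitted multiscale state with summary, export and plotting helpers."""

    config: PipelineConfig
    k_p: float
    k_p_calibrated: bool
    deformation: pd.DataFrame
    modal_stresses: pd.DataFrame
    oxygenation: pd.DataFrame
    baseline_fraction: float
    _macro: dict = field(default_factory=dict, repr=False)
    _mesh: object = None
    _cap_mesh: object = None
    _baseline_field: object = None
    _coupled_fields: dict = field(default_factory=dict, repr=False)
    _roi_map: dict = field(default_factory=dict, repr=False)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted multiscale model."""
        cfg = self.config
        g = cfg.geometry
        lines = [
            "=" * 72,
            "NPWT multiscale model results".center(72),
            "=" * 72,
            f"Geometry: limb L={g.limb_length:g} cm, muscle R={g.muscle_radius:g} cm, "
            f"wound r={g.wound_radius:g} cm x d={g.wound_depth:g} cm ({g.edge_shape} edges)",
            f"Pressure stress factor K_P = {self.k_p:.4g} cm^2/s "
            + ("(calibrated)" if self.k_p_calibrated else "(fixed)"),
            f"Baseline oxygenated tissue-area fraction = {self.baseline_fraction:.4f} "
            f"(threshold {cfg.diffusion.threshold:g} uM at tau={cfg.diffusion.tau_end:g})",
            "-" * 72,
            "Macro deformation and wound contraction:",
            self.deformation.to_string(index=False, float_format=lambda v: f"{v:8.3f}"),
            "-" * 72,
            "Oxygenated-area change per ROI layer (negative = decrease):",
            self.oxygenation[
                [
                    "suction_mmHg",
                    "direction",
                    "offset_mm",
                    "change_pct",
                    "pattern",
                ]
            ].to_string(index=False, float_format=lambda v: f"{v:8.2f}"),
            "=" * 72,
        ]
        return "\n".join(lines)

    # -- artifact export ----------------------------------------------------

    def save(self, outdir) -> Path:
        """Write CSV/JSON/VTU/PNG artifacts; returns the output directory."""
        from . import io
        from .diffusion import export_binary_mask
        from .fem import pressure_stress, principal_stresses

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.deformation.to_csv(out / "deformation.csv", index=False)
        self.modal_stresses.to_csv(out / "modal_stresses.csv", index=False)
        self.oxygenation.to_csv(out / "oxygenation.csv", index=False)
        io.write_json(
            out / "report.json",
            {
                "k_p_cm2_per_s": self.k_p,
                "k_p_calibrated": self.k_p_calibrated,
                "baseline_oxygenated_fraction": self.baseline_fraction,
                "deformation": self.deformation.to_dict(orient="records"),
                "oxygenation": self.oxygenation.to_dict(orient="records"),
            },
        )
        # modal hand-off (roi_stats -> capillary_meso contract)
        io.write_json(
            out / "modal_handoff.json",
            self.modal_stresses.to_dict(orient="records"),
        )
        for s, res in self._macro.items():
            smax, smid, smin = res.principal()
            io.write_vtu(
                out / f"macro_{s:g}mmHg.vtu",
                res.mesh,
                point_data={"displacement_m": res.u, "magnitude_m": res.solution.magnitude},
                cell_data={
                    "sigma_max_MPa": smax,
                    "sigma_min_MPa": smin,
                    "pressure_stress_MPa": res.pressure(),
                },
            )
        if self._baseline_field is not None:
            export_binary_mask(self._baseline_field, path=out / "mask_baseline.png")
            for (s, label), fld in self._coupled_fields.items():
                tag = label.replace(":", "_")
                export_binary_mask(fld, path=out / f"mask_{s:g}mmHg_{tag}.png")
        self.config.to_yaml(out / "config.yaml")
        return out

    # -- plots --------------------------------------------------------------

    def plot_contraction(self, ax=None):
        """Wound-area reduction and max deformation vs suction level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.deformation.sort_values("suction_mmHg")
        ax.plot(d.suction_mmHg, d.wound_area_change_pct, "o-", label="wound area change (%)")
        ax.set_xlabel("suction (mmHg)")
        ax.set_ylabel("wound area reduction (%)")
        ax2 = ax.twinx()
        ax2.plot(d.suction_mmHg, d.max_deformation_mm, "s--", color="C1", label="max deformation (mm)")
        ax2.set_ylabel("max deformation (mm)")
        ax.figure.legend(loc="upper left")
        return ax

    def plot_oxygenation(self, ax=None):
        """Bar chart of oxygenated-area change per ROI layer and suction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.oxygenation.copy()
        d["label"] = d.direction.str.replace("_wound", "") + " " + d.offset_mm.astype(str) + " mm"
        for i, (s, grp) in enumerate(d.groupby("suction_mmHg")):
            ax.bar(
                np.arange(len(grp)) + 0.25 * i,
                grp.change_pct,
                width=0.22,
                label=f"{s:g} mmHg",
            )
        ax.set_xticks(np.arange(d.label.nunique()))
        ax.set_xticklabels(d.label.unique(), rotation=30, ha="right")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel("oxygenated-area change (%)")
        ax.legend()
        return ax
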