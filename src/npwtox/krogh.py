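"""Axial solute balance along the capillary (Krogh cylinder, closed form).

A 1-mm capillary with parabolic (Poiseuille) flow at centreline velocity
``V_max`` delivers oxygen to its tissue sleeve at a zeroth-order rate M per
unit tissue volume. A balance over a slice dz gives a linearly decreasing
luminal concentration

    C(z) = C_in - M * (R_t^2 - R_c^2) * z / (R_c^2 * v_bar),

with mean velocity ``v_bar = V_max/2``. The tissue consumption rate is not a
printed constant; instead :func:`calibrate_consumption` inverts the profile so
that the mid-length wall concentration matches a prescribed value (40.32 µM by
default downstream), which the diffusion model then uses as its wall boundary
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import UM

__all__ = ["AxialTransportParams", "axial_profile", "calibrate_consumption"]


@dataclass(frozen=True)
class CapillaryGeometry:
    """Krogh-cylinder cross-section (µm): lumen, wall, tissue sleeve."""

    lumen_radius: float = 5.0
    wall_thickness: float = 0.5
    tissue_outer_radius: float = 40.0

    def __post_init__(self) -> None:
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be >= 0")
        if self.lumen_radius + self.wall_thickness >= self.tissue_outer_radius:
            raise ValueError("tissue outer radius must exceed lumen + wall")

    @property
    def wall_outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness


@dataclass(frozen=True)
class AxialTransportParams:
    """Inputs of the axial balance (µM, m/s, mm; M in µM/s)."""

    c_in: float = 120.0
    v_max: float = 0.0005
    length: float = 1.0
    consumption_m: float = 0.0
    geometry: CapillaryGeometry = field(default_factory=CapillaryGeometry)
    plug_flow: bool = False

    def __post_init__(self) -> None:
        if self.c_in <= 0 or self.v_max <= 0 or self.length <= 0:
            raise ValueError("c_in, v_max and length must be positive")
        if self.consumption_m < 0:
            raise ValueError("consumption rate must be >= 0")

    @property
    def mean_velocity(self) -> float:
        """m/s; V_max/2 for parabolic flow, V_max for plug flow."""
        return self.v_max if self.plug_flow else self.v_max / 2.0

    @property
    def drop_per_mm(self) -> float:
        """Concentration decrease per mm of capillary length (µM/mm)."""
        g = self.geometry
        rc = g.lumen_radius * UM
        rt = g.tissue_outer_radius * UM
        return self.consumption_m * (rt**2 - rc**2) / (rc**2 * self.mean_velocity) * 1.0e-3


def axial_profile(params: AxialTransportParams, z):
    """Luminal O2 concentration (µM) at axial position z (mm from inlet)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > params.length):
        raise ValueError(f"z must lie in [0, {params.length}] mm")
    c = params.c_in - params.drop_per_mm * z
    return c[()] if c.ndim == 0 else c


def calibrate_consumption(
    params: AxialTransportParams, target_wall_conc: float, z_eval: float | None = None
) -> float:
    """Consumption rate M (µM/s) that puts C(z_eval) at the target value.

    ``z_eval`` defaults to mid-length. Closed-form inversion of the linear
    profile; raises if the target is not below the inlet concentration.
    """
    if not 0.0 < target_wall_conc < params.c_in:
        if target_wall_conc == params.c_in:
            return 0.0
        raise ValueError("target must satisfy 0 < target < C_in")
    z = params.length / 2.0 if z_eval is None else float(z_eval)
    if not 0 < z <= params.length:
        raise ValueError("z_eval must lie in (0, length]")
    g = params.geometry
    rc = g.lumen_radius * UM
    rt = g.tissue_outer_radius * UM
    drop = params.c_in - target_wall_conc  # µM over z mm
    return drop / z * 1.0e3 * rc**2 * params.mean_velocity / (rt**2 - rc**2)
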