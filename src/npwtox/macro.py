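"""Macro-scale NPWT load case: the axisymmetric limb under suction.

Loads follow the therapy's physics: the sealed foam transmits the applied
vacuum, so the wound's lateral and bottom faces see an outward (suction)
traction of the set magnitude, while the drape presses the exposed foam top
inward with the atmospheric differential (equal to the suction level by
default). The proximal end is encastre, the rigid femur is a fixed boundary,
muscle-foam and muscle-bone interfaces are tied (shared mesh nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import materials as mat
from .fem import FESolution, NonlinearFE, principal_stresses, pressure_stress
from .geometry import Mesh
from .units import mmhg_to_mpa

__all__ = [
    "NPWTLoadCase",
    "MacroResult",
    "solve_macro",
    "max_deformation",
    "wound_area_change",
    "DEFAULT_MATERIALS",
]

DEFAULT_MATERIALS: Mapping[str, object] = {
    "muscle": mat.MUSCLE,
    "filler": mat.PU_FOAM,
}


@dataclass(frozen=True)
class NPWTLoadCase:
    """Suction magnitude in mmHg (positive number = vacuum level).

    ``atmospheric_on_filler_top`` is the pressure differential pressing the
    drape/foam top inward; ``None`` means equal to the suction level (sealed
    dressing at the set vacuum). Conversion to MPa is exact (133.322 Pa/mmHg).
    """

    suction: float
    atmospheric_on_filler_top: float | None = None

    @property
    def suction_mpa(self) -> float:
        return mmhg_to_mpa(self.suction)

    @property
    def top_mpa(self) -> float:
        top = (
            self.suction
            if self.atmospheric_on_filler_top is None
            else self.atmospheric_on_filler_top
        )
        return mmhg_to_mpa(top)


@dataclass
class MacroResult:
    """Solved macro state: displacements plus centroid stress fields."""

    mesh: Mesh
    load: NPWTLoadCase
    solution: FESolution
    sigma: np.ndarray  # (E, 2, 2) in-plane Cauchy block, MPa
    sigma_hoop: np.ndarray  # (E,)

    @property
    def u(self) -> np.ndarray:
        return self.solution.u

    def principal(self):
        """(sigma_max, sigma_mid, sigma_min) per element, MPa."""
        return principal_stresses(self.sigma, self.sigma_hoop)

    def pressure(self) -> np.ndarray:
        """Equivalent pressure stress p = -tr(sigma)/3 per element, MPa."""
        return pressure_stress(self.sigma, self.sigma_hoop)


def build_problem(
    mesh: Mesh,
    load: NPWTLoadCase,
    materials: Mapping[str, object] | None = None,
) -> NonlinearFE:
    materials = dict(materials or DEFAULT_MATERIALS)
    fe = NonlinearFE(mesh, materials, mode="axisymmetric")
    fe.fix(mesh.facet_nodes("proximal_end"), (0, 1))
    fe.fix(mesh.facet_nodes("bone_interface"), (0, 1))
    fe.fix(mesh.facet_nodes("symmetry_axis"), 0)
    if load.suction != 0.0:
        # suction = negative pressure on the wound faces (pulls tissue inward,
        # i.e. along the outward normal of the muscle surface)
        for name in ("wound_lateral", "wound_bottom"):
            fe.add_pressure(mesh.facets[mesh.facet_ids(name)], -load.suction_mpa)
    if load.top_mpa != 0.0 and len(mesh.facet_ids("filler_top")):
        fe.add_pressure(mesh.facets[mesh.facet_ids("filler_top")], load.top_mpa)
    return fe


def solve_macro(
    mesh: Mesh,
    load: NPWTLoadCase,
    materials: Mapping[str, object] | None = None,
    n_steps: int = 10,
    tol: float = 1.0e-8,
) -> MacroResult:
    """Nonlinear static solve of the limb under the given NPWT load."""
    fe = build_problem(mesh, load, materials)
    sol = fe.solve(n_steps=n_steps, tol=tol)
    sig2, sig33 = fe.element_stress(sol.u)
    return MacroResult(mesh, load, sol, sig2, sig33)


def max_deformation(result: MacroResult) -> float:
    """Maximum displacement magnitude over muscle nodes, in mm."""
    muscle_nodes = np.unique(result.mesh.elements[result.mesh.region_ids("muscle")])
    return float(result.solution.magnitude[muscle_nodes].max() * 1.0e3)


def wound_area_change(result: MacroResult) -> float:
    """Relative reduction of the wound opening area, percent.

    The deformed opening area is computed from the displaced wound-edge rim
    node (axisymmetric: the node at (r_w, z=0)); returns 100*(A0 - A)/A0,
    positive when the wound contracts.
    """
    mesh = result.mesh
    p = mesh.metadata["geometry"]
    if p.wound_radius <= 0:
        raise ValueError("no wound cavity in this geometry")
    if result.load.suction == 0.0 and result.load.top_mpa == 0.0:
        return 0.0
    from .units import CM

    rim = np.array([p.wound_radius * CM, 0.0])
    d2 = np.sum((mesh.nodes - rim) ** 2, axis=1)
    node = int(np.argmin(d2))
    r0 = mesh.nodes[node, 0]
    r1 = r0 + result.u[node, 0]
    return float(100.0 * (r0**2 - r1**2) / r0**2)
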