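"""Meso-scale structural model of one capillary cross-section.

A plane-strain Krogh-cylinder cross-section: circular lumen (radius 5 µm),
hyperelastic wall (0.5 µm), and muscle tissue out to the 40 µm Krogh radius,
embedded in a square frame of tissue (side 2.2 x Krogh radius) on which the
ROI modal principal stresses are applied as uniform normal tractions — the
modal sigma_max on the vertical (x-normal) edge pair, sigma_min on the
horizontal pair. A constant luminal pressure (0.5 kPa by default) models the
static blood pressure. Plane strain is chosen because a capillary is long and
axially constrained.

The mesh is a structured polar grid (rings x sectors) with an O-grid
transition from the Krogh circle to the square frame; its structure is kept
in the metadata for rasterisation and symmetry mappings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import materials as mat
from .fem import FESolution, NonlinearFE, pressure_stress, principal_stresses
from .geometry import Mesh, graded_points
from .krogh import CapillaryGeometry
from .units import UM

__all__ = [
    "CapillaryGeometry",
    "CapillaryLoadCase",
    "CapillaryResult",
    "build_capillary_mesh",
    "solve_capillary",
    "DEFAULT_CAPILLARY_MATERIALS",
]

DEFAULT_CAPILLARY_MATERIALS = {
    "wall": mat.CAPILLARY_WALL,
    "tissue": mat.MUSCLE,
}

WALL_CODE, TISSUE_CODE = 1, 2
_CAP_TAGS = {1: "lumen_surface", 2: "outer_boundary", 3: "load_x", 4: "load_y"}


@dataclass(frozen=True)
class CapillaryLoadCase:
    """Far-field modal stresses (MPa, tension positive) + luminal pressure (kPa)."""

    far_field_sigma_max: float = 0.0
    far_field_sigma_min: float = 0.0
    luminal_pressure: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.far_field_sigma_max, self.far_field_sigma_min, self.luminal_pressure):
            if not np.isfinite(v):
                raise ValueError("load values must be finite")

    @property
    def luminal_mpa(self) -> float:
        return self.luminal_pressure * 1.0e-3


def build_capillary_mesh(
    geom: CapillaryGeometry | None = None,
    n_theta: int = 48,
    h_wall: float = 0.25,
    h_tissue: float = 3.0,
    frame: bool = True,
    frame_ratio: float = 1.1,
    n_frame: int = 4,
    refine: float = 1.0,
) -> Mesh:
    """Structured quad mesh of the capillary cross-section (metres).

    ``frame=False`` gives the bare wall+tissue annulus with a free circular
    outer boundary (used for Lame-type verification); otherwise the annulus is
    embedded in tissue filling a square frame of half-side
    ``frame_ratio * tissue_outer_radius``. ``n_theta`` must be a multiple of 8
    so that mesh lines lie on both symmetry axes and the diagonals.
    """
    g = geom or CapillaryGeometry()
    if n_theta % 8:
        raise ValueError("n_theta must be a multiple of 8")
    n_theta = int(n_theta * refine) // 8 * 8
    h_wall = h_wall / refine
    h_tissue = h_tissue / refine

    rl, rw, rt = g.lumen_radius, g.wall_outer_radius, g.tissue_outer_radius
    radii = [np.array([rl])] if g.wall_thickness == 0 else [
        graded_points(rl, rw, h_wall, h_wall)
    ]
    radii.append(graded_points(rw, rt, min(2.0 * h_wall, h_tissue), h_tissue))
    ring_r = np.concatenate([radii[0], radii[1][1:]]) if g.wall_thickness else np.concatenate(
        [radii[0], radii[1][1:]]
    )
    n_annulus = len(ring_r)

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)

    rings = [r * np.stack([ct, st], axis=1) for r in ring_r]
    if frame:
        s = frame_ratio * rt
        rho_sq = s / np.maximum(np.abs(ct), np.abs(st))
        for k in range(1, int(n_frame * refine) + 1):
            t = k / float(int(n_frame * refine))
            rho = (1.0 - t) * rt + t * rho_sq
            rings.append(np.stack([rho * ct, rho * st], axis=1))
    nodes = np.concatenate(rings, axis=0)
    n_rings = len(rings)

    def nid(i, j):
        return i * n_theta + (j % n_theta)

    quads, region = [], []
    for i in range(n_rings - 1):
        mid_r = 0.5 * (np.linalg.norm(rings[i][0]) + np.linalg.norm(rings[i + 1][0]))
        code = WALL_CODE if (g.wall_thickness > 0 and mid_r < rw) else TISSUE_CODE
        for j in range(n_theta):
            quads.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
            region.append(code)
    quads = np.asarray(quads, dtype=int)
    region = np.asarray(region, dtype=int)

    # facets: inner ring (lumen) and outermost ring (square frame or circle)
    facets, tags = [], []
    for j in range(n_theta):
        facets.append((nid(0, j + 1), nid(0, j)))  # oriented: normal into lumen
        tags.append(1)
    outer = n_rings - 1
    s_half = frame_ratio * rt if frame else rt
    for j in range(n_theta):
        a, b = nid(outer, j), nid(outer, j + 1)
        facets.append((a, b))
        if not frame:
            tags.append(2)
        else:
            mx, my = 0.5 * (nodes[a] + nodes[b])
            tags.append(3 if abs(mx) >= abs(my) - 1e-12 else 4)
    facets = np.asarray(facets, dtype=int)
    tags = np.asarray(tags, dtype=int)

    mesh = Mesh(
        nodes=nodes * UM,
        elements=quads,
        region=region,
        region_names={WALL_CODE: "wall", TISSUE_CODE: "tissue"},
        facets=facets,
        facet_tags=tags,
        facet_tag_names=dict(_CAP_TAGS),
        metadata={
            "geometry": g,
            "kind": "capillary",
            "n_theta": n_theta,
            "ring_radii_um": ring_r,
            "n_annulus_rings": n_annulus,
            "frame": frame,
        },
    )
    if np.any(mesh.element_areas() <= 0):
        raise RuntimeError("capillary mesh has inverted elements")
    return mesh


@dataclass
class CapillaryResult:
    """Solved capillary state: displacement, centroid stress and p field."""

    mesh: Mesh
    load: CapillaryLoadCase
    solution: FESolution
    sigma: np.ndarray
    sigma_zz: np.ndarray

    @property
    def u(self) -> np.ndarray:
        return self.solution.u

    def principal(self):
        return principal_stresses(self.sigma, self.sigma_zz)

    def pressure(self) -> np.ndarray:
        """Equivalent pressure stress p per element (MPa), Eq. p = -tr(sigma)/3."""
        return pressure_stress(self.sigma, self.sigma_zz)


def solve_capillary(
    mesh: Mesh,
    load: CapillaryLoadCase,
    materials=None,
    n_steps: int = 5,
    tol: float = 1.0e-8,
) -> CapillaryResult:
    """Plane-strain solve of the capillary cross-section under modal loads.

    The modal sigma_max traction acts on the x-normal frame edges, sigma_min
    on the y-normal pair (tension positive); luminal pressure pushes on the
    lumen surface. Symmetry of loads and geometry about both axes is used to
    suppress rigid-body modes (u_x = 0 on the x = 0 line, u_y = 0 on y = 0).
    """
    materials = dict(materials or DEFAULT_CAPILLARY_MATERIALS)
    if mesh.metadata.get("frame"):
        if "load_x" not in mesh.facet_tag_names.values():
            raise ValueError("frame mesh without load edges")
    fe = NonlinearFE(mesh, materials, mode="plane_strain")
    tol_geom = 1.0e-3 * UM
    on_x0 = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < tol_geom)
    on_y0 = np.flatnonzero(np.abs(mesh.nodes[:, 1]) < tol_geom)
    fe.fix(on_x0, 0)
    fe.fix(on_y0, 1)
    if load.luminal_pressure:
        fe.add_pressure(mesh.facets[mesh.facet_ids("lumen_surface")], load.luminal_mpa)
    if mesh.metadata.get("frame"):
        if load.far_field_sigma_max:
            fe.add_pressure(mesh.facets[mesh.facet_ids("load_x")], -load.far_field_sigma_max)
        if load.far_field_sigma_min:
            fe.add_pressure(mesh.facets[mesh.facet_ids("load_y")], -load.far_field_sigma_min)
    sol = fe.solve(n_steps=n_steps, tol=tol)
    sig2, sig33 = fe.element_stress(sol.u)
    return CapillaryResult(mesh, load, sol, sig2, sig33)
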