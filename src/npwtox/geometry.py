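"""Parametric axisymmetric residual-limb geometry, meshing and ROI layers.

The patient-specific 3D reconstruction is replaced by a 2D axisymmetric
surrogate: a cylindrical residual limb (rigid femur core, hyperelastic muscle
sleeve) with a circumferential distal wound cavity of configurable radius and
depth, filled by an identically sized polyurethane foam block. Coordinates are
``(r, z)`` with ``z = 0`` at the distal face and ``z = L`` at the proximal
(encastre) end; the mesh is stored in metres, geometry parameters are given
in centimetres.

The mesh is a structured, graded quadrilateral grid whose coordinate lines
pass exactly through the material breakpoints (bone radius, wound radius,
wound depth, bone tip), so region boundaries are conforming; round wound
edges are realised by remapping the cavity-floor grid line onto a fillet arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import CM, MM

__all__ = [
    "LimbGeometryParams",
    "MeshOptions",
    "Mesh",
    "ROILayerSpec",
    "build_limb_geometry",
    "wound_opening_area",
    "cavity_wall_area",
    "define_roi_layers",
    "graded_points",
]

MUSCLE, FILLER, WALL, TISSUE = 1, 2, 3, 4

REGION_NAMES = {MUSCLE: "muscle", FILLER: "filler", WALL: "wall", TISSUE: "tissue"}


@dataclass(frozen=True)
class LimbGeometryParams:
    """Axisymmetric residual-limb geometry (all lengths in cm).

    The wound cavity (radius ``wound_radius``, depth ``wound_depth``) is cut
    into the distal face around the axis and filled with foam. ``edge_shape``
    'round' fillets the cavity floor rim with ``edge_fillet_radius``.
    ``bone_tip_offset`` is the distance from the distal face to the resected
    femur tip (not printed in the source; surrogate default).
    """

    limb_length: float = 18.0
    muscle_radius: float = 7.0
    bone_radius: float = 1.5
    wound_radius: float = 3.6
    wound_depth: float = 0.8
    edge_shape: str = "sharp"
    edge_fillet_radius: float = 0.2
    bone_tip_offset: float = 3.0

    def __post_init__(self) -> None:
        p = self
        if min(p.limb_length, p.muscle_radius, p.bone_radius, p.wound_depth) <= 0:
            raise ValueError("all lengths must be positive")
        if p.wound_radius < 0:
            raise ValueError("wound_radius must be >= 0")
        if p.bone_radius >= p.muscle_radius:
            raise ValueError("bone_radius must be smaller than muscle_radius")
        if p.wound_radius >= p.muscle_radius:
            raise ValueError("wound cavity wider than the limb")
        if p.wound_depth >= p.limb_length:
            raise ValueError("wound cavity deeper than the limb")
        if p.wound_depth >= p.bone_tip_offset:
            raise ValueError("wound cavity would expose the bone tip")
        if p.bone_tip_offset >= p.limb_length:
            raise ValueError("bone tip offset exceeds limb length")
        if p.edge_shape not in ("round", "sharp"):
            raise ValueError("edge_shape must be 'round' or 'sharp'")
        if p.edge_shape == "round":
            if not 0 < p.edge_fillet_radius < min(p.wound_depth, p.wound_radius):
                raise ValueError("fillet radius must fit inside the cavity")

    @property
    def fillet(self) -> float:
        return self.edge_fillet_radius if self.edge_shape == "round" else 0.0

    def cavity_depth_at(self, r_cm):
        """Cavity floor depth d(r) in cm (0 outside the cavity)."""
        r = np.asarray(r_cm, dtype=float)
        d = np.where(r < self.wound_radius, self.wound_depth, 0.0)
        f = self.fillet
        if f > 0.0:
            r0 = self.wound_radius - f
            band = (r >= r0) & (r < self.wound_radius)
            arg = np.maximum(f**2 - (r - r0) ** 2, 0.0)
            d = np.where(band, self.wound_depth - f + np.sqrt(arg), d)
        return d[()] if d.ndim == 0 else d


@dataclass(frozen=True)
class MeshOptions:
    """Mesh-size controls (cm). ``scale`` > 1 refines everything uniformly.

    ``h_roi``/``roi_extent`` keep the element spacing below the default ROI
    layer thickness (2 mm) within ``roi_extent`` of the wound surfaces so that
    thin centroid-selected tissue layers are always resolved.
    """

    h_fine: float = 0.1
    h_mid: float = 0.3
    h_far: float = 0.5
    h_roi: float = 0.18
    roi_extent: float = 2.0
    scale: float = 1.0
    jitter: float = 0.0
    seed: int = 0

    def sized(self) -> tuple[float, float, float, float]:
        s = self.scale
        return self.h_fine / s, self.h_mid / s, self.h_far / s, self.h_roi / s


@dataclass
class Mesh:
    """Unstructured quadrilateral mesh with region and boundary tags.

    ``nodes`` are (N, 2) coordinates in metres; ``elements`` (E, 4) node
    indices (counter-clockwise); ``region`` per-element integer codes named in
    ``region_names``. ``facets`` are (F, 2) boundary/interface segments,
    oriented so that the right-hand normal ``(dz, -dr)`` points out of the
    owning region; ``facet_tags`` label them via ``facet_tag_names``.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    region_names: dict
    facets: np.ndarray
    facet_tags: np.ndarray
    facet_tag_names: dict
    metadata: dict = field(default_factory=dict)

    # -- basic measures -----------------------------------------------------

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]

    def element_centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def element_areas(self) -> np.ndarray:
        xy = self.element_coords()
        x, y = xy[..., 0], xy[..., 1]
        x2, y2 = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * y2 - x2 * y, axis=1)

    def region_ids(self, name: str) -> np.ndarray:
        code = {v: k for k, v in self.region_names.items()}[name]
        return np.flatnonzero(self.region == code)

    def facet_ids(self, name: str) -> np.ndarray:
        code = {v: k for k, v in self.facet_tag_names.items()}[name]
        return np.flatnonzero(self.facet_tags == code)

    def facet_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.facets[self.facet_ids(name)])

    def revolved_volume(self, name: str | None = None) -> float:
        """Solid-of-revolution volume (m^3) by Pappus' theorem (exact for polygons)."""
        ids = np.arange(len(self.elements)) if name is None else self.region_ids(name)
        xy = self.element_coords()[ids]
        x, y = xy[..., 0], xy[..., 1]
        x2, y2 = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        cross = x * y2 - x2 * y
        area = 0.5 * cross.sum(axis=1)
        cx = np.sum((x + x2) * cross, axis=1) / (6.0 * area)
        return float(np.sum(2.0 * np.pi * cx * area))

    def total_area(self, name: str | None = None) -> float:
        ids = np.arange(len(self.elements)) if name is None else self.region_ids(name)
        return float(self.element_areas()[ids].sum())


@dataclass(frozen=True)
class ROILayerSpec:
    """Tissue layer at a given offset from the wound-bed surface.

    ``beneath_wound`` layers sit under the cavity floor (distance measured
    along depth, +z); ``beside_wound`` layers flank the lateral cavity wall
    (distance measured radially outward). Offsets/thickness in mm.
    """

    direction: str = "beneath_wound"
    offset: float = 0.0
    thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.direction not in ("beneath_wound", "beside_wound"):
            raise ValueError("direction must be beneath_wound or beside_wound")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")

    @property
    def label(self) -> str:
        return f"{self.direction}:{self.offset:g}mm"


# ---------------------------------------------------------------------------
# 1D graded point distributions
# ---------------------------------------------------------------------------


def graded_points(a: float, b: float, h_a: float, h_b: float) -> np.ndarray:
    """Points from a to b with spacing ramping geometrically h_a -> h_b."""
    length = b - a
    if length <= 0:
        raise ValueError("need b > a")
    n = max(int(np.ceil(2.0 * length / (h_a + h_b))), 1)
    if n == 1:
        return np.array([a, b])
    t = np.arange(n)
    h = h_a * (h_b / h_a) ** (t / (n - 1))
    x = np.concatenate([[0.0], np.cumsum(h)])
    x *= length / x[-1]
    return a + x


def _merge_segments(segs: Iterable[np.ndarray]) -> np.ndarray:
    pts = [np.asarray(s) for s in segs]
    out = [pts[0]]
    for s in pts[1:]:
        out.append(s[1:])
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Limb mesh generation
# ---------------------------------------------------------------------------


def build_limb_geometry(
    params: LimbGeometryParams | None = None, options: MeshOptions | None = None
) -> Mesh:
    """Generate the conforming muscle + filler mesh of the residual limb.

    The filler exactly occupies the wound cavity; element size is graded fine
    near the wound/filler interface and coarse in the far field. Returns a
    :class:`Mesh` in metres whose metadata records the geometry parameters.
    """
    p = params or LimbGeometryParams()
    o = options or MeshOptions()
    hf, hm, hc, hr = o.sized()
    ext = o.roi_extent

    Rb, Rm, L = p.bone_radius, p.muscle_radius, p.limb_length
    rw, dw, zt, f = p.wound_radius, p.wound_depth, p.bone_tip_offset, p.fillet

    # radial lines (cm)
    rsegs = []
    if rw > 0.0:
        if Rb < rw:
            rsegs.append(graded_points(0.0, Rb, hm, hm))
            rsegs.append(graded_points(Rb, max(rw - f, Rb + 1e-9), hm, hf))
        else:  # wound narrower than bone radius (unusual but legal)
            rsegs.append(graded_points(0.0, max(rw - f, 1e-9), hm, hf))
            rsegs.append(graded_points(max(rw - f, 1e-9), Rb, hf, hm))
        if f > 0.0:
            # fine arc sampling: the filler volume deficit of the inscribed
            # polyline scales with the chord count squared
            h_arc = min(hf, f / 8.0)
            rsegs.append(graded_points(rw - f, rw, h_arc, h_arc))
        elif rsegs[-1][-1] < rw:
            rsegs.append(graded_points(rsegs[-1][-1], rw, hf, hf))
        if rw + ext < Rm - 1e-9:
            rsegs.append(graded_points(rw, rw + ext, hf, hr))
            rsegs.append(graded_points(rw + ext, Rm, hr, hc))
        else:
            rsegs.append(graded_points(rw, Rm, hf, hr))
        rline = _merge_segments(rsegs)
    else:
        rline = _merge_segments(
            [graded_points(0.0, Rb, hm, hm), graded_points(Rb, Rm, hm, hc)]
        )

    # axial lines (cm)
    zsegs = [graded_points(0.0, dw, hf, hf) if dw > 0 else np.array([0.0])]
    if dw + ext < zt - 1e-9:
        zsegs.append(graded_points(dw, dw + ext, hf, hr))
        zsegs.append(graded_points(dw + ext, zt, hr, hm))
    else:
        zsegs.append(graded_points(dw, zt, hf, hr))
    zsegs.append(graded_points(zt, L, hm, hc))
    zline = _merge_segments(zsegs)

    nr, nz = len(rline), len(zline)
    R, Z = np.meshgrid(rline, zline, indexing="ij")

    # remap cavity-floor line onto the fillet arc, column by column
    if f > 0.0 and rw > 0.0:
        j_dw = int(np.argmin(np.abs(zline - dw)))
        j_zt = int(np.argmin(np.abs(zline - zt)))
        for i in range(nr):
            r_i = rline[i]
            if rw - f < r_i <= rw + 1e-12:
                d_i = float(p.cavity_depth_at(min(r_i, rw - 1e-12)))
                if r_i >= rw - 1e-12:
                    d_i = dw - f
                zcol = Z[i].copy()
                lo = zcol[: j_dw + 1]
                Z[i, : j_dw + 1] = lo * (d_i / dw)
                mid = zcol[j_dw : j_zt + 1]
                Z[i, j_dw : j_zt + 1] = d_i + (mid - dw) * (zt - d_i) / (zt - dw)

    # optional interior jitter (seeded); breakpoint lines are left untouched
    if o.jitter > 0.0:
        rng = np.random.default_rng(o.seed)
        key_r = {0.0, Rb, rw, rw - f, Rm}
        key_z = {0.0, dw, zt, L}
        hr = np.gradient(rline)
        hz = np.gradient(zline)
        for i in range(1, nr - 1):
            if any(abs(rline[i] - k) < 1e-9 for k in key_r) or (rw - f) <= rline[i] <= rw:
                continue
            for j in range(1, nz - 1):
                if any(abs(zline[j] - k) < 1e-9 for k in key_z):
                    continue
                R[i, j] += o.jitter * hr[i] * rng.uniform(-0.5, 0.5)
                Z[i, j] += o.jitter * hz[j] * rng.uniform(-0.5, 0.5)

    nid = np.arange(nr * nz).reshape(nr, nz)
    quads = np.stack(
        [
            nid[:-1, :-1].ravel(),
            nid[1:, :-1].ravel(),
            nid[1:, 1:].ravel(),
            nid[:-1, 1:].ravel(),
        ],
        axis=1,
    )
    nodes = np.stack([R.ravel(), Z.ravel()], axis=1)

    cent = nodes[quads].mean(axis=1)
    rc, zc = cent[:, 0], cent[:, 1]
    d_at = p.cavity_depth_at(rc)
    in_bone = (rc < Rb) & (zc > zt)
    in_filler = (rc < rw) & (zc < d_at)
    keep = ~in_bone
    quads = quads[keep]
    region = np.where(in_filler[keep], FILLER, MUSCLE)

    # drop unused nodes, renumber
    used = np.unique(quads)
    remap = -np.ones(nodes.shape[0], dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    quads = remap[quads]

    facets, tags, tag_names = _extract_facets(nodes, quads, region, p)

    mesh = Mesh(
        nodes=nodes * CM,
        elements=quads,
        region=region,
        region_names={MUSCLE: "muscle", FILLER: "filler"},
        facets=facets,
        facet_tags=tags,
        facet_tag_names=tag_names,
        metadata={"geometry": p, "options": o, "kind": "limb"},
    )
    areas = mesh.element_areas()
    if np.any(areas <= 0):
        raise RuntimeError("mesh generation produced inverted elements")
    return mesh


_LIMB_TAGS = {
    1: "symmetry_axis",
    2: "proximal_end",
    3: "bone_interface",
    4: "outer_skin",
    5: "filler_top",
    6: "wound_lateral",
    7: "wound_bottom",
}


def _extract_facets(nodes_cm, quads, region, p: LimbGeometryParams):
    """Exterior + muscle/filler interface facets, tagged and muscle-outward oriented."""
    tol = 1e-6
    edges = {}
    for e, quad in enumerate(quads):
        for k in range(4):
            a, b = int(quad[k]), int(quad[(k + 1) % 4])
            key = (a, b) if a < b else (b, a)
            edges.setdefault(key, []).append(e)

    cent = nodes_cm[quads].mean(axis=1)
    facets, tags = [], []
    for (a, b), owners in edges.items():
        if len(owners) == 2 and region[owners[0]] == region[owners[1]]:
            continue
        if len(owners) == 2:
            owner = owners[0] if region[owners[0]] == MUSCLE else owners[1]
            interface = True
        else:
            owner = owners[0]
            interface = False
        pa, pb = nodes_cm[a], nodes_cm[b]
        mid = 0.5 * (pa + pb)
        dr, dz = pb - pa
        # orient so normal (dz, -dr) points away from the owner centroid
        n = np.array([dz, -dr])
        if np.dot(n, mid - cent[owner]) < 0.0:
            a, b = b, a
        if interface:
            tag = 6 if abs(dz) >= abs(dr) else 7
        else:
            tag = _classify_exterior(mid, p, tol)
            if tag is None:
                raise RuntimeError(f"unclassifiable boundary facet at {mid}")
        facets.append((a, b))
        tags.append(tag)
    return (
        np.asarray(facets, dtype=int),
        np.asarray(tags, dtype=int),
        dict(_LIMB_TAGS),
    )


def _classify_exterior(mid_cm, p: LimbGeometryParams, tol):
    r, z = mid_cm
    if r < tol:
        return 1
    if z > p.limb_length - tol:
        return 2
    near_bone_r = abs(r - p.bone_radius) < tol and z > p.bone_tip_offset - tol
    near_bone_z = abs(z - p.bone_tip_offset) < tol and r < p.bone_radius + tol
    if near_bone_r or near_bone_z:
        return 3
    if z < tol:
        return 5 if r < p.wound_radius else 4
    if r > p.muscle_radius - tol:
        return 4
    # distal face outside the wound (can be slightly above z=0 only if jittered)
    if z < p.wound_depth + tol and r > p.wound_radius - tol:
        return 4
    return None


# ---------------------------------------------------------------------------
# Closed-form areas
# ---------------------------------------------------------------------------


def wound_opening_area(params: LimbGeometryParams) -> float:
    """Wound opening (cross-sectional) area pi*r^2 in cm^2."""
    if params.wound_radius <= 0:
        raise ValueError("wound_radius must be positive")
    return float(np.pi * params.wound_radius**2)


def cavity_wall_area(params: LimbGeometryParams) -> float:
    """Full cavity wall area pi*r^2 + 2*pi*r*d in cm^2 (diagnostic only)."""
    r, d = params.wound_radius, params.wound_depth
    return float(np.pi * r**2 + 2.0 * np.pi * r * d)


# ---------------------------------------------------------------------------
# ROI layers
# ---------------------------------------------------------------------------


def define_roi_layers(mesh: Mesh, specs: Sequence[ROILayerSpec]) -> dict:
    """Map each ROI spec to the muscle elements whose centroid distance from
    the wound-bed surface falls in [offset, offset + thickness).

    Distances are measured from the nominal (sharp) cavity surfaces: along +z
    from the cavity floor for ``beneath_wound``, radially outward from the
    lateral wall for ``beside_wound`` (restricted to the cavity depth band).
    Raises ``ValueError`` naming the spec if a layer is empty.
    """
    p: LimbGeometryParams = mesh.metadata["geometry"]
    if p.wound_radius <= 0:
        raise ValueError("ROI layers require a wound cavity")
    cent = mesh.element_centroids() / CM  # cm
    rc, zc = cent[:, 0], cent[:, 1]
    muscle = mesh.region == MUSCLE

    out = {}
    for spec in specs:
        off, thk = spec.offset * MM / CM, spec.thickness * MM / CM  # -> cm
        if spec.direction == "beneath_wound":
            dist = zc - p.wound_depth
            inside = muscle & (rc <= p.wound_radius)
        else:
            dist = rc - p.wound_radius
            inside = muscle & (zc <= p.wound_depth)
        sel = inside & (dist >= off) & (dist < off + thk)
        ids = np.flatnonzero(sel)
        if ids.size == 0:
            raise ValueError(f"ROI layer {spec.label} selects no elements")
        out[spec.label] = ids
    return out
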