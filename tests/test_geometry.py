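"""Limb geometry, meshing and ROI-layer tests."""

import numpy as np
import pytest
from scipy.integrate import quad

from npwtox.geometry import (
    FILLER,
    LimbGeometryParams,
    Mesh,
    MeshOptions,
    ROILayerSpec,
    build_limb_geometry,
    cavity_wall_area,
    define_roi_layers,
    graded_points,
    wound_opening_area,
)
from npwtox import io


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bone_radius=8.0),  # bone wider than muscle
            dict(wound_radius=7.5),  # wound wider than limb
            dict(wound_depth=20.0),  # deeper than limb
            dict(wound_depth=3.5),  # would expose bone tip
            dict(edge_shape="bevel"),
            dict(edge_shape="round", edge_fillet_radius=1.0),  # fillet > depth
            dict(limb_length=-1.0),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            LimbGeometryParams(**kwargs)

    def test_cavity_profile(self, limb_params):
        p = limb_params
        assert p.cavity_depth_at(0.0) == p.wound_depth
        assert p.cavity_depth_at(p.wound_radius + 0.1) == 0.0
        rnd = LimbGeometryParams(edge_shape="round")
        assert rnd.cavity_depth_at(rnd.wound_radius - 1e-9) == pytest.approx(
            rnd.wound_depth - rnd.edge_fillet_radius, abs=1e-4
        )


class TestAreas:
    def test_wound_opening_area(self, limb_params):
        assert wound_opening_area(limb_params) == pytest.approx(np.pi * 3.6**2, rel=1e-12)

    def test_unit_radius(self):
        p = LimbGeometryParams(wound_radius=1.0)
        assert wound_opening_area(p) == pytest.approx(np.pi, rel=1e-12)

    def test_zero_radius_error(self):
        p = LimbGeometryParams(wound_radius=0.0)
        with pytest.raises(ValueError):
            wound_opening_area(p)

    def test_cavity_wall_area_diagnostic(self, limb_params):
        expected = np.pi * 3.6**2 + 2 * np.pi * 3.6 * 0.8
        assert cavity_wall_area(limb_params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(58.81, abs=0.01)


class TestMesh:
    def test_filler_volume_matches_cylinder(self, limb_mesh, limb_params):
        v = limb_mesh.revolved_volume("filler") * 1e6  # m^3 -> cm^3
        analytic = np.pi * limb_params.wound_radius**2 * limb_params.wound_depth
        assert v == pytest.approx(analytic, rel=1e-9)
        assert analytic == pytest.approx(32.57, abs=0.01)

    def test_muscle_volume_matches_solid_of_revolution(self, limb_mesh, limb_params):
        p = limb_params
        v = limb_mesh.revolved_volume("muscle") * 1e6
        analytic = (
            np.pi * p.muscle_radius**2 * p.limb_length
            - np.pi * p.bone_radius**2 * (p.limb_length - p.bone_tip_offset)
            - np.pi * p.wound_radius**2 * p.wound_depth
        )
        assert v == pytest.approx(analytic, rel=1e-9)

    def test_no_inverted_elements_and_axis_nodes(self, limb_mesh):
        assert (limb_mesh.element_areas() > 0).all()
        axis = limb_mesh.facet_nodes("symmetry_axis")
        assert np.abs(limb_mesh.nodes[axis, 0]).max() == 0.0

    def test_refinement_volume_stability(self, limb_mesh, limb_params):
        fine = build_limb_geometry(limb_params, MeshOptions(scale=2.0))
        for region in ("muscle", "filler"):
            v0 = limb_mesh.revolved_volume(region)
            v1 = fine.revolved_volume(region)
            assert abs(v1 - v0) / v0 < 0.005

    def test_round_vs_sharp_volume_fillet_correction(self, limb_params):
        rnd_p = LimbGeometryParams(edge_shape="round")
        sharp = build_limb_geometry(limb_params)
        rnd = build_limb_geometry(rnd_p)
        dv = (sharp.revolved_volume("filler") - rnd.revolved_volume("filler")) * 1e6
        # analytic fillet ring volume: 2*pi*int r*(d_w - d(r)) dr over the band
        f = rnd_p.edge_fillet_radius
        r0 = rnd_p.wound_radius - f
        integrand = lambda r: r * (rnd_p.wound_depth - rnd_p.cavity_depth_at(r))
        dv_analytic = 2 * np.pi * quad(integrand, r0, rnd_p.wound_radius)[0]
        # inscribed-polyline approximation of the arc: first-order interface
        # sampling leaves a few-percent deficit at the default resolution
        assert dv == pytest.approx(dv_analytic, rel=0.08)
        assert dv / (sharp.revolved_volume("filler") * 1e6) < 0.01

    def test_degenerate_no_wound(self):
        p = LimbGeometryParams(wound_radius=0.0)
        m = build_limb_geometry(p)
        assert (m.region != FILLER).all()
        assert "filler" not in [m.region_names[c] for c in np.unique(m.region)]

    def test_exterior_boundary_closes(self, limb_mesh):
        """Outward normals integrated over the exterior boundary must cancel
        (closed-curve identity in the (r,z) plane); interface facets excluded."""
        ext = [
            t
            for t in limb_mesh.facet_tag_names.values()
            if t not in ("wound_lateral", "wound_bottom")
        ]
        total = np.zeros(2)
        length = 0.0
        for tag in ext:
            fa = limb_mesh.facets[limb_mesh.facet_ids(tag)]
            d = limb_mesh.nodes[fa[:, 1]] - limb_mesh.nodes[fa[:, 0]]
            n = np.stack([d[:, 1], -d[:, 0]], axis=1)
            total += n.sum(axis=0)
            length += np.linalg.norm(d, axis=1).sum()
        assert np.linalg.norm(total) < 1e-9 * length

    def test_msh_roundtrip(self, limb_mesh_coarse, tmp_path):
        path = tmp_path / "limb.msh"
        io.write_msh(path, limb_mesh_coarse)
        nodes, elems, region = io.read_msh(path)
        assert np.allclose(nodes, limb_mesh_coarse.nodes, atol=1e-15)
        assert (elems == limb_mesh_coarse.elements).all()
        assert (region == limb_mesh_coarse.region).all()

    def test_vtu_writes(self, limb_mesh_coarse, tmp_path):
        path = tmp_path / "limb.vtu"
        io.write_vtu(path, limb_mesh_coarse, point_data={"z": limb_mesh_coarse.nodes[:, 1]})
        text = path.read_text()
        assert "UnstructuredGrid" in text and "z" in text


class TestROILayers:
    def test_default_layers_disjoint_nonempty(self, limb_mesh):
        specs = [ROILayerSpec("beneath_wound", o) for o in (0.0, 10.0, 15.0)]
        roi = define_roi_layers(limb_mesh, specs)
        sets = [set(ids.tolist()) for ids in roi.values()]
        assert all(sets)
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_zero_offset_touches_wound_bottom(self, limb_mesh, limb_params):
        roi = define_roi_layers(limb_mesh, [ROILayerSpec("beneath_wound", 0.0)])
        ids = roi["beneath_wound:0mm"]
        zc = limb_mesh.element_centroids()[ids, 1] * 100.0  # cm
        assert (zc >= limb_params.wound_depth).all()
        assert zc.min() < limb_params.wound_depth + 0.25  # first element row

    def test_brute_force_centroid_scan(self, limb_mesh, limb_params):
        """The ROI rule re-derived independently from raw centroids."""
        spec = ROILayerSpec("beneath_wound", 10.0, 2.0)
        roi = define_roi_layers(limb_mesh, [spec])[spec.label]
        cent = limb_mesh.element_centroids() * 100.0
        expected = set()
        for e, (rc, zc) in enumerate(cent):
            if limb_mesh.region_names[limb_mesh.region[e]] != "muscle":
                continue
            d = zc - limb_params.wound_depth
            if rc <= limb_params.wound_radius and 1.0 <= d < 1.2:
                expected.add(e)
        assert set(roi.tolist()) == expected

    def test_offset_outside_limb_raises(self, limb_mesh):
        with pytest.raises(ValueError, match="beneath_wound:500mm"):
            define_roi_layers(limb_mesh, [ROILayerSpec("beneath_wound", 500.0)])

    def test_renumbering_invariance(self, limb_mesh):
        """ROI element sets must not depend on node numbering."""
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(limb_mesh.nodes))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = Mesh(
            nodes=limb_mesh.nodes[perm],
            elements=inv[limb_mesh.elements],
            region=limb_mesh.region,
            region_names=limb_mesh.region_names,
            facets=inv[limb_mesh.facets],
            facet_tags=limb_mesh.facet_tags,
            facet_tag_names=limb_mesh.facet_tag_names,
            metadata=limb_mesh.metadata,
        )
        specs = [ROILayerSpec("beneath_wound", 10.0), ROILayerSpec("beside_wound", 5.0)]
        a = define_roi_layers(limb_mesh, specs)
        b = define_roi_layers(shuffled, specs)
        for k in a:
            assert (a[k] == b[k]).all()

    @pytest.mark.parametrize(
        "kwargs", [dict(direction="sideways"), dict(offset=-1.0), dict(thickness=0.0)]
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            ROILayerSpec(**{**dict(direction="beneath_wound", offset=0.0), **kwargs})


def test_graded_points_properties():
    pts = graded_points(0.0, 1.0, 0.01, 0.1)
    assert pts[0] == 0.0 and pts[-1] == 1.0
    d = np.diff(pts)
    assert (d > 0).all()
    assert d[-1] > d[0]  # grading direction
    with pytest.raises(ValueError):
        graded_points(1.0, 0.0, 0.1, 0.1)
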