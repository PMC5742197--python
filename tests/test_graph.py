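import numpy as np
import pytest

from vascatlas.graph import (
    SWCError,
    SkeletonParams,
    VesselGraph,
    build_graph,
    estimate_radii,
    read_swc,
    render_tubes,
    skeletonize,
    trace_dents,
    write_swc,
)
from vascatlas.stack import BinaryVolume


def single_node_graph(z, y, x, radius=1.0):
    return VesselGraph(
        np.array([1]), np.array([7]), np.array([float(x)]), np.array([float(y)]),
        np.array([float(z)]), np.array([float(radius)]), np.array([-1]),
    )


def capsule(shape, p0, p1, r):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    q = np.stack([zz, yy, xx], -1).astype(float)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((q - p0) @ d) / (d @ d), 0, 1)
    return np.linalg.norm(q - (p0 + t[..., None] * d), axis=-1) <= r


class TestSkeletonize:
    def test_empty_mask_gives_empty_skeleton(self):
        out = skeletonize(BinaryVolume(np.zeros((5, 5, 5), bool)))
        assert not out.voxels.any()

    def test_straight_tube_reduces_to_single_axis_path(self, cylinder_factory):
        mask, c = cylinder_factory(4, length=100)
        skel = skeletonize(mask, SkeletonParams(prune_spur_len_um=12))
        g = build_graph(skel, SkeletonParams(node_spacing_um=5))
        assert len(g.components()) == 1
        assert len(g.loop_edges) == 0
        assert abs(g.total_length_um() - 100) <= 5  # within 5% of the true 100

    def test_skeleton_subset_of_mask(self, cylinder_factory):
        mask, _ = cylinder_factory(4)
        skel = skeletonize(mask)
        assert not (skel.voxels & ~mask.voxels).any()

    def test_y_junction_topology(self):
        shape = (60, 40, 40)
        vol = (
            capsule(shape, (5, 20, 20), (30, 20, 20), 3)
            | capsule(shape, (30, 20, 20), (55, 10, 10), 3)
            | capsule(shape, (30, 20, 20), (55, 30, 30), 3)
        )
        skel = skeletonize(BinaryVolume(vol), SkeletonParams(prune_spur_len_um=5))
        from vascatlas.graph import _voxel_graph

        g = _voxel_graph(np.argwhere(skel.voxels), 26, (1, 1, 1))
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        junctions = [n for n in g.nodes if g.degree(n) > 2]
        assert len(endpoints) == 3
        # junction voxels form one tight cluster
        import networkx as nx

        assert nx.number_connected_components(g.subgraph(junctions)) == 1


class TestBuildGraph:
    def test_single_path_is_linear_chain(self, cylinder_factory):
        mask, _ = cylinder_factory(2, length=50)
        g = build_graph(skeletonize(mask, SkeletonParams(prune_spur_len_um=8)))
        assert len(g.roots()) == 1
        assert not g.loop_edges
        # linear: every non-root node has exactly one child
        parents = [p for p in g.parent if p != -1]
        assert len(set(parents)) == len(parents)

    def test_torus_yields_one_loop_edge(self):
        zz, yy, xx = np.mgrid[0:30, 0:60, 0:60]
        d = np.sqrt((np.sqrt((yy - 30.0) ** 2 + (xx - 30.0) ** 2) - 20) ** 2 + (zz - 15.0) ** 2)
        g = build_graph(skeletonize(BinaryVolume(d <= 4)))
        # Euler: edges - nodes + components = independent cycles = 1
        assert len(g.roots()) == 1
        assert len(g.loop_edges) == 1

    def test_two_components_two_roots(self):
        vol = np.zeros((40, 20, 20), bool)
        vol |= capsule(vol.shape, (2, 10, 10), (15, 10, 10), 2)
        vol |= capsule(vol.shape, (25, 10, 10), (38, 10, 10), 2)
        g = build_graph(skeletonize(BinaryVolume(vol)))
        assert len(g.roots()) == 2
        assert len(g.components()) == 2

    def test_thinning_preserves_component_count(self):
        from scipy import ndimage

        vol = np.zeros((70, 40, 40), bool)
        vol |= capsule(vol.shape, (5, 10, 10), (30, 10, 10), 3)
        vol |= capsule(vol.shape, (5, 28, 28), (65, 28, 28), 4)
        vol |= capsule(vol.shape, (40, 10, 10), (65, 10, 30), 2)
        mask = BinaryVolume(vol)
        skel = skeletonize(mask)
        s = np.ones((3, 3, 3), bool)
        _, n_mask = ndimage.label(mask.voxels, structure=s)
        _, n_skel = ndimage.label(skel.voxels, structure=s)
        assert n_skel == n_mask


class TestEstimateRadii:
    @pytest.mark.parametrize("r", [2, 4, 8, 12])
    def test_cylinder_radius_recovery(self, cylinder_factory, r):
        mask, _ = cylinder_factory(r, length=80)
        params = SkeletonParams(prune_spur_len_um=3 * r, node_spacing_um=3)
        g = build_graph(skeletonize(mask, params), params)
        g = estimate_radii(g, mask, params)
        interior = (g.z > 15) & (g.z < 65)
        med = np.median(g.radius[interior])
        assert abs(med - r) <= 0.5 + 1e-9

    def test_single_voxel_gets_half_voxel_radius(self):
        vol = np.zeros((9, 9, 9), bool)
        vol[4, 4, 4] = True
        g = estimate_radii(single_node_graph(4, 4, 4), BinaryVolume(vol))
        assert g.radius[0] == pytest.approx(0.5)

    def test_sphere_radius(self):
        zz, yy, xx = np.mgrid[0:25, 0:25, 0:25]
        sphere = ((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 100
        g = estimate_radii(single_node_graph(12, 12, 12), BinaryVolume(sphere))
        assert 9.5 <= g.radius[0] <= 10.5

    def test_node_outside_mask_flagged_zero(self):
        vol = np.zeros((5, 5, 5), bool)
        vol[2, 2, 2] = True
        g = estimate_radii(single_node_graph(0, 0, 0), BinaryVolume(vol))
        assert g.radius[0] == 0.0
        assert g.metadata["radius_flags"] == [1]

    def test_monotone_under_dilation(self, cylinder_factory):
        from vascatlas import _morph

        mask, _ = cylinder_factory(3, length=40)
        params = SkeletonParams(node_spacing_um=3)
        g = build_graph(skeletonize(mask, params), params)
        r1 = estimate_radii(g, mask, params).radius
        dilated = BinaryVolume(_morph.dilate(mask.voxels, 1.0), (1, 1, 1))
        r2 = estimate_radii(g, dilated, params).radius
        assert (r2 >= r1 - 1e-9).all()


class TestSWC:
    def test_round_trip_truth_graph(self, default_scene, tmp_path):
        g = default_scene.truth_graph
        write_swc(g, tmp_path / "g.swc")
        back = read_swc(tmp_path / "g.swc")
        np.testing.assert_array_equal(back.ids, g.ids)
        np.testing.assert_array_equal(back.parent, g.parent)
        np.testing.assert_array_equal(back.x, g.x)
        np.testing.assert_array_equal(back.radius, g.radius)

    def test_all_orphans_is_forest_of_singletons(self, tmp_path):
        p = tmp_path / "s.swc"
        p.write_text("1 7 0 0 0 1.0 -1\n2 7 5 0 0 1.0 -1\n")
        g = read_swc(p)
        assert len(g.roots()) == 2

    def test_six_columns_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("# header\n1 7 0 0 0 1.0\n")
        with pytest.raises(SWCError, match=":2"):
            read_swc(p)

    def test_forward_parent_reference_allowed(self, tmp_path):
        p = tmp_path / "fwd.swc"
        p.write_text("1 7 0 0 0 1.0 2\n2 7 5 0 0 1.0 -1\n")
        g = read_swc(p)
        assert g.parent[0] == 2

    def test_loop_sidecar_round_trip(self, tmp_path):
        g = VesselGraph(
            np.array([1, 2, 3]), np.array([7, 7, 7]),
            np.array([0.0, 5.0, 10.0]), np.zeros(3), np.zeros(3),
            np.ones(3), np.array([-1, 1, 2]), loop_edges=[(3, 1)],
        )
        write_swc(g, tmp_path / "loop.swc")
        back = read_swc(tmp_path / "loop.swc")
        assert back.loop_edges == [(3, 1)]


class TestRenderTubes:
    def test_cylinder_volume_close_to_analytic(self):
        g = VesselGraph(
            np.array([1, 2]), np.array([5, 5]),
            np.array([15.0, 15.0]), np.array([15.0, 15.0]), np.array([5.0, 75.0]),
            np.array([4.0, 4.0]), np.array([-1, 1]),
        )
        vol = render_tubes(g, (80, 31, 31), (1, 1, 1))
        expected = np.pi * 16 * 70
        assert abs(vol.sum() - expected) / expected < 0.1

    def test_every_node_center_inside_render(self, default_scene):
        g = default_scene.truth_graph
        vs = np.asarray(default_scene.params.voxel_size_um)
        vol = render_tubes(g, default_scene.params.shape, vs)
        idx = np.rint(g.positions_um() / vs).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
        assert vol[idx[ok, 0], idx[ok, 1], idx[ok, 2]].all()


class TestTraceDents:
    def test_empty_dents_empty_graph(self):
        g = trace_dents(BinaryVolume(np.zeros((5, 5, 5), bool)))
        assert g.n_nodes == 0

    def test_two_parallel_tubes_two_components(self):
        # two parallel half-embedded tubes carved out of a slab surface
        n = 80
        vol = np.zeros((60, 40, n), bool)
        slab = np.zeros_like(vol)
        slab[:, 10:, :] = True  # tissue below y=10; surface at y=10
        t1 = capsule(vol.shape, (5, 10, 20), (55, 10, 20), 5)
        t2 = capsule(vol.shape, (5, 10, 60), (55, 10, 60), 5)
        mask = BinaryVolume(slab & ~(t1 | t2), (1, 1, 1), "brain_mask")
        from vascatlas.contour import extract_dents

        dents = extract_dents(mask, 15)
        g = trace_dents(dents, SkeletonParams(prune_spur_len_um=10))
        assert len(g.components()) == 2

    def test_straight_pial_tube_centerline_close_to_axis(self):
        n = 80
        vol = np.zeros((60, 40, n), bool)
        slab = np.zeros_like(vol)
        slab[:, 10:, :] = True
        # pial tube mostly sunk into the surface (axis 2 voxels below it)
        tube = capsule(vol.shape, (5, 12, 40), (55, 12, 40), 5)
        mask = BinaryVolume(slab & ~tube, (1, 1, 1), "brain_mask")
        from vascatlas.contour import extract_dents

        dents = extract_dents(mask, 15)
        g = trace_dents(dents, SkeletonParams(prune_spur_len_um=10))
        assert len(g.components()) == 1
        # every traced node within 2 voxels of the true axis line (y=12, x=40)
        d = np.sqrt((g.y - 12) ** 2 + (g.x - 40) ** 2)
        interior = (g.z > 10) & (g.z < 50)
        assert interior.any()
        assert d[interior].max() <= 2.0 + 1e-9
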