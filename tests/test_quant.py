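import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vascatlas.graph import VesselGraph
from vascatlas.quant import (
    DEFAULT_SHRINKAGE,
    DensityReport,
    DiameterBins,
    DistributionMatrix,
    LevelCutoffs,
    annotate_vessel,
    compare_regions,
    corrected_diameter,
    count_branch_levels,
    distribution_proportions,
    fractional_volume,
    mean_distribution,
    normalized_length,
    shrinkage_correct,
    shrinkage_invert,
    validate_tracing,
)
from vascatlas.stack import BinaryVolume, LabelVolume


def line_graph(points_zyx, radii, type_code=7):
    n = len(points_zyx)
    pts = np.asarray(points_zyx, dtype=float)
    return VesselGraph(
        np.arange(1, n + 1), np.full(n, type_code),
        pts[:, 2], pts[:, 1], pts[:, 0],
        np.asarray(radii, dtype=float),
        np.array([-1] + list(range(1, n)), dtype=np.int64),
    )


class TestValidateTracing:
    def test_identical_masks_perfect_scores(self):
        vol = np.zeros((10, 20, 20), bool)
        vol[:, 8:12, 8:12] = True
        m = BinaryVolume(vol, (10, 1, 1), "vessel_mask")
        rep = validate_tracing(m, m, interval_um=10)
        assert rep.pooled_recall == 1.0
        assert rep.pooled_precision == 1.0
        assert rep.pooled_diameter_ratio == 1.0
        assert (rep.per_slice["R"].dropna() == 1.0).all()

    def test_area_ratio_formula(self):
        truth = np.zeros((1, 20, 20), bool)
        truth[0, :10, :10] = True  # 100 px
        traced = np.zeros_like(truth)
        traced[0, :9, :10] = True  # 90 px
        rep = validate_tracing(
            BinaryVolume(traced, (1, 1, 1)), BinaryVolume(truth, (1, 1, 1)), interval_um=1
        )
        assert rep.pooled_diameter_ratio == pytest.approx(0.9)

    def test_hand_computed_three_region_slice(self):
        """Three truth regions, two traced regions hitting two of them."""
        truth = np.zeros((1, 30, 30), bool)
        truth[0, 2:6, 2:6] = True       # region 1 (16 px)
        truth[0, 2:6, 12:16] = True     # region 2 (16 px)
        truth[0, 20:24, 20:24] = True   # region 3 (16 px)
        traced = np.zeros_like(truth)
        traced[0, 2:6, 2:6] = True      # hits region 1 exactly
        traced[0, 3:5, 13:15] = True    # hits region 2 partially (4 px)
        rep = validate_tracing(
            BinaryVolume(traced, (1, 1, 1)), BinaryVolume(truth, (1, 1, 1)), interval_um=1
        )
        assert rep.pooled_recall == pytest.approx(2 / 3)   # B=2 of B1=3
        assert rep.pooled_precision == pytest.approx(1.0)  # both traced regions overlap
        assert rep.pooled_diameter_ratio == pytest.approx(20 / 48)

    def test_phantom_truth_render_self_consistent(self, default_scene):
        rep = validate_tracing(
            default_scene.truth_graph, default_scene.vessel_mask, interval_um=70
        )
        assert rep.pooled_recall >= 0.95
        assert rep.pooled_precision >= 0.95

    def test_empty_truth_rejected(self):
        empty = BinaryVolume(np.zeros((5, 5, 5), bool))
        traced = BinaryVolume(np.ones((5, 5, 5), bool))
        with pytest.raises(ValueError, match="empty"):
            validate_tracing(traced, empty, interval_um=1)


class TestDensity:
    def test_empty_vessels_zero_fv(self):
        fv = fractional_volume(BinaryVolume(np.zeros((5, 5, 5), bool)))
        assert fv["total"] == 0.0

    def test_fully_vascular_roi_fv_one(self):
        fv = fractional_volume(BinaryVolume(np.ones((4, 4, 4), bool)))
        assert fv["total"] == 1.0

    def test_cylinder_fv_close_to_analytic(self):
        # r = 4 um, L = 400 um in a 400^3 um cube at 2 um voxels
        g = line_graph([(0, 200, 200), (400, 200, 200)], [4.0, 4.0])
        fv = fractional_volume(g, shape=(200, 200, 200), voxel_size_um=(2, 2, 2))
        analytic = np.pi * 16 * 400 / 400**3
        assert fv["small"] == pytest.approx(analytic, rel=0.10)
        assert fv["medium"] == 0.0 and fv["large"] == 0.0

    def test_bins_partition_sums_to_total(self, default_scene):
        g = default_scene.truth_graph
        fv = fractional_volume(
            g, shape=default_scene.params.shape,
            voxel_size_um=default_scene.params.voxel_size_um,
        )
        assert fv["small"] + fv["medium"] + fv["large"] == pytest.approx(fv["total"], abs=1e-12)

    def test_nl_closed_form(self):
        g = line_graph([(0, 0, 0), (400, 0, 0)], [3.0, 3.0])
        nl = normalized_length(g, roi_volume_mm3=0.064)
        assert nl["small"] == pytest.approx(6.25, abs=1e-6)
        assert nl["total"] == pytest.approx(6.25, abs=1e-6)

    def test_empty_graph_nl_zero(self):
        assert normalized_length(VesselGraph.empty(), roi_volume_mm3=1.0)["total"] == 0.0

    def test_loop_edges_counted_once(self):
        g = VesselGraph(
            np.array([1, 2, 3]), np.full(3, 7),
            np.array([0.0, 100.0, 100.0]), np.array([0.0, 0.0, 100.0]), np.zeros(3),
            np.full(3, 2.0), np.array([-1, 1, 2]), loop_edges=[(3, 1)],
        )
        nl = normalized_length(g, roi_volume_mm3=1.0)
        expected = (100 + 100 + np.sqrt(100**2 + 100**2)) / 1000.0
        assert nl["total"] == pytest.approx(expected, rel=1e-9)

    def test_phantom_total_length_recovered(self, default_scene):
        g = default_scene.truth_graph
        nl = normalized_length(g, roi_volume_mm3=1.0)
        true_len_mm = g.total_length_um() / 1000.0
        assert nl["total"] == pytest.approx(true_len_mm, rel=0.05)


class TestShrinkage:
    def _report(self, nl_small=6.25):
        frame = pd.DataFrame(
            {"small": [nl_small], "medium": [0.0], "large": [0.0], "total": [nl_small]},
            index=[1],
        )
        fv = frame / 100.0
        return DensityReport(fv=fv, nl=frame)

    def test_zero_shrinkage_identity(self):
        rep = self._report()
        out = shrinkage_correct(rep, 0.0)
        pd.testing.assert_frame_equal(out.nl, rep.nl)
        pd.testing.assert_frame_equal(out.fv, rep.fv)

    def test_closed_form_value(self):
        out = shrinkage_correct(self._report(6.25), 0.259)
        assert out.nl.loc[1, "small"] == pytest.approx(6.25 * 0.741**2, abs=1e-9)

    def test_fv_invariant(self):
        rep = self._report()
        out = shrinkage_correct(rep, 0.259)
        pd.testing.assert_frame_equal(out.fv, rep.fv)

    def test_invertible_to_1e9(self):
        rep = self._report(3.21)
        back = shrinkage_invert(shrinkage_correct(rep, 0.259))
        assert abs(back.nl.loc[1, "small"] - 3.21) < 1e-9

    def test_diameter_migrates_bin_after_correction(self):
        d = corrected_diameter(7.0, 0.259)
        assert d == pytest.approx(7.0 / 0.741, rel=1e-9)
        assert d == pytest.approx(9.446, abs=0.005)
        bins = DiameterBins()
        assert bins.assign(7.0) == 0      # small when measured
        assert bins.assign(d) == 1        # medium after shrinkage correction

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_correct(self._report(), 1.0)


class TestDistribution:
    def _labels(self, arr, names=None):
        return LabelVolume(np.asarray(arr, dtype=np.uint16), (1, 1, 1), names=names or {})

    def test_vessel_inside_single_region(self):
        v = np.zeros((4, 4, 4), int)
        r = np.ones((4, 4, 4), int)
        v[1:3, 1:3, 1:3] = 7
        m = distribution_proportions(self._labels(v), self._labels(r))
        assert m.frame.loc[7, 1] == pytest.approx(1.0)
        assert m.frame.loc[7, "unassigned"] == 0.0

    def test_fifty_fifty_split(self):
        v = np.zeros((4, 4, 4), int)
        v[0, 0, :4] = 3
        r = np.zeros((4, 4, 4), int)
        r[:, :, :2] = 1
        r[:, :, 2:] = 2
        m = distribution_proportions(self._labels(v), self._labels(r))
        assert m.frame.loc[3, 1] == pytest.approx(0.5)
        assert m.frame.loc[3, 2] == pytest.approx(0.5)

    def test_tube_crossing_slabs_matches_voxel_count_oracle(self, default_scene):
        filled = LabelVolume(
            _filled_regions(default_scene), default_scene.params.voxel_size_um
        )
        m = distribution_proportions(default_scene.vessel_labels, filled)
        vl = default_scene.vessel_labels.voxels
        for vid in default_scene.vessel_labels.labels():
            name = default_scene.vessel_labels.names[int(vid)]
            sel = vl == vid
            total = sel.sum()
            for r in filled.labels():
                expected = np.count_nonzero(sel & (filled.voxels == r)) / total
                assert m.frame.loc[name, int(r)] == pytest.approx(expected, abs=1e-12)

    def test_rows_sum_to_one_including_unassigned(self, default_scene):
        m = distribution_proportions(
            default_scene.vessel_labels, default_scene.region_labels
        )
        np.testing.assert_allclose(m.frame.sum(axis=1), 1.0, atol=1e-9)

    def test_pial_rasterized_at_default_radii(self):
        from vascatlas.graph import TYPE_VEIN, VesselGraph

        pial = VesselGraph(
            np.array([1, 2]), np.array([TYPE_VEIN] * 2),
            np.array([100.0, 300.0]), np.array([200.0, 200.0]), np.array([200.0, 200.0]),
            np.array([5.0, 5.0]), np.array([-1, 1]),
        )
        shape = (40, 40, 40)  # 10 um voxels -> 400 um cube
        v = self._labels(np.zeros(shape, int))
        v.voxel_size_um = (10.0, 10.0, 10.0)
        r = self._labels(np.ones(shape, int))
        r.voxel_size_um = (10.0, 10.0, 10.0)
        m = distribution_proportions(v, r, pial_graph=pial)
        # rendered with the 250 um vein radius: a thick slab of voxels appears
        assert m.voxel_counts.iloc[0] > 4.0 / 3 * np.pi * 25**3 * 0.2  # >> thin-tube volume
        np.testing.assert_allclose(m.frame.sum(axis=1), 1.0, atol=1e-9)

    def test_mean_distribution_row_stochastic(self):
        rng = np.random.default_rng(3)
        mats = []
        for _ in range(5):
            raw = rng.random((4, 3))
            raw /= raw.sum(axis=1, keepdims=True)
            frame = pd.DataFrame(raw, index=list("abcd"), columns=[1, 2, "unassigned"])
            mats.append(DistributionMatrix(frame=frame))
        mean = mean_distribution(mats)
        np.testing.assert_allclose(mean.frame.sum(axis=1), 1.0, atol=1e-9)

    def test_mean_of_identical_is_identity(self):
        frame = pd.DataFrame([[1.0, 0.0]], index=["v"], columns=[1, "unassigned"])
        m = DistributionMatrix(frame=frame)
        out = mean_distribution([m, m])
        pd.testing.assert_frame_equal(out.frame, frame)

    def test_mean_of_opposites_is_half(self):
        f1 = pd.DataFrame([[1.0, 0.0]], index=["v"], columns=[1, "unassigned"])
        f2 = pd.DataFrame([[0.0, 1.0]], index=["v"], columns=[1, "unassigned"])
        out = mean_distribution([DistributionMatrix(f1), DistributionMatrix(f2)])
        assert out.frame.loc["v", 1] == pytest.approx(0.5)

    def test_bad_row_sum_rejected(self):
        frame = pd.DataFrame([[0.7, 0.2]], index=["v"], columns=[1, "unassigned"])
        with pytest.raises(ValueError, match="sum to 1"):
            DistributionMatrix(frame=frame)


def _filled_regions(scene):
    from vascatlas.quant import fill_region_labels

    domain = scene.brain_mask.voxels | scene.vessel_mask.voxels
    return fill_region_labels(scene.region_labels, domain=domain).astype(np.uint16)


def binary_tree_graph(trunk_d=100.0, child_d=60.0, grandchild_d=20.0, mirror_x=0.0):
    """Trunk splitting into 2 children, each splitting into 2 grandchildren."""
    ids, tc, xs, ys, zs, rs, ps = [], [], [], [], [], [], []

    def add(x, y, z, r, parent):
        ids.append(len(ids) + 1)
        tc.append(5)
        xs.append(x + mirror_x)
        ys.append(y)
        zs.append(z)
        rs.append(r / 2)
        ps.append(parent)
        return ids[-1]

    t0 = add(100, 0, 0, trunk_d, -1)
    t1 = add(100, 0, 100, trunk_d, t0)
    for dx in (-40, 40):
        c0 = add(100 + dx, 0, 160, child_d, t1)
        for dy in (-30, 30):
            add(100 + dx, dy, 220, grandchild_d, c0)
    return VesselGraph(
        np.array(ids), np.array(tc), np.array(xs, float), np.array(ys, float),
        np.array(zs, float), np.array(rs, float), np.array(ps),
    )


class TestBranchLevels:
    def test_single_trunk_is_one_first_level_branch(self):
        g = line_graph([(0, 0, 0), (100, 0, 0), (200, 0, 0)], [50.0, 50.0, 50.0])
        df = count_branch_levels(g)
        assert df.loc[1, "total"] == 1
        assert df.loc[2, "total"] == 0
        assert df.loc[3, "total"] == 0

    def test_constructed_tree_counts_1_2_4(self):
        df = count_branch_levels(binary_tree_graph())
        assert df["total"].tolist() == [1, 2, 4]

    def test_mirrored_tree_equal_left_right(self):
        left = binary_tree_graph(mirror_x=-400.0)
        right = binary_tree_graph(mirror_x=+400.0)
        from vascatlas.graph import VesselGraph as VG

        both = VG.concatenate([left, right])
        df = count_branch_levels(both, side_plane_x_um=100.0)
        assert (df["left"] == df["right"]).all()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="root"):
            count_branch_levels(VesselGraph.empty())

    def test_cutoffs_must_decrease(self):
        with pytest.raises(ValueError):
            LevelCutoffs(level1_min_um=40.0, level2_min_um=90.0)


class TestAnnotation:
    @pytest.mark.parametrize(
        "orient, region, kind, connected, expected",
        [
            (["anterior"], "striate", "artery", None, "anterior-striate-artery"),
            (["dorsal", "lateral"], "HIP", "vein", None, "dorsal-lateral-HIP-vein"),
            (["medial"], None, "vein", "Lhiv", "medial-branch of-Lhiv"),
        ],
    )
    def test_naming_rules(self, orient, region, kind, connected, expected):
        assert annotate_vessel(orient, region, kind, connected) == expected

    def test_too_many_orientations_rejected(self):
        with pytest.raises(ValueError):
            annotate_vessel(["a", "b", "c", "d"], "HIP", "vein")


class TestCompareRegions:
    def test_identical_groups_f_zero(self):
        res = compare_regions({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)

    def test_matches_hand_computed_msb_msw(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]}
        res = compare_regions(groups)
        # grand mean 3; SSB = 3*(2-3)^2 + 3*(3-3)^2 + 3*(4-3)^2 = 6; MSB = 3
        # SSW = 3 groups * 2 = 6; MSW = 1; F = 3
        assert res.f_statistic == pytest.approx(3.0)
        f_sp, p_sp = stats.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f_sp)
        assert res.p_value == pytest.approx(p_sp)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = compare_regions({"a": a, "b": b})
        t, p = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_pairwise_grid_symmetric(self):
        res = compare_regions({"a": [1, 2, 3], "b": [2, 3, 4], "c": [5, 6, 9]})
        pd.testing.assert_frame_equal(res.pairwise_p, res.pairwise_p.T)

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compare_regions({"a": [1, 1], "b": [2, 2]})


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.01, 0.6), st.floats(0.1, 50.0))
def test_shrinkage_round_trip_property(s, nl):
    frame = pd.DataFrame({"small": [nl], "medium": [0.0], "large": [0.0], "total": [nl]}, index=[1])
    rep = DensityReport(fv=frame / 1000.0, nl=frame)
    back = shrinkage_invert(shrinkage_correct(rep, s))
    assert abs(back.nl.loc[1, "small"] - nl) < 1e-9 * max(1.0, nl)
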