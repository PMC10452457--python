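import numpy as np
import pytest

from asset_lv import (
    RunConfig,
    SEGMENT_NAMES,
    SectorScheme,
    UndefinedAzimuthError,
    ValidationError,
    VolumeGrid,
    assign_segments,
    close_segments,
    compute_plax,
    dice,
    make_myocardium,
    orient_base_to_apex,
    region_planes,
    run_asset,
    sector_label,
)
from asset_lv.geometry import Axis, angle_between_lines
from asset_lv.phantom import PhantomSpec, make_lv_phantom
from asset_lv.segmentation import RegionPlanes
from conftest import cylinder_mask, rotation4


class TestRegionPlanes:
    def test_phantom_construction_geometry(self):
        """Phantom with base 0, cavity tip 70, apex tip 90 (wall 20 mm).

        Uses the phantom's analytic shell/cavity so the expected plane
        positions follow from construction geometry alone.
        """
        from asset_lv.myocardium import MyocardiumSet

        ph = make_lv_phantom(PhantomSpec(wall_mm=20.0))
        myo = ph.truth_labels.data > 0
        cavity = ph.lv_mask.data.astype(bool) & ~myo
        ms = MyocardiumSet(
            myo=ph.lv_mask.with_data(myo),
            cavity=ph.lv_mask.with_data(cavity),
            thickness_mm=20.0,
        )
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        # convert to absolute axial position in the phantom frame (base = 0)
        offset = float(ax.axial_coord(ph.true_axis.anchor)[0])
        got = np.array([planes.t0, planes.t1, planes.t2, planes.t3, planes.t4])
        got -= offset
        half_vox = 0.5 * max(ph.lv_mask.spacing)
        expected = [0.0, 70.0 / 3, 140.0 / 3, 70.0, 90.0]
        assert np.allclose(got, expected, atol=half_vox + 1e-9)

    def test_fraction_rule_closed_form(self):
        """apex_rule=fraction 0.2 with extent [0,100] -> t3=80, t1=26.67, t2=53.33."""
        grid = cylinder_mask(20.0, 100.0, inner_radius_mm=15.0)
        ms = make_myocardium(grid, 8.0)  # hollow: cavity empty
        ax = Axis([0, 0, 0], [0, 0, 1], 0.0, 100.0)
        planes = region_planes(ms, ax, apex_rule=("fraction", 0.2))
        t0 = planes.t0
        assert planes.t3 - t0 == pytest.approx(0.8 * (planes.t4 - t0), abs=1e-9)
        assert planes.t1 - t0 == pytest.approx((planes.t3 - t0) / 3, abs=1e-9)
        assert planes.t2 - t0 == pytest.approx(2 * (planes.t3 - t0) / 3, abs=1e-9)
        assert planes.t4 - t0 == pytest.approx(100.0, abs=1.0)

    def test_equal_spans_invariant(self, voxel_result):
        p = voxel_result.planes
        spans = (p.t1 - p.t0, p.t2 - p.t1, p.t3 - p.t2)
        assert max(spans) - min(spans) < 1e-6

    def test_cavity_tip_requires_cavity(self):
        grid = cylinder_mask(20.0, 100.0, inner_radius_mm=15.0)
        ms = make_myocardium(grid, 8.0)
        ax = Axis([0, 0, 0], [0, 0, 1], 0.0, 100.0)
        with pytest.raises(ValidationError):
            region_planes(ms, ax, apex_rule="cavity_tip")

    def test_unordered_planes_rejected(self):
        with pytest.raises(ValidationError):
            RegionPlanes(0.0, 30.0, 20.0, 60.0, 80.0)
        with pytest.raises(ValidationError):
            RegionPlanes(0.0, 10.0, 20.0, 35.0, 80.0)  # unequal spans


class TestSectorLabel:
    def test_apex_ignores_theta(self):
        assert sector_label("apex", 123.4) == 17

    def test_basal_mid_anterior_at_30(self):
        assert sector_label("basal", 30.0) == 1
        assert sector_label("mid", 30.0) == 7

    def test_apical_boundaries(self):
        assert sector_label("apical", 30.0) == 13
        assert sector_label("apical", 300.0) == 14

    @pytest.mark.parametrize(
        "region,order",
        [
            ("basal", (1, 6, 5, 4, 3, 2)),
            ("mid", (7, 12, 11, 10, 9, 8)),
        ],
    )
    def test_sixty_degree_sector_order(self, region, order):
        for k, lab in enumerate(order):
            assert sector_label(region, 60.0 * k) == lab
            assert sector_label(region, 60.0 * k + 59.999) == lab

    def test_apical_ninety_degree_sectors(self):
        for lo, lab in zip((-15.0, 75.0, 165.0, 255.0), (13, 16, 15, 14)):
            assert sector_label("apical", lo % 360.0) == lab
            assert sector_label("apical", (lo + 89.999) % 360.0) == lab

    def test_total_function_wraps(self):
        assert sector_label("basal", 359.9999) == 2
        assert sector_label("apical", 359.0) == 13  # inside [-15, 75)

    def test_unknown_region(self):
        with pytest.raises(ValidationError):
            sector_label("equator", 10.0)

    def test_scheme_boundaries_and_widths(self):
        scheme = SectorScheme(ref_dir=[1, 0, 0])
        for lab in range(1, 13):
            lo, hi = scheme.segment_boundaries(lab)
            assert hi - lo == pytest.approx(60.0)
        for lab in range(13, 17):
            lo, hi = scheme.segment_boundaries(lab)
            assert hi - lo == pytest.approx(90.0)
        assert scheme.segment_boundaries(13) == (-15.0, 75.0)
        with pytest.raises(ValidationError):
            scheme.segment_boundaries(17)


class TestAssignSegments:
    def test_partition_of_myocardium(self, default_phantom):
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        res = assign_segments(ms, ax, ph.rv_point, planes)
        labels = res.labels.data
        assert ((labels > 0) == ms.myo.data).all()
        assert set(np.unique(labels)) - {0} == set(range(1, 18))

    def test_agreement_with_analytic_oracle_on_oracle_support(self, default_phantom):
        """Assignment logic vs the closed-form oracle on the same shell: >=99%."""
        ph = default_phantom
        truth = ph.truth_labels.data
        myo = truth > 0
        from asset_lv.myocardium import MyocardiumSet

        # cavity = analytic cavity (inside LV, not myocardium)
        cavity = ph.lv_mask.data.astype(bool) & ~myo
        ms = MyocardiumSet(
            myo=ph.lv_mask.with_data(myo),
            cavity=ph.lv_mask.with_data(cavity),
            thickness_mm=8.0,
        )
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        res = assign_segments(ms, ax, ph.rv_point, planes)
        agree = (res.labels.data[myo] == truth[myo]).mean()
        assert agree >= 0.99

    def test_rv_on_axis_rejected(self, default_phantom):
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        on_axis = ax.point_at(0.5 * (planes.t0 + planes.t4))
        with pytest.raises(UndefinedAzimuthError):
            assign_segments(ms, ax, on_axis, planes)

    def test_rv_outside_extent_warns(self, default_phantom):
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        far = ph.rv_point + ax.direction * 500.0
        res = assign_segments(ms, ax, far, planes)
        assert any("outside the axial extent" in w for w in res.warnings)

    def test_rotating_rv_by_60_permutes_basal_and_mid(self, default_phantom):
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        res0 = assign_segments(ms, ax, ph.rv_point, planes)

        # rotate the RV point by +60 deg about the axis
        d = ax.direction
        v = ax.radial_vector(ph.rv_point)[0]
        t = float(ax.axial_coord(ph.rv_point)[0])
        c, s = np.cos(np.radians(60.0)), np.sin(np.radians(60.0))
        v_rot = c * v + s * np.cross(d, v)
        rv60 = ax.point_at(t) + v_rot
        res60 = assign_segments(ms, ax, rv60, planes)

        # permutation forced by the sector tables: a voxel at old azimuth
        # theta sits at theta-60 in the rotated frame, so the basal ring
        # cycles anterior->anteroseptal->... and likewise for mid.  Apical
        # 90-degree sectors do not commute with a 60-degree turn and are
        # excluded.
        perm = {1: 2, 2: 3, 3: 4, 4: 5, 5: 6, 6: 1,
                7: 8, 8: 9, 9: 10, 10: 11, 11: 12, 12: 7}
        sel = (res0.labels.data >= 1) & (res0.labels.data <= 12)
        mapped = np.vectorize(perm.get)(res0.labels.data[sel])
        agree = (mapped == res60.labels.data[sel]).mean()
        assert agree > 0.99  # voxel-boundary ties only

    def test_flip_rotation_mirrors_labels(self, default_phantom):
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        res = assign_segments(ms, ax, ph.rv_point, planes, flip_rotation=True)
        # chirality flip sends azimuth theta to -theta: sector [0,60) maps to
        # (300,360], so anterior<->anteroseptal, anterolateral<->inferoseptal,
        # inferolateral<->inferior.  Apical sectors are not symmetric about
        # the reference and do not permute cleanly; the apex is unaffected.
        normal = assign_segments(ms, ax, ph.rv_point, planes)
        swap = {1: 2, 2: 1, 6: 3, 3: 6, 5: 4, 4: 5,
                7: 8, 8: 7, 12: 9, 9: 12, 11: 10, 10: 11}
        sel = (normal.labels.data >= 1) & (normal.labels.data <= 12)
        mapped = np.vectorize(swap.get)(normal.labels.data[sel])
        assert (mapped == res.labels.data[sel]).mean() > 0.99
        assert ((normal.labels.data == 17) == (res.labels.data == 17)).all()


class TestCloseSegments:
    def test_radius_zero_identity(self, voxel_result):
        out = close_segments(voxel_result, 0.0)
        assert out is voxel_result

    def test_punched_hole_filled(self, default_phantom):
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        res = assign_segments(ms, ax, ph.rv_point, planes)
        labels = res.labels.data.copy()
        # pick an interior voxel of some segment (all 6-neighbors same label)
        from scipy import ndimage as ndi

        seg = labels == 7
        interior = ndi.binary_erosion(seg, ndi.generate_binary_structure(3, 1),
                                      iterations=2)
        ijk = tuple(np.argwhere(interior)[0])
        labels[ijk] = 0
        punched = res.labels.with_data(labels)
        from asset_lv.segmentation import SegmentationResult

        res2 = SegmentationResult(punched, res.axis, res.planes, res.scheme)
        out = close_segments(res2, 2.0, myo=ms.myo.data)
        assert out.labels.data[ijk] == 7

    def test_partition_preserved_on_phantom(self, default_phantom, voxel_result):
        myo = make_myocardium(default_phantom.lv_mask).myo.data
        labels = voxel_result.labels.data
        assert ((labels > 0) == myo).all()


class TestRunAsset:
    def test_all_17_labels_present(self, voxel_result):
        assert voxel_result.present_labels() == list(range(1, 18))

    def test_partition_invariant(self, default_phantom, voxel_result):
        myo = make_myocardium(default_phantom.lv_mask).myo.data
        assert ((voxel_result.labels.data > 0) == myo).all()

    def test_cross_mode_dice(self, voxel_result, surface_result):
        for lab in range(1, 18):
            a = voxel_result.labels.with_data(voxel_result.labels.data == lab)
            b = surface_result.labels.with_data(surface_result.labels.data == lab)
            assert dice(a, b) >= 0.85, f"label {lab} ({SEGMENT_NAMES[lab]})"

    def test_surface_mode_is_partition_too(self, default_phantom, surface_result):
        myo = make_myocardium(default_phantom.lv_mask).myo.data
        assert ((surface_result.labels.data > 0) == myo).all()

    def test_on_axis_rv_point_errors(self, default_phantom):
        ph = default_phantom
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        on_axis = ax.point_at(10.0)
        with pytest.raises(UndefinedAzimuthError):
            run_asset(ph.lv_mask, on_axis, RunConfig(closing_radius_mm=0.0))

    def test_provenance_recorded(self, voxel_result):
        assert voxel_result.config["thickness_mm"] == 8.0
        assert voxel_result.config["mode"] == "voxel"
        assert "compute_plax" in voxel_result.timings_s

    def test_basal_cut_config(self, default_phantom):
        ph = default_phantom
        cfg = RunConfig(closing_radius_mm=0.0)
        base = run_asset(ph.lv_mask, ph.rv_point, cfg)
        t_cut = base.planes.t0 + 10.0
        cut = run_asset(
            ph.lv_mask, ph.rv_point,
            RunConfig(closing_radius_mm=0.0, basal_cut_t=t_cut),
        )
        t = base.axis.axial_coord(cut.labels.mask_world_coords())
        assert (t >= t_cut - 1e-6).all()
        assert cut.labels.count() < base.labels.count()

    def test_rigid_motion_equivariance(self, default_phantom, voxel_result):
        """Rigidly moving the grid affine + RV point relabels identically up
        to 1-voxel boundary differences."""
        from conftest import assert_mismatches_on_decision_boundaries

        ph = default_phantom
        T = rotation4([17, -25, 40], order="xyz", translation=(5.0, -7.0, 11.0))
        moved = VolumeGrid(ph.lv_mask.data, T @ ph.lv_mask.affine)
        rv_moved = T[:3, :3] @ ph.rv_point + T[:3, 3]
        res2 = run_asset(moved, rv_moved, RunConfig())
        assert_mismatches_on_decision_boundaries(voxel_result, res2, ph.lv_mask)

    def test_axis_perturbation_monotone_degradation(self, default_phantom):
        """Pipeline with an axis tilted by 0 / 3.5 / 7 degrees: mean per-segment
        DSC against the unperturbed result degrades monotonically."""
        ph = default_phantom
        ms = make_myocardium(ph.lv_mask)
        ax = orient_base_to_apex(compute_plax(ph.lv_mask), ph.lv_mask)
        planes = region_planes(ms, ax)
        ref = assign_segments(ms, ax, ph.rv_point, planes)

        def tilted_mean_dsc(angle_deg):
            R = rotation4([angle_deg, 0, 0], order="xyz")[:3, :3]
            d = R @ ax.direction
            ax_t = Axis(ax.anchor, d, ax.t_min, ax.t_max)
            planes_t = region_planes(ms, ax_t)
            res = assign_segments(ms, ax_t, ph.rv_point, planes_t)
            vals = []
            for lab in range(1, 18):
                vals.append(dice(
                    ref.labels.with_data(ref.labels.data == lab),
                    res.labels.with_data(res.labels.data == lab),
                ))
            return float(np.mean(vals))

        d0, d35, d7 = (tilted_mean_dsc(a) for a in (0.0, 3.5, 7.0))
        assert d0 == pytest.approx(1.0, abs=1e-12)
        assert d0 >= d35 >= d7
        assert d7 > 0.5  # still a smooth, modest degradation
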