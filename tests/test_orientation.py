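"""Skeletonisation, segment extraction, angles, classification and indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteovasc import orientation as ori
from osteovasc import phantom as ph
from osteovasc.errors import (DegenerateInputError, FitFailureError,
                              UndefinedGeometryError)
from osteovasc.volumes import BinaryVolume

from conftest import make_cylinder


def _segment(direction, midpoint=(100.0, 0.0, 50.0), length=30.0,
             frame=ori.BoneFrame(center=(0.0, 0.0))):
    v = np.asarray(direction, float)
    v = v / np.linalg.norm(v)
    mid = np.asarray(midpoint, float)
    tl = ori.longitudinal_angle(v)
    tr = ori.radial_angle(mid, v, frame)
    return ori.CanalSegment(
        endpoints=np.stack([mid - length / 2 * v, mid + length / 2 * v]),
        midpoint=mid, direction=v, chord_length=length, path_length=length,
        theta_long=tl, theta_rad=tr, category=ori.classify_segment(tl, tr))


class TestAngles:
    @pytest.mark.parametrize("v,expected", [
        ((0, 0, 1), 90.0), ((1, 0, 0), 0.0), ((1, 0, 1), 45.0), ((0, 0, -1), 90.0),
    ])
    def test_longitudinal_angle(self, v, expected):
        assert ori.longitudinal_angle(np.asarray(v, float) / np.linalg.norm(v)) \
            == pytest.approx(expected)

    @pytest.mark.parametrize("v,expected", [
        ((0, 1, 0), 0.0),   # circumferential
        ((1, 0, 0), 90.0),  # radial spoke
        ((0, 0, 1), 0.0),   # axial
    ])
    def test_radial_angle_at_reference_midpoint(self, v, expected):
        frame = ori.BoneFrame(center=(0.0, 0.0))
        mid = np.array([150.0, 0.0, 50.0])
        assert ori.radial_angle(mid, np.asarray(v, float), frame) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ori.longitudinal_angle((0, 0, 0))

    def test_midpoint_on_axis_rejected(self):
        frame = ori.BoneFrame(center=(10.0, 10.0))
        with pytest.raises(UndefinedGeometryError):
            ori.radial_angle(np.array([10.0, 10.0, 5.0]), np.array([1.0, 0, 0]), frame)

    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=200, derandomize=True)
    def test_angles_sign_free(self, x, y, z):
        v = np.array([x, y, z])
        if np.linalg.norm(v) < 1e-6:
            return
        v = v / np.linalg.norm(v)
        frame = ori.BoneFrame(center=(0.0, 0.0))
        mid = np.array([200.0, 40.0, 10.0])
        assert ori.longitudinal_angle(v) == pytest.approx(ori.longitudinal_angle(-v))
        assert ori.radial_angle(mid, v, frame) == pytest.approx(ori.radial_angle(mid, -v, frame))


class TestClassification:
    @pytest.mark.parametrize("tl,tr,expected", [
        (70, 50, "longitudinal"),
        (30, 80, "radial"),
        (30, 10, "laminar"),
        (30, 45, "oblique"),
        (67.5, 0, "longitudinal"),   # boundary: longitudinal wins
        (30, 67.5, "radial"),        # boundary: radial box inclusive
        (30, 22.5, "laminar"),       # boundary: laminar box inclusive
    ])
    def test_examples(self, tl, tr, expected):
        assert ori.classify_segment(tl, tr) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ori.classify_segment(91, 10)
        with pytest.raises(ValueError):
            ori.classify_segment(10, -1)

    def test_grid_sweep_matches_truth_table(self):
        """0.1-degree sweep over [0,90]^2 against an independent evaluation
        of the three category boxes plus the oblique complement."""
        tl, tr = np.meshgrid(np.arange(0, 90.05, 0.1), np.arange(0, 90.05, 0.1),
                             indexing="ij")
        got = ori.classify_many(tl, tr)
        in_longitudinal = (tl >= 67.5) & (tl <= 90.0)
        in_radial = (tl <= 67.5) & (tr >= 67.5) & (tr <= 90.0)
        in_laminar = (tl <= 67.5) & (tr <= 22.5)
        expected = np.full(tl.shape, "oblique", dtype=object)
        expected[in_laminar] = "laminar"
        # overlap resolution: radial beats laminar (impossible anyway),
        # longitudinal beats both
        expected[in_radial] = "radial"
        expected[in_longitudinal] = "longitudinal"
        assert (got == expected).all()


class TestSkeleton:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        skel = ori.skeletonize(BinaryVolume(m, 1.0))
        assert np.array_equal(skel.voxels, m)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            ori.skeletonize(BinaryVolume(np.zeros((4, 4, 4), dtype=bool), 1.0))

    def test_cylinder_skeleton_on_centreline(self):
        """Radius-5 cylinder: every skeleton voxel within 1 voxel of the true
        centreline; single chord within 5% of the true length."""
        cv = make_cylinder(10, 170, voxel_size=1.0, pad_z=5)
        skel = ori.skeletonize(cv)
        zs, ys, xs = np.nonzero(skel.voxels)
        c = cv.shape[1] // 2
        assert np.hypot(xs - c, ys - c).max() <= 1.0
        segs = ori.extract_segments(skel, ori.BoneFrame(center=(0.0, 0.0)))
        assert len(segs) == 1
        assert abs(segs[0].chord_length - 169.0) / 169.0 <= 0.05

    def test_thin_cylinder_endpoints_near_ends(self):
        """Radius-4 cylinder: branch-end retraction stays within 2 voxels."""
        cv = make_cylinder(8, 120, voxel_size=1.0, pad_z=5)
        skel = ori.skeletonize(cv)
        zs = np.nonzero(skel.voxels)[0]
        assert zs.min() - 5 <= 2 and 124 - zs.max() <= 2

    def test_y_shape_three_segments(self):
        """Union of three tubes meeting at a point: three endpoints, one
        branch neighbourhood, three extracted segments."""
        n = 60
        m = np.zeros((n, n, n), dtype=bool)
        center = np.array([30.0, 30.0, 30.0])
        dirs = [np.array([0, 0, 1.0]), np.array([0, 1.0, 0]), np.array([0, -0.7, -0.7])]
        zz, yy, xx = np.mgrid[:n, :n, :n]
        pts = np.stack([zz, yy, xx], axis=-1).astype(float)
        for d in dirs:
            d = d / np.linalg.norm(d)
            rel = pts - center
            t = np.clip((rel * d).sum(-1), 0, 25)
            proj = center + t[..., None] * d  # (z, y, x) order throughout
            dist = np.linalg.norm(pts - proj, axis=-1)
            m |= dist <= 3.0
        skel = ori.skeletonize(BinaryVolume(m, 1.0))
        coords, adj = ori._skeleton_graph(skel.voxels)
        deg = np.array([len(a) for a in adj])
        assert (deg == 1).sum() == 3       # three endpoints
        assert (deg >= 3).sum() >= 1       # one branch neighbourhood
        segs = ori.extract_segments(skel, ori.BoneFrame(center=(-50.0, -50.0)),
                                    min_length=5.0)
        assert len(segs) == 3

    def test_ring_skeleton_split_into_chords(self):
        """A closed ring decomposes into at least 2 chords (cycle split)."""
        n = 48
        z, y, x = np.ogrid[:9, :n, :n]
        rho = np.hypot(x - 24, y - 24)
        torus = np.sqrt((rho - 15) ** 2 + (z - 4) ** 2) <= 2.5
        skel = ori.skeletonize(BinaryVolume(torus, 1.0))
        segs = ori.extract_segments(skel, ori.BoneFrame(center=(-40.0, -40.0)))
        assert len(segs) >= 2


class TestIndices:
    def test_single_circumferential_segment(self):
        s = _segment((0, 1, 0))
        idx = ori.orientation_indices([s])
        assert idx.laminar_index == 1.0
        assert idx.longitudinal_index == idx.radial_index == idx.oblique_index == 0.0

    def test_length_weighting(self):
        a = _segment((0, 0, 1), length=2.0)   # longitudinal
        b = _segment((0, 1, 0), length=1.0)   # laminar
        idx = ori.orientation_indices([a, b])
        assert idx.longitudinal_index == pytest.approx(2 / 3)
        assert idx.laminar_index == pytest.approx(1 / 3)

    def test_empty_list_rejected(self):
        with pytest.raises(DegenerateInputError):
            ori.orientation_indices([])

    def test_indices_sum_to_one_and_in_unit_interval(self, phantom200):
        idx = phantom200["indices"]
        vals = [idx.laminar_index, idx.longitudinal_index, idx.radial_index,
                idx.oblique_index]
        assert abs(sum(vals) - 1.0) < 1e-9
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_removing_category_renormalises(self, phantom200):
        segs = [s for s in phantom200["segments"] if s.category != "laminar"]
        idx = ori.orientation_indices(segs)
        assert idx.laminar_index == 0.0
        assert abs(idx.longitudinal_index + idx.radial_index + idx.oblique_index - 1.0) < 1e-9

    def test_rotation_invariance_about_bone_axis(self, phantom200):
        """Rigid rotation of all segments about the bone axis leaves the
        length-weighted indices unchanged."""
        frame = phantom200["frame"]
        cx, cy = frame.center
        theta = np.radians(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])

        rotated = []
        for s in phantom200["segments"]:
            mid = s.midpoint.copy()
            mid[:2] = R @ (mid[:2] - [cx, cy]) + [cx, cy]
            v = s.direction.copy()
            v[:2] = R @ v[:2]
            tl = ori.longitudinal_angle(v)
            tr = ori.radial_angle(mid, v, frame)
            rotated.append(ori.CanalSegment(
                endpoints=s.endpoints, midpoint=mid, direction=v,
                chord_length=s.chord_length, path_length=s.path_length,
                theta_long=tl, theta_rad=tr,
                category=ori.classify_segment(tl, tr)))
        a = ori.orientation_indices(phantom200["segments"])
        b = ori.orientation_indices(rotated)
        for k in ("laminar_index", "longitudinal_index", "radial_index", "oblique_index"):
            assert a.as_dict()[k] == pytest.approx(b.as_dict()[k], abs=1e-9)

    def test_angle_recovery_error_small_on_phantom(self, phantom200):
        """Segment-level angle error: median per-segment nearest-truth error
        is small; chord-weighted index error is covered elsewhere."""
        gt = phantom200["vols"].spec.canal_specs
        gt_mid = np.array([0.5 * (c.centerline[0] + c.centerline[-1]) for c in gt])
        gt_tl = np.array([c.true_longitudinal_angle for c in gt])
        errs = []
        for s in phantom200["segments"]:
            if s.chord_length < 40.0:
                continue
            i = int(np.argmin(np.linalg.norm(gt_mid - s.midpoint, axis=1)))
            if np.linalg.norm(gt_mid[i] - s.midpoint) > 30.0:
                continue
            errs.append(abs(s.theta_long - gt_tl[i]))
        assert len(errs) > 30
        assert np.mean(errs) <= 5.0


class TestEstimateCenter:
    def test_full_ring_center_within_one_voxel(self):
        n = 160
        z, y, x = np.ogrid[:1, :n, :n]
        rho = np.hypot((x + 0.5) - 80.3, (y + 0.5) - 79.6)
        ring = np.broadcast_to((rho >= 40) & (rho <= 70), (10, n, n)).copy()
        frame = ori.estimate_center(BinaryVolume(ring, 2.0))
        # world-space truth: centre voxel coordinates x 2 um
        assert abs(frame.center[0] - 80.3 * 2) <= 2.0
        assert abs(frame.center[1] - 79.6 * 2) <= 2.0

    def test_quadrant_sector_center_within_three_voxels(self):
        spec = ph.PhantomSpec(outer_radius=300, cortical_thickness=150, height=40,
                              sector=(0.0, 90.0), noise_sd=0.0)
        vols = ph.render_phantom(spec)
        frame = ori.estimate_center(vols.bone_truth)
        cx, cy = spec.center_um()
        assert np.hypot(frame.center[0] - cx, frame.center[1] - cy) <= 3 * spec.voxel_size

    def test_straight_slab_rejected(self):
        m = np.zeros((10, 40, 40), dtype=bool)
        m[:, 10:20, :] = True
        with pytest.raises(FitFailureError):
            ori.estimate_center(BinaryVolume(m, 1.0))

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            ori.estimate_center(BinaryVolume(np.zeros((4, 4, 4), dtype=bool), 1.0))
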