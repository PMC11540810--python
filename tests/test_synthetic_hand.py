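"""Kinematic simulator: templates, posing, projection, dataset generation."""

import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import thumbrom.synthetic_hand as sh
from thumbrom import (
    ProjectionError,
    ValidationError,
    compute_features,
    direct_angle_estimate,
    write_landmark_table,
)
from thumbrom.landmarks_io import HandLandmarkFrame

PALM = list(sh.PALM_LANDMARKS)
CHAIN = list(sh.THUMB_CHAIN)


class TestMakeTemplate:
    def test_deterministic(self):
        a = sh.make_template(11, 1.0)
        b = sh.make_template(11, 1.0)
        np.testing.assert_array_equal(a.points3d, b.points3d)

    def test_homogeneous_scaling_doubles_distances(self):
        a = sh.make_template(5, 1.0).points3d
        b = sh.make_template(5, 2.0).points3d
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        np.testing.assert_allclose(db, 2.0 * da, rtol=1e-12, atol=1e-12)

    def test_palm_coplanar(self):
        for seed in range(5):
            pts = sh.make_template(seed, 1.0).points3d
            assert np.abs(pts[PALM, 2]).max() < 1e-9

    def test_bone_lengths_positive(self):
        pts = sh.make_template(3, 1.0).points3d
        for i in range(1, 21):
            assert np.linalg.norm(pts[i] - pts[sh._PARENT[i]]) > 0.1

    def test_rejects_non_positive_scale(self):
        with pytest.raises(ValidationError):
            sh.make_template(0, 0.0)


class TestPoseHand:
    def test_zero_abduction_is_identity(self):
        tpl = sh.make_template(2, 1.0)
        np.testing.assert_array_equal(sh.pose_hand(tpl, 0.0), tpl.points3d)

    def test_non_thumb_landmarks_fixed(self):
        tpl = sh.make_template(2, 1.0)
        posed = sh.pose_hand(tpl, 60.0)
        others = [i for i in range(21) if i not in CHAIN]
        np.testing.assert_array_equal(posed[others], tpl.points3d[others])

    @pytest.mark.parametrize("angle", [10.0, 45.0, 80.0])
    def test_rigid_chain_distances_preserved(self, angle):
        tpl = sh.make_template(4, 1.0)
        posed = sh.pose_hand(tpl, angle)
        for i in CHAIN:
            for j in CHAIN + [0]:
                before = np.linalg.norm(tpl.points3d[i] - tpl.points3d[j])
                after = np.linalg.norm(posed[i] - posed[j])
                assert after == pytest.approx(before, rel=1e-9)

    def test_inverse_rotation_restores_template(self):
        tpl = sh.make_template(6, 1.0)
        posed = sh.pose_hand(tpl, 50.0)
        axis = sh._abduction_axis(tpl.points3d)
        undo = Rotation.from_rotvec(np.radians(50.0) * axis)
        restored = undo.apply(posed[CHAIN])
        np.testing.assert_allclose(restored, tpl.points3d[CHAIN], atol=1e-9)

    @pytest.mark.parametrize("angle", [-5.0, 95.0])
    def test_rejects_angle_outside_range(self, angle):
        with pytest.raises(ValidationError):
            sh.pose_hand(sh.make_template(0, 1.0), angle)


class TestProjection:
    def test_point_on_optical_axis_hits_principal_point(self):
        cam = sh.CameraPose()
        pts = np.tile(sh.HAND_CENTER, (21, 1))
        pts[:, 2] = np.linspace(-5, 5, 21)  # along the frontal optical axis
        frame = sh.project_to_camera(pts, cam)
        np.testing.assert_allclose(frame.points,
                                   np.tile(cam.principal_point, (21, 1)),
                                   atol=1e-9)

    def test_doubling_distance_halves_span(self):
        tpl = sh.make_template(1, 1.0)
        posed = sh.pose_hand(tpl, 40.0)
        near = sh.project_to_camera(posed, sh.CameraPose(distance=70.0))
        far = sh.project_to_camera(posed, sh.CameraPose(distance=140.0))
        c = np.array(sh.CameraPose().principal_point)
        span_near = np.linalg.norm(near.points - c, axis=1).max()
        span_far = np.linalg.norm(far.points - c, axis=1).max()
        assert span_far / span_near == pytest.approx(0.5, rel=0.01)

    def test_frontal_planar_hand_projects_as_similarity(self):
        # a hand flattened into z = 0 seen frontally: angles and distance
        # ratios are preserved exactly by the pinhole map
        tpl = sh.make_template(8, 1.0)
        flat = tpl.points3d.copy()
        flat[:, 2] = 0.0
        frame = sh.project_to_camera(flat, sh.CameraPose())
        world = flat[:, :2]
        img = frame.points
        dw = np.linalg.norm(world[4] - world[0]) / np.linalg.norm(world[9] - world[0])
        di = np.linalg.norm(img[4] - img[0]) / np.linalg.norm(img[9] - img[0])
        assert di == pytest.approx(dw, rel=1e-9)

        def angle(p, a, b, v):
            u1, u2 = p[a] - p[v], p[b] - p[v]
            cosv = u1 @ u2 / np.linalg.norm(u1) / np.linalg.norm(u2)
            return np.degrees(np.arccos(np.clip(cosv, -1, 1)))

        for (a, b, v) in [(9, 4, 0), (5, 17, 0), (9, 2, 0)]:
            assert angle(img, a, b, v) == pytest.approx(angle(world, a, b, v),
                                                        abs=1e-9)

    def test_rejects_points_behind_camera(self):
        pts = np.tile(sh.HAND_CENTER, (21, 1))
        pts[0, 2] = 100.0  # beyond the camera at z = 70
        with pytest.raises(ProjectionError):
            sh.project_to_camera(pts, sh.CameraPose())

    def test_frame_carries_view_azimuth(self):
        posed = sh.pose_hand(sh.make_template(0, 1.0), 30.0)
        frame = sh.project_to_camera(posed, sh.CameraPose(azimuth_deg=30.0))
        assert frame.view_azimuth_deg == 30.0


class TestDetectorBias:
    def test_only_tip_landmark_moves(self, rng):
        pts = 400 + 200 * rng.random((21, 2))
        out = sh.DetectorBias().apply(pts)
        others = [i for i in range(21) if i != 4]
        np.testing.assert_array_equal(out[others], pts[others])

    def test_pull_decays_with_separation(self):
        tpl = sh.make_template(1, 1.0)
        cam = sh.CameraPose()
        bias = sh.DetectorBias()

        def pull_fraction(angle):
            frame = sh.project_to_camera(sh.pose_hand(tpl, angle), cam)
            out = bias.apply(frame.points)
            return (np.linalg.norm(out[4] - frame.points[4])
                    / np.linalg.norm(frame.points[4] - frame.points[8]))

        adducted, abducted = pull_fraction(0.0), pull_fraction(80.0)
        assert adducted > 0.85          # occluded tip collapses to the index
        assert abducted < 0.3           # visible tip is close to truth
        assert abducted < adducted / 2

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            sh.DetectorBias(strength=1.0)
        with pytest.raises(ValidationError):
            sh.DetectorBias(width=0.0)


class TestGenerateDataset:
    def test_size_and_labels(self):
        cfg = sh.SimConfig(n_subjects=2, angles_deg=(0, 40, 80),
                           frames_per_angle=4, azimuths_deg=(0.0, 30.0),
                           noise=sh.NoiseModel(sigma_px=1.0), seed=5)
        ds = sh.generate_dataset(cfg)
        assert len(ds) == 2 * 3 * 4 * 2 == cfg.n_frames
        assert sorted({f.true_angle_deg for f in ds}) == [0.0, 40.0, 80.0]
        assert {f.subject_id for f in ds} == {"S01", "S02"}
        assert {f.view_azimuth_deg for f in ds} == {0.0, 30.0}
        assert len({f.frame_id for f in ds}) == len(ds)

    def test_default_protocol_is_about_five_thousand_frames(self):
        cfg = sh.SimConfig()
        assert cfg.n_frames == 10 * 9 * 56 * 1 == 5040

    def test_same_seed_reproduces_identical_csv_bytes(self):
        cfg = sh.SimConfig(n_subjects=2, frames_per_angle=2, seed=9)
        bufs = []
        for _ in range(2):
            ds = sh.generate_dataset(cfg)
            buf = io.StringIO()
            ds.to_dataframe().to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seeds_differ(self):
        a = sh.generate_dataset(sh.SimConfig(n_subjects=1, frames_per_angle=1, seed=1))
        b = sh.generate_dataset(sh.SimConfig(n_subjects=1, frames_per_angle=1, seed=2))
        assert not np.array_equal(a.frames[0].points, b.frames[0].points)

    def test_rejects_bad_config(self):
        with pytest.raises(ValidationError):
            sh.SimConfig(angles_deg=(0, 95))
        with pytest.raises(ValidationError):
            sh.SimConfig(n_subjects=0)


class TestMonotoneObservability:
    """With zero jitter and a frontal camera, the projected thumb geometry
    grows monotonically with the commanded abduction for every subject."""

    @pytest.mark.parametrize("seed", [1, 38, 75, 112, 149])
    def test_direct_estimate_strictly_increasing(self, seed):
        tpl = sh.make_template(seed, 1.0)
        cam = sh.CameraPose()
        bias = sh.DetectorBias()
        vals = []
        for angle in range(0, 81, 10):
            frame = sh.project_to_camera(sh.pose_hand(tpl, angle), cam)
            detected = HandLandmarkFrame(0, bias.apply(frame.points))
            vals.append(direct_angle_estimate(detected))
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("feature", ["tip_joint_angle", "mp_joint_angle",
                                         "ip_joint_angle"])
    def test_thumb_angle_features_non_decreasing(self, feature):
        cam = sh.CameraPose()
        bias = sh.DetectorBias()
        for seed in (1, 38, 75):
            tpl = sh.make_template(seed, 1.0)
            vals = []
            for angle in range(0, 81, 10):
                frame = sh.project_to_camera(sh.pose_hand(tpl, angle), cam)
                detected = HandLandmarkFrame(0, bias.apply(frame.points))
                vals.append(getattr(compute_features(detected), feature))
            assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))
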