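"""rigid_kinematics: Kabsch pose, swing-twist angle, virtual points."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from manipkin.errors import DegenerateFrameError, RankDeficiencyError, WindowError
from manipkin.rigid_kinematics import (
    AngleSeries,
    Pose,
    RigidBodyDef,
    angle_series,
    axial_rotation_angle,
    build_body,
    estimate_pose,
    max_rotation_angle,
    virtual_points,
)
from manipkin.synthetic_data import SubjectParams, simulate_trial

from _oracles import grid_search_rotation, rotation_geodesic_deg, twist_about_z_by_search


def _random_body(rng, n_markers=5, name="body"):
    shape = rng.normal(scale=0.1, size=(n_markers, 3))
    return RigidBodyDef(name, tuple(f"m{i}" for i in range(n_markers)), shape)


def _identity_pose():
    return Pose(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# estimate_pose
# ---------------------------------------------------------------------------

class TestEstimatePose:
    def test_identity_on_reference(self, rng):
        body = _random_body(rng)
        frame = dict(zip(body.marker_labels, body.reference_shape))
        pose = estimate_pose(body, frame)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translation, 0.0, atol=1e-12)
        assert pose.residual_rmsd < 1e-12

    def test_known_transform_recovered(self, rng):
        body = _random_body(rng)
        rot = Rotation.from_euler("z", 30.0, degrees=True).as_matrix()
        trans = np.array([0.1, 0.0, 0.0])
        frame = {
            lb: rot @ p + trans for lb, p in zip(body.marker_labels, body.reference_shape)
        }
        pose = estimate_pose(body, frame)
        assert rotation_geodesic_deg(pose.rotation, rot) < 1e-9
        np.testing.assert_allclose(pose.translation, trans, atol=1e-12)

    @pytest.mark.parametrize("sigma_mm,p99_bound_deg", [(1.0, 1.5), (0.5, 0.75)])
    def test_monte_carlo_axial_angle_under_noise(self, rng, sigma_mm, p99_bound_deg):
        # 6-marker anatomical head cluster under per-axis Gaussian marker
        # noise: the axial-angle error's 99th percentile over 1000 draws is
        # bounded by the cluster's ~6 cm in-plane lever arm (error scales
        # linearly with sigma; 1 mm noise gives ~0.4 deg error SD)
        from manipkin.synthetic_data import _HEAD_LABELS, _SUBJECT_BASE

        shape = np.array([_SUBJECT_BASE[lb] for lb in _HEAD_LABELS], dtype=float)
        body = RigidBodyDef("head", _HEAD_LABELS, shape)
        errors = []
        for _ in range(1000):
            angle = rng.uniform(-80, 80)
            rot = Rotation.from_euler("z", angle, degrees=True).as_matrix()
            obs = body.reference_shape @ rot.T + rng.normal(scale=sigma_mm * 1e-3, size=(6, 3))
            pose = estimate_pose(body, dict(zip(body.marker_labels, obs)))
            got = axial_rotation_angle(pose, _identity_pose())
            errors.append(abs(got - angle))
        assert np.percentile(errors, 99) < p99_bound_deg

    def test_too_few_markers(self, rng):
        body = _random_body(rng)
        frame = {lb: body.reference_shape[i] for i, lb in enumerate(body.marker_labels[:2])}
        with pytest.raises(DegenerateFrameError, match="2 visible"):
            estimate_pose(body, frame)

    def test_collinear_markers_rejected(self):
        with pytest.raises(RankDeficiencyError):
            RigidBodyDef("bad", ("a", "b", "c"), np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))

    def test_reflection_guard(self, rng):
        # near-planar cluster + noise must still yield det +1
        shape = rng.normal(scale=0.1, size=(4, 3))
        shape[:, 2] *= 1e-4
        body = RigidBodyDef("flat", ("a", "b", "c", "d"), shape)
        obs = body.reference_shape @ Rotation.from_euler("y", 170, degrees=True).as_matrix().T
        obs += rng.normal(scale=1e-5, size=obs.shape)
        pose = estimate_pose(body, dict(zip(body.marker_labels, obs)))
        assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_grows_with_noise(self, rng):
        body = _random_body(rng, n_markers=6)
        means = []
        for sigma in (0.5e-3, 1e-3, 2e-3):
            vals = []
            for _ in range(200):
                obs = body.reference_shape + rng.normal(scale=sigma, size=(6, 3))
                vals.append(estimate_pose(body, dict(zip(body.marker_labels, obs))).residual_rmsd)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_noise_free_rmsd_zero(self, rng):
        body = _random_body(rng)
        rot = Rotation.random(random_state=7).as_matrix()
        obs = body.reference_shape @ rot.T + np.array([0.3, -0.1, 0.2])
        pose = estimate_pose(body, dict(zip(body.marker_labels, obs)))
        assert pose.residual_rmsd < 1e-9


class TestKabschVsGridOracle:
    @pytest.mark.parametrize("n_markers", [4, 5, 6])
    def test_matches_brute_force_search(self, n_markers):
        rng = np.random.default_rng(100 + n_markers)
        body = _random_body(rng, n_markers=n_markers)
        true_rot = Rotation.from_euler(
            "xyz", rng.uniform(-25, 25, size=3), degrees=True
        ).as_matrix()
        obs = body.reference_shape @ true_rot.T + rng.normal(scale=2e-3, size=(n_markers, 3))
        pose = estimate_pose(body, dict(zip(body.marker_labels, obs)))
        oracle_rot = grid_search_rotation(body.reference_shape, obs)
        assert rotation_geodesic_deg(pose.rotation, oracle_rot) < 0.2  # 0.1 deg grid, 2x slack


# ---------------------------------------------------------------------------
# axial_rotation_angle
# ---------------------------------------------------------------------------

class TestAxialAngle:
    def test_identical_poses_zero(self, rng):
        rot = Rotation.random(random_state=3).as_matrix()
        pose = Pose(rot, np.zeros(3))
        assert axial_rotation_angle(pose, pose) == pytest.approx(0.0, abs=1e-9)

    def test_pure_z_rotation_is_angle(self):
        # the post-manipulation maximum this construction must represent
        head = Pose(Rotation.from_euler("z", 73.7, degrees=True).as_matrix(), np.zeros(3))
        assert axial_rotation_angle(head, _identity_pose()) == pytest.approx(73.7, abs=1e-9)

    def test_z_then_x_twist_component(self):
        rel = (
            Rotation.from_euler("z", 45, degrees=True) * Rotation.from_euler("x", 5, degrees=True)
        ).as_matrix()
        head = Pose(rel, np.zeros(3))
        got = axial_rotation_angle(head, _identity_pose(), "twist_z")
        oracle = twist_about_z_by_search(rel)
        assert got == pytest.approx(oracle, abs=0.01)
        assert abs(got - 45.0) < 0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_twist_matches_search_oracle(self, seed):
        rel = Rotation.random(random_state=seed).as_matrix()
        got = axial_rotation_angle(Pose(rel, np.zeros(3)), _identity_pose(), "twist_z")
        oracle = twist_about_z_by_search(rel)
        assert got == pytest.approx(oracle, abs=0.01)

    def test_frame_invariance(self, rng):
        # common rigid transform applied to both poses leaves the angle fixed
        head = Pose(Rotation.random(random_state=1).as_matrix(), rng.normal(size=3))
        thorax = Pose(Rotation.random(random_state=2).as_matrix(), rng.normal(size=3))
        common = Rotation.random(random_state=3).as_matrix()
        shift = rng.normal(size=3)
        head2 = Pose(common @ head.rotation, common @ head.translation + shift)
        thorax2 = Pose(common @ thorax.rotation, common @ thorax.translation + shift)
        a1 = axial_rotation_angle(head, thorax)
        a2 = axial_rotation_angle(head2, thorax2)
        assert a1 == pytest.approx(a2, abs=1e-6)

    def test_composition_about_z(self):
        for alpha, beta in [(10, 20), (50, 40), (100, 100), (-30, 75)]:
            ra = Rotation.from_euler("z", alpha, degrees=True).as_matrix()
            rb = Rotation.from_euler("z", beta, degrees=True).as_matrix()
            got = axial_rotation_angle(Pose(rb @ ra, np.zeros(3)), _identity_pose())
            expected = (alpha + beta + 180) % 360 - 180
            assert got == pytest.approx(expected, abs=1e-6)

    def test_gimbal_flag_cardan(self):
        rel = Rotation.from_euler("xyz", [10, 89.5, 20], degrees=True).as_matrix()
        _, flag = axial_rotation_angle(
            Pose(rel, np.zeros(3)), _identity_pose(), "cardan_xyz", return_flag=True
        )
        assert flag


# ---------------------------------------------------------------------------
# angle_series / max_rotation_angle
# ---------------------------------------------------------------------------

class TestAngleSeries:
    def test_generator_ramp_recovered(self):
        trial, truth = simulate_trial(
            SubjectParams(seed=5, rot_pre=70.0, rot_post=70.0, artifact_time=None)
        )
        from manipkin.config import AnalysisConfig

        cfg = AnalysisConfig()
        head = build_body(trial, "head", cfg.head_markers)
        thorax = build_body(trial, "thorax", cfg.thorax_markers)
        series = angle_series(trial, head, thorax, config=cfg)
        assert np.nanmax(series.axial_angle) == pytest.approx(70.0, abs=0.1)

    def test_static_trial_zero(self):
        trial, _ = simulate_trial(
            SubjectParams(seed=6, rot_pre=0.0, rot_post=0.0, extension=0.0, artifact_time=None)
        )
        from manipkin.config import AnalysisConfig

        cfg = AnalysisConfig()
        head = build_body(trial, "head", cfg.head_markers)
        thorax = build_body(trial, "thorax", cfg.thorax_markers)
        series = angle_series(trial, head, thorax, config=cfg)
        assert np.nanmax(np.abs(series.axial_angle)) < 1e-6

    def test_occluded_frames_masked(self, default_config):
        trial, _ = simulate_trial(SubjectParams(seed=7, artifact_time=None))
        trial.markers["crown"].occluded[150:171] = True
        head = build_body(trial, "head", default_config.head_markers)
        thorax = build_body(trial, "thorax", default_config.thorax_markers)
        series = angle_series(trial, head, thorax, config=default_config)
        assert series.masked[150:171].all()
        assert not series.masked[:150].any()
        assert not series.masked[171:].any()

    def test_max_rotation_windows(self):
        times = np.arange(100) / 100.0
        angles = np.linspace(0, 50, 100)  # monotone ramp
        series = AngleSeries(times, angles, np.zeros(100, bool), "twist_Z")
        assert max_rotation_angle(series, (0.0, 0.99)) == pytest.approx(50.0, abs=0.6)
        # single-frame window returns that frame's angle
        assert max_rotation_angle(series, (0.50, 0.50)) == pytest.approx(angles[50])

    def test_fully_masked_window_errors(self):
        times = np.arange(10) / 10.0
        series = AngleSeries(times, np.zeros(10), np.ones(10, bool), "twist_Z")
        with pytest.raises(WindowError):
            max_rotation_angle(series, (0.0, 1.0))


# ---------------------------------------------------------------------------
# virtual points
# ---------------------------------------------------------------------------

class TestVirtualPoints:
    def _trial_with(self, left, right, crown, n=10):
        from manipkin.trial_io import ForceChannel, MarkerTrajectory, Trial

        markers = {
            "shoulder_peak_left": MarkerTrajectory("shoulder_peak_left", np.tile(left, (n, 1)), 200.0),
            "shoulder_peak_right": MarkerTrajectory("shoulder_peak_right", np.tile(right, (n, 1)), 200.0),
            "crown": MarkerTrajectory("crown", np.tile(crown, (n, 1)), 200.0),
        }
        z = np.zeros(n * 5)
        plates = (ForceChannel(1, z, z, z, 1000.0), ForceChannel(2, z, z, z, 1000.0))
        return Trial(markers=markers, plates=plates)

    def test_midpoint_arithmetic(self):
        trial = self._trial_with([-0.2, 0, 1.4], [0.2, 0, 1.4], [0, 0.3, 1.5])
        vps = virtual_points(trial)
        np.testing.assert_allclose(vps["mid_shoulder"].positions[0], [0, 0, 1.4], atol=1e-12)

    def test_symmetric_perturbation_cancels(self):
        delta = np.array([0.01, -0.02, 0.005])
        t1 = self._trial_with([-0.2, 0, 1.4], [0.2, 0, 1.4], [0, 0.3, 1.5])
        t2 = self._trial_with([-0.2, 0, 1.4] + delta, [0.2, 0, 1.4] - delta, [0, 0.3, 1.5])
        np.testing.assert_allclose(
            virtual_points(t1)["mid_shoulder"].positions,
            virtual_points(t2)["mid_shoulder"].positions,
            atol=1e-12,
        )

    def test_matches_generator_t1_proxy(self, default_trial):
        trial, _ = default_trial
        vps = virtual_points(trial)
        from manipkin.synthetic_data import _SUBJECT_BASE

        expected = 0.5 * (
            np.array(_SUBJECT_BASE["shoulder_peak_left"])
            + np.array(_SUBJECT_BASE["shoulder_peak_right"])
        )
        np.testing.assert_allclose(vps["mid_shoulder"].positions[0], expected, atol=1e-9)

    def test_occluded_acromion_masks_frame(self):
        trial = self._trial_with([-0.2, 0, 1.4], [0.2, 0, 1.4], [0, 0.3, 1.5])
        trial.markers["shoulder_peak_left"].occluded[3] = True
        vps = virtual_points(trial)
        assert vps["mid_shoulder"].masked[3]
        assert not vps["mid_shoulder"].masked[4]


# ---------------------------------------------------------------------------
# marker-level frame invariance of the relative angle
# ---------------------------------------------------------------------------

def test_angle_series_frame_invariant(default_config):
    trial, _ = simulate_trial(SubjectParams(seed=9, artifact_time=None))
    cfg = default_config
    head = build_body(trial, "head", cfg.head_markers)
    thorax = build_body(trial, "thorax", cfg.thorax_markers)
    base = angle_series(trial, head, thorax, config=cfg)

    # same body definitions (reference shapes), all observations moved by one
    # common rigid transform: the relative angle must not change
    common = Rotation.from_euler("xyz", [14.0, -8.0, 33.0], degrees=True).as_matrix()
    shift = np.array([0.5, -0.2, 0.9])
    for traj in trial.markers.values():
        traj.positions = traj.positions @ common.T + shift
    moved = angle_series(trial, head, thorax, config=cfg)
    np.testing.assert_allclose(moved.axial_angle, base.axial_angle, atol=1e-6)
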