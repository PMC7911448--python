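"""Synthetic trajectories, the correspondence oracle, and the renderer."""

import numpy as np
import pytest

from capstrack.cleanliness import frame_cleanliness
from capstrack.features import detect_and_match
from capstrack.geometry import CylinderModel, unwrap_frame
from capstrack.motion import estimate_roll, estimate_speed, unit_displacement_samples
from capstrack.simulator import (
    GroundTruthTrajectory,
    SyntheticVideoConfig,
    TrajectoryConfig,
    TrajectorySample,
    render_frames,
    simulate_correspondences,
    simulate_trajectory,
)


def _straight(n, d=0.1, **kw):
    return GroundTruthTrajectory(
        [TrajectorySample(d=d, gamma=0, Omega=0, omega=0, R=2.3, f=2.0, **kw) for _ in range(n)]
    )


class TestSimulateTrajectory:
    def test_all_zero_motion_collapses_to_a_point(self):
        cfg = TrajectoryConfig(
            n_frames=40, state_probs=(1.0, 0.0, 0.0), roll_std=0.0,
            roll_episode_prob=0.0, tilt_prob=0.0,
        )
        traj = simulate_trajectory(cfg, np.random.default_rng(0))
        assert traj.arc_length == 0.0
        assert np.allclose(traj.positions(), 0.0)

    def test_constant_displacement_sums_to_path_length(self):
        traj = _straight(100, d=0.1)
        assert traj.arc_length == pytest.approx(10.0)
        poly = traj.positions()
        assert np.linalg.norm(poly[-1] - poly[0]) == pytest.approx(10.0, abs=1e-9)

    def test_deterministic_for_fixed_seed(self):
        cfg = TrajectoryConfig(n_frames=60, dirt_fraction=0.1)
        a = simulate_trajectory(cfg, np.random.default_rng(5)).to_dataframe()
        b = simulate_trajectory(cfg, np.random.default_rng(5)).to_dataframe()
        assert a.equals(b)

    def test_dataframe_round_trip(self):
        traj = simulate_trajectory(
            TrajectoryConfig(n_frames=30, dirt_fraction=0.1), np.random.default_rng(2)
        )
        back = GroundTruthTrajectory.from_dataframe(traj.to_dataframe())
        assert back.arc_length == pytest.approx(traj.arc_length)
        assert [s.dirty for s in back.samples] == [s.dirty for s in traj.samples]

    def test_section_labels_follow_arc_length_order(self):
        traj = _straight(100)
        labels = traj.section_labels()
        order = {"I": 0, "II": 1, "III": 2, "IV": 3, "V": 4, "VI": 5}
        idx = [order[l] for l in labels]
        assert idx == sorted(idx)
        assert idx[0] == 0 and idx[-1] == 5

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryConfig(n_frames=1)
        with pytest.raises(ValueError):
            TrajectoryConfig(dirt_fraction=1.5)


class TestCorrespondenceOracle:
    def test_axial_displacement_inverts_exactly(self, geometry):
        """The defining property: zero-noise correspondences return the
        true displacement at machine precision for every point."""
        traj = simulate_trajectory(
            TrajectoryConfig(n_frames=30, tilt_prob=0.0), np.random.default_rng(3)
        )
        mss = simulate_correspondences(
            traj, geometry, n_points=50, noise_px=0.0,
            rng=np.random.default_rng(4), placement="band",
        )
        for s, ms in zip(traj.samples, mss):
            d = CylinderModel(s.R).radius_R * unit_displacement_samples(ms, geometry)
            if s.d != 0:
                assert np.max(np.abs(d - s.d) / abs(s.d)) < 1e-9
            else:
                assert np.max(np.abs(d)) < 1e-12

    def test_pure_roll_shifts_azimuth_only(self, geometry):
        gamma = np.deg2rad(5.0)
        traj = GroundTruthTrajectory(
            [TrajectorySample(d=0.0, gamma=gamma, Omega=0, omega=0, R=2.3, f=2.0)]
        )
        ms = simulate_correspondences(traj, geometry, 100, rng=np.random.default_rng(0))[0]
        L = geometry.unwrapped_width_L
        dx = (ms.points_t1[:, 0] - ms.points_t[:, 0] + L) % L
        assert np.allclose(dx, L * gamma / (2 * np.pi))
        assert np.allclose(ms.points_t1[:, 1], ms.points_t[:, 1])

    def test_dirty_transition_emits_no_matches(self, geometry):
        traj = GroundTruthTrajectory(
            [TrajectorySample(d=0.1, gamma=0, Omega=0, omega=0, R=2.3, f=2.0, dirty=True)]
        )
        ms = simulate_correspondences(traj, geometry, 100, rng=np.random.default_rng(0))[0]
        assert ms.FP == 0

    def test_invalid_arguments_rejected(self, geometry):
        traj = _straight(2)
        with pytest.raises(ValueError):
            simulate_correspondences(traj, geometry, n_points=0)
        with pytest.raises(ValueError):
            simulate_correspondences(traj, geometry, 10, placement="spiral")


class TestRenderer:
    def test_zero_motion_gives_identical_frames(self, geometry):
        traj = _straight(3, d=0.0)
        cfg = SyntheticVideoConfig(noise_sigma=0.0)
        frames = render_frames(traj, cfg, rng=np.random.default_rng(0))
        assert np.array_equal(frames[0], frames[1])
        assert np.array_equal(frames[1], frames[3])

    def test_center_region_is_underexposed(self, geometry):
        frames = render_frames(_straight(2), rng=np.random.default_rng(0))
        c = frames[0][118:138, 118:138]
        edge = frames[0][128, 200:240]
        assert c.mean() < 0.1 < edge.mean()

    def test_fully_dirty_frame_scores_unacceptable(self, clean_model):
        traj = _straight(3, d=0.05)
        traj.samples[0] = TrajectorySample(
            d=0.05, gamma=0, Omega=0, omega=0, R=2.3, f=2.0, dirty=True
        )
        cfg = SyntheticVideoConfig(dirt_cover=1.0)
        frames = render_frames(traj, cfg, rng=np.random.default_rng(1))
        assert frame_cleanliness(frames[1], clean_model).level_L == 0

    def test_clean_frame_scores_adequate(self, clean_model, rendered_video):
        traj, frames = rendered_video
        clean_idx = [0] + [i + 1 for i, s in enumerate(traj.samples) if not s.dirty]
        levels = [frame_cleanliness(frames[i], clean_model).level_L for i in clean_idx[:4]]
        assert all(l >= 1 for l in levels)

    def test_rendered_roll_recovered_end_to_end(self, geometry):
        gamma = np.deg2rad(4.0)
        traj = GroundTruthTrajectory(
            [TrajectorySample(d=0.0, gamma=gamma, Omega=0, omega=0, R=2.3, f=2.0)]
        )
        cfg = SyntheticVideoConfig(noise_sigma=0.005)
        frames = render_frames(traj, cfg, rng=np.random.default_rng(2))
        ms = detect_and_match(unwrap_frame(frames[0], geometry), unwrap_frame(frames[1], geometry))
        assert ms.FP > 50
        assert abs(np.degrees(estimate_roll(ms, geometry) - gamma)) < 1.0

    def test_rendered_speed_recovered_end_to_end(self, geometry):
        traj = _straight(2, d=0.15)
        cfg = SyntheticVideoConfig(noise_sigma=0.005)
        frames = render_frames(traj, cfg, rng=np.random.default_rng(3))
        ms = detect_and_match(unwrap_frame(frames[0], geometry), unwrap_frame(frames[1], geometry))
        v = estimate_speed(ms, geometry, CylinderModel(2.3), 2.0)
        assert v == pytest.approx(0.3, rel=0.15)

    def test_deterministic_given_rng(self):
        traj = _straight(3)
        a = render_frames(traj, rng=np.random.default_rng(9))
        b = render_frames(traj, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)
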