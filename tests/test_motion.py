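"""Mode estimation and per-frame speed / roll / tilt recovery."""

import numpy as np
import pytest

from capstrack.features import MatchSet
from capstrack.geometry import CameraGeometry, CylinderModel
from capstrack.motion import (
    InvalidEstimate,
    ModeEstimatorConfig,
    TiltConfig,
    circular_mode,
    estimate_motion,
    estimate_roll,
    estimate_speed,
    estimate_tilt,
    mode_of,
    pitch_yaw,
    wrapped_dx,
)
from capstrack.simulator import (
    GroundTruthTrajectory,
    TrajectorySample,
    simulate_correspondences,
)


def _matchset_from_dx(dx_values, g, y=64.0):
    n = len(dx_values)
    x = np.linspace(10, g.unwrapped_width_L - 10, n)
    pts = np.column_stack([x, np.full(n, y)])
    dst = pts.copy()
    dst[:, 0] = (dst[:, 0] + dx_values) % g.unwrapped_width_L
    return MatchSet(pts, dst, np.zeros(n))


def _oracle_transition(d=0.1, gamma=0.0, Omega=0.0, omega=0.0, R=2.3, f=2.0, n=200,
                       noise=0.0, seed=0, **kw):
    traj = GroundTruthTrajectory(
        [TrajectorySample(d=d, gamma=gamma, Omega=Omega, omega=omega, R=R, f=f)]
    )
    g = CameraGeometry()
    ms = simulate_correspondences(
        traj, g, n_points=n, noise_px=noise, rng=np.random.default_rng(seed), **kw
    )[0]
    return ms, g, traj.samples[0]


class TestModeOf:
    def test_degenerate_ensemble_returns_its_value(self):
        assert mode_of(np.full(50, 3.2)) == 3.2

    def test_dominant_component_of_mixture_found(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 0.1, 8000), rng.normal(5, 0.1, 2000)]
        assert abs(mode_of(x)) < 0.05

    def test_too_few_samples_signal_invalid(self):
        with pytest.raises(InvalidEstimate):
            mode_of(np.array([]))
        with pytest.raises(InvalidEstimate):
            mode_of(np.array([1.0, 2.0]), ModeEstimatorConfig(min_samples=5))

    def test_grid_refinement_converges(self, rng):
        """The grid argmax at the default resolution sits within one
        cell of a much finer brute-force evaluation of the same KDE."""
        from scipy.stats import gaussian_kde

        for _ in range(20):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 2), 300)
            coarse = mode_of(x, ModeEstimatorConfig(grid_size=512))
            kde = gaussian_kde(x, bw_method="silverman")
            fine_grid = np.linspace(x.min(), x.max(), 10_000)
            fine = fine_grid[np.argmax(kde(fine_grid))]
            cell = (x.max() - x.min()) / 511
            assert abs(coarse - fine) <= cell

    def test_histogram_method_matches_peak(self, rng):
        x = np.r_[rng.normal(2, 0.05, 5000), rng.uniform(0, 4, 1000)]
        m = mode_of(x, ModeEstimatorConfig(method="histogram", grid_size=256))
        assert abs(m - 2.0) < 0.1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModeEstimatorConfig(grid_size=8)
        with pytest.raises(ValueError):
            ModeEstimatorConfig(method="mean-shift")


class TestCircularMode:
    def test_concentrated_angles_recovered_across_seam(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, 500) % (2 * np.pi)  # cluster straddling 0
        m = circular_mode(a)
        assert np.abs(np.angle(np.exp(1j * m))) < 0.1


class TestEstimateSpeed:
    def test_noiseless_oracle_exact(self):
        ms, g, s = _oracle_transition(d=0.1, f=2.0)
        v = estimate_speed(ms, g, CylinderModel(s.R), s.f)
        assert v == pytest.approx(0.2, rel=1e-6)

    def test_stationary_capsule_zero_speed(self):
        ms, g, s = _oracle_transition(d=0.0)
        assert estimate_speed(ms, g, CylinderModel(s.R), s.f) == pytest.approx(0.0, abs=1e-12)

    def test_pixel_noise_within_ten_percent_at_fixed_seed(self):
        # one millimetre of travel at 2 Hz seen through 1 px of noise
        ms, g, s = _oracle_transition(d=0.1, f=2.0, noise=1.0, seed=0)
        v = estimate_speed(ms, g, CylinderModel(s.R), s.f)
        assert abs(v - 0.2) / 0.2 < 0.10

    def test_pixel_noise_error_shrinks_with_ensemble_size(self):
        """More tracked points concentrate the displacement ensemble."""
        errs = {}
        for n in (50, 800):
            e = []
            for seed in range(8):
                ms, g, s = _oracle_transition(d=0.1, f=2.0, n=n, noise=1.0, seed=seed)
                e.append(abs(estimate_speed(ms, g, CylinderModel(s.R), s.f) - 0.2) / 0.2)
            errs[n] = np.mean(e)
        assert errs[800] < errs[50]

    def test_receding_motion_carries_negative_sign(self):
        ms, g, s = _oracle_transition(d=-0.1)
        assert estimate_speed(ms, g, CylinderModel(s.R), s.f) < 0

    def test_no_usable_matches_invalid(self, geometry):
        with pytest.raises(InvalidEstimate):
            estimate_speed(MatchSet.empty(), geometry, CylinderModel(1.0), 2.0)


class TestEstimateRoll:
    def test_zero_displacement_zero_roll(self, geometry):
        ms = _matchset_from_dx(np.zeros(50), geometry)
        assert estimate_roll(ms, geometry) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_width_shift_is_quarter_turn(self, geometry):
        L = geometry.unwrapped_width_L
        ms = _matchset_from_dx(np.full(50, L / 4), geometry)
        assert estimate_roll(ms, geometry) == pytest.approx(np.pi / 2, rel=1e-6)

    def test_wrapped_dx_convention(self, geometry):
        L = geometry.unwrapped_width_L
        ms = _matchset_from_dx(np.full(10, -L / 2), geometry)
        assert np.allclose(wrapped_dx(ms, L), L / 2)  # (-L/2, L/2] wrap

    def test_noisy_roll_within_half_degree(self):
        ms, g, s = _oracle_transition(d=0.1, gamma=np.deg2rad(5.0), noise=1.0, seed=3)
        err = abs(estimate_roll(ms, g) - s.gamma)
        assert np.degrees(err) < 0.5


class TestEstimateTilt:
    def test_pure_axial_motion_has_zero_tilt(self):
        ms, g, _ = _oracle_transition(d=0.1)
        Omega, _ = estimate_tilt(ms, g)
        assert Omega == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_defines_magnitude_directly(self, geometry):
        H = geometry.unwrapped_height_H
        pts = np.array([[10.0, 40.0], [200.0, 80.0]])
        dst = np.array([[10.0, 44.0], [200.0, 82.0]])
        ms = MatchSet(pts, dst, np.zeros(2))
        eta = geometry.eta_eff
        dp, dq = 4 * eta / H, 2 * eta / H
        Omega, _ = estimate_tilt(ms, geometry)
        assert Omega == pytest.approx((dp - dq) / dp, rel=1e-9)

    def test_magnitude_and_direction_recovered(self):
        ms, g, s = _oracle_transition(
            d=0.12, Omega=np.deg2rad(6.0), omega=np.deg2rad(45.0), seed=4
        )
        Omega, omega = estimate_tilt(ms, g)
        assert abs(np.degrees(Omega - s.Omega)) < 1.0
        assert np.degrees(abs(np.angle(np.exp(1j * (omega - s.omega))))) < 10.0

    def test_receding_camera_handled_symmetrically(self):
        ms, g, s = _oracle_transition(
            d=-0.12, Omega=np.deg2rad(6.0), omega=np.deg2rad(45.0), seed=4
        )
        Omega, _ = estimate_tilt(ms, g)
        assert Omega < np.deg2rad(8.0)  # finite, not blown up by sign

    def test_fewer_than_two_matches_invalid(self, geometry):
        ms = MatchSet(np.array([[5.0, 50.0]]), np.array([[5.0, 52.0]]), np.zeros(1))
        with pytest.raises(InvalidEstimate):
            estimate_tilt(ms, geometry)


class TestPitchYaw:
    @pytest.mark.parametrize(
        "omega,expect",
        [(0.0, (1.0, 0.0)), (np.pi / 2, (0.0, 1.0))],
    )
    def test_axis_aligned_directions(self, omega, expect):
        alpha, beta = pitch_yaw(1.0, omega)
        assert (alpha, beta) == pytest.approx(expect, abs=1e-12)

    def test_magnitude_identity(self, rng):
        for _ in range(50):
            Om, om = rng.uniform(0, 0.5), rng.uniform(0, 2 * np.pi)
            a, b = pitch_yaw(Om, om)
            assert a * a + b * b == pytest.approx(Om * Om)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            pitch_yaw(-0.1, 0.0)


class TestEnsembleProperties:
    def test_estimates_invariant_to_match_ordering(self):
        ms, g, s = _oracle_transition(d=0.1, gamma=0.02, noise=0.5, seed=7)
        perm = np.random.default_rng(0).permutation(ms.FP)
        shuffled = MatchSet(ms.points_t[perm], ms.points_t1[perm], ms.distances[perm])
        cyl, f = CylinderModel(s.R), s.f
        assert estimate_speed(ms, g, cyl, f) == estimate_speed(shuffled, g, cyl, f)
        assert estimate_roll(ms, g) == estimate_roll(shuffled, g)

    def test_motion_estimate_flags_thin_support(self, geometry):
        est = estimate_motion(
            MatchSet.empty(), geometry, CylinderModel(1.0), 2.0
        )
        assert not est.valid and est.n_support == 0

    def test_full_estimate_consistent_with_parts(self):
        ms, g, s = _oracle_transition(d=0.1, gamma=0.03, seed=9)
        est = estimate_motion(ms, g, CylinderModel(s.R), s.f)
        assert est.valid
        assert est.v == pytest.approx(estimate_speed(ms, g, CylinderModel(s.R), s.f))
        assert est.alpha == pytest.approx(est.Omega * np.cos(est.omega))
        assert est.beta == pytest.approx(est.Omega * np.sin(est.omega))


def test_tilt_config_validation():
    with pytest.raises(ValueError):
        TiltConfig(xi=1.5)
    with pytest.raises(ValueError):
        TiltConfig(max_pairs=0)
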