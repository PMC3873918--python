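import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celltrax import (
    AcquisitionConfig,
    angle_of_deflection,
    angle_of_trajectory,
    compute_kinematics,
    msd,
    summarize_population,
)
from celltrax.kinematics import (
    KinematicsTable,
    circular_mean_deg,
    displacement_and_speed,
    interval_pairs,
)
from celltrax.synthetic import PRWSimParams, add_positional_jitter, simulate_prw

from conftest import make_track, straight_track


class TestIntervalPairs:
    @pytest.mark.parametrize(
        "length,a,expected_n",
        [(10, 3, 7), (2, 1, 1), (3, 3, 0), (5, 1, 4)],
    )
    def test_overlapping_pair_count(self, length, a, expected_n):
        track = straight_track(length)
        pairs = interval_pairs(track, a)
        assert len(pairs) == expected_n
        assert all(nb - na == a for na, nb in pairs)

    def test_gapped_track_skips_missing_endpoints(self):
        track = make_track([(0, 0), (1, 0), (3, 0)], frames=[0, 1, 3])
        assert interval_pairs(track, 1) == [(0, 1)]
        assert interval_pairs(track, 2) == [(1, 3)]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_pairs(straight_track(5), 0)


class TestDisplacementAndSpeed:
    def test_standard_calibration_speed(self, config_a1):
        """1 px per 7-min frame at 1.314 µm/px is 11.263 µm/hour."""
        d, speed = displacement_and_speed((0.0, 0.0), (1.0, 0.0), config_a1)
        assert d == pytest.approx(1.0)
        assert speed == pytest.approx(1.314 * 60 / 7, abs=1e-9)
        assert speed == pytest.approx(11.263, abs=5e-4)

    def test_zero_displacement_zero_speed(self, config_a3):
        d, speed = displacement_and_speed((5.0, 5.0), (5.0, 5.0), config_a3)
        assert d == 0.0 and speed == 0.0

    def test_speed_linear_in_pixel_size(self):
        a = AcquisitionConfig(pixel_size_um=1.0, interval_size=1)
        b = AcquisitionConfig(pixel_size_um=2.0, interval_size=1)
        _, sa = displacement_and_speed((0, 0), (3, 4), a)
        _, sb = displacement_and_speed((0, 0), (3, 4), b)
        assert sb == pytest.approx(2 * sa)

    def test_binning_divides_speed(self):
        a1 = AcquisitionConfig(interval_size=1)
        a3 = AcquisitionConfig(interval_size=3)
        _, s1 = displacement_and_speed((0, 0), (3, 4), a1)
        _, s3 = displacement_and_speed((0, 0), (3, 4), a3)
        assert s3 == pytest.approx(s1 / 3)


class TestAngleOfTrajectory:
    @pytest.mark.parametrize(
        "dx,dy,expected",
        [
            (1.0, 0.0, 0.0),
            (0.0, -1.0, 90.0),   # up on screen
            (-1.0, 0.0, 180.0),
            (0.0, 1.0, 270.0),   # down on screen
            (1.0, -1.0, 45.0),   # up-and-right: the compass example
        ],
    )
    def test_axis_and_diagonal_cases(self, dx, dy, expected):
        assert angle_of_trajectory(dx, dy) == pytest.approx(expected)

    def test_zero_displacement_undefined(self):
        assert np.isnan(angle_of_trajectory(0.0, 0.0))

    def test_matches_arctangent_oracle_on_dense_grid(self):
        """All 3600 directions at 0.1° spacing agree with atan2 to 1e-9."""
        want = np.arange(0.0, 360.0, 0.1)
        rad = np.radians(want)
        dx, dy_screen = np.cos(rad), -np.sin(rad)
        got = angle_of_trajectory(dx, dy_screen)
        # compare on the circle (360 ~ 0)
        diff = np.abs((got - want + 180.0) % 360.0 - 180.0)
        assert diff.max() < 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(0.0, 359.999), st.floats(0.1, 100.0), st.floats(-360.0, 360.0)
    )
    def test_rotational_equivariance(self, theta, r, phi):
        rad = np.radians(theta)
        dx, dy = r * np.cos(rad), -r * np.sin(rad)
        rot = np.radians(phi)
        dxr = dx * np.cos(rot) - (-dy) * np.sin(rot)
        dyr = -(dx * np.sin(rot) + (-dy) * np.cos(rot))
        got = angle_of_trajectory(dxr, dyr)
        want = (theta + phi) % 360.0
        assert abs((got - want + 180.0) % 360.0 - 180.0) < 1e-6


class TestAngleOfDeflection:
    @pytest.mark.parametrize(
        "prev,curr,expected",
        [
            (90.0, 45.0, 45.0),    # clockwise turn is positive
            (123.4, 123.4, 0.0),
            (350.0, 10.0, -20.0),  # counterclockwise across the wrap
            (10.0, 350.0, 20.0),
            (0.0, 180.0, 180.0),   # exact reversal maps to +180
        ],
    )
    def test_sign_and_wrap_cases(self, prev, curr, expected):
        assert angle_of_deflection(prev, curr) == pytest.approx(expected)

    def test_undefined_inputs_propagate(self):
        assert np.isnan(angle_of_deflection(np.nan, 45.0))
        assert np.isnan(angle_of_deflection(45.0, np.nan))

    def test_brute_force_wrap_oracle_on_degree_grid(self):
        """Every (θ1, θ2) pair on a 1° grid: |d| <= 180 and d rotates θ1 onto θ2."""
        t1, t2 = np.meshgrid(np.arange(360.0), np.arange(360.0), indexing="ij")
        d = angle_of_deflection(t1, t2)
        assert (d > -180.0).all() and (d <= 180.0).all()
        # rotating the previous angle clockwise by d must land on the current
        np.testing.assert_allclose((t1 - d) % 360.0, t2 % 360.0, atol=1e-9)

    def test_closed_polygon_turns_sum_to_360(self):
        """Interior turns of a closed convex polygon sum to -360° (CCW, y-up)."""
        k = 12
        vertex_angles = 2 * np.pi * np.arange(k) / k
        x = 50 + 10 * np.cos(vertex_angles)
        y = 50 - 10 * np.sin(vertex_angles)  # screen y down: CCW in compass terms
        # close the loop and repeat the first leg so every turn appears once
        xs = np.concatenate([x, x[:1], x[1:2]])
        ys = np.concatenate([y, y[:1], y[1:2]])
        legs = angle_of_trajectory(np.diff(xs), np.diff(ys))
        turns = angle_of_deflection(legs[:-1], legs[1:])
        assert np.nansum(turns) == pytest.approx(-360.0, abs=1e-9)
        clockwise = angle_of_deflection(legs[::-1][:-1], legs[::-1][1:])
        assert np.nansum(clockwise) == pytest.approx(360.0, abs=1e-9)


class TestMsd:
    def test_ballistic_closed_form(self):
        track = straight_track(20, step_px=2.5)
        for lag in (1, 3, 7):
            assert msd(track, lag) == pytest.approx((2.5 * lag) ** 2)

    def test_stationary_track_zero(self):
        track = make_track([(5.0, 5.0)] * 10)
        assert msd(track, 4) == 0.0

    def test_lag_beyond_track_undefined(self):
        track = straight_track(5)
        assert np.isnan(msd(track, 10))

    def test_diffusive_closed_form_on_lattice_walk(self):
        """2-D lattice random walk: MSD(lag) ≈ step² · lag within 5%."""
        rng = np.random.default_rng(42)
        steps = rng.choice([(1, 0), (-1, 0), (0, 1), (0, -1)], size=10_000)
        xy = np.cumsum(steps, axis=0)
        track = make_track(xy)
        for lag in (1, 5, 10):
            assert msd(track, lag) == pytest.approx(lag, rel=0.05)


class TestComputeKinematics:
    def test_straight_track_table(self, config_a1):
        kin = compute_kinematics([straight_track(5, step_px=2.0, direction_deg=90.0)], config_a1)
        t = kin.table
        assert len(t) == 5
        np.testing.assert_allclose(t["displacement_px"][:4], 2.0)
        assert np.isnan(t["displacement_px"].iloc[-1])
        np.testing.assert_allclose(t["theta_trajectory_deg"].dropna(), 90.0)
        np.testing.assert_allclose(t["theta_deflection_deg"].dropna(), 0.0, atol=1e-9)
        np.testing.assert_allclose(t["msd_px2"], (2.0 * np.arange(5)) ** 2)

    def test_deflection_uses_consecutive_legs_at_interval(self, config_a3):
        """At interval a the turn at frame n compares legs (n-a, n) and (n, n+a)."""
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 3, size=(10, 2)), axis=0)
        track = make_track(xy)
        kin = compute_kinematics([track], config_a3)
        t = kin.table.set_index("frame")
        a = 3
        for n in range(a, 10 - a):
            leg1 = angle_of_trajectory(*(xy[n] - xy[n - a]))
            leg2 = angle_of_trajectory(*(xy[n + a] - xy[n]))
            assert t.loc[n, "theta_deflection_deg"] == pytest.approx(
                angle_of_deflection(leg1, leg2)
            )

    def test_stationary_cell_has_undefined_angles(self, config_a1):
        kin = compute_kinematics([make_track([(5.0, 5.0)] * 6)], config_a1)
        assert kin.table["theta_trajectory_deg"].isna().all()
        assert kin.table["theta_deflection_deg"].isna().all()


class TestSummarizePopulation:
    @staticmethod
    def _table_from_deflections(deflections):
        rows = [
            {
                "cell_id": i,
                "frame": 0,
                "x": 0.0,
                "y": 0.0,
                "displacement_px": 1.0,
                "theta_trajectory_deg": 0.0,
                "theta_deflection_deg": d,
                "msd_px2": 0.0,
            }
            for i, d in enumerate(deflections)
        ]
        return KinematicsTable(table=pd.DataFrame(rows), interval_size=1)

    def test_hand_enumerated_deflection_aggregates(self):
        summary = summarize_population(
            self._table_from_deflections([100.0, -120.0, 10.0, -20.0])
        )
        row = summary.table.iloc[0]
        assert row["pct_turning_gt_90"] == pytest.approx(50.0)
        assert row["avg_abs_deflection_deg"] == pytest.approx(62.5)

    def test_straight_population_zero_turning(self, config_a1):
        tracks = [straight_track(6, direction_deg=d, cell_id=i) for i, d in enumerate([10, 200])]
        summary = summarize_population(compute_kinematics(tracks, config_a1))
        mid = summary.table.iloc[2]
        assert mid["pct_turning_gt_90"] == 0.0
        assert mid["avg_abs_deflection_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_directions_flat_histogram(self):
        """1e5 iid uniform directions: each bin within 4 binomial sigma of n/360."""
        rng = np.random.default_rng(123)
        n = 100_000
        theta = rng.uniform(0.0, 360.0, size=n)
        rows = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "frame": 0,
                "x": 0.0,
                "y": 0.0,
                "displacement_px": 1.0,
                "theta_trajectory_deg": theta,
                "theta_deflection_deg": np.nan,
                "msd_px2": 0.0,
            }
        )
        summary = summarize_population(KinematicsTable(table=rows, interval_size=1))
        hist = summary.table.iloc[0]["direction_histogram_bins_0_359"]
        assert hist.sum() == n
        expected = n / 360.0
        sigma = np.sqrt(n * (1 / 360) * (359 / 360))
        assert np.abs(hist - expected).max() < 4 * sigma

    def test_arithmetic_and_circular_means_agree_away_from_wrap(self):
        angles = np.array([80.0, 90.0, 100.0])
        assert circular_mean_deg(angles) == pytest.approx(90.0)
        # near the wrap they differ: that is why both are exposed
        near_wrap = np.array([350.0, 10.0])
        assert circular_mean_deg(near_wrap) == pytest.approx(0.0, abs=1e-9)
        assert np.mean(near_wrap) == pytest.approx(180.0)


class TestIntervalNoiseSuppression:
    def test_binning_suppresses_jitter_monotonically(self):
        """Mean and SD of |deflection| fall with interval size on jittered straight tracks."""
        rng = np.random.default_rng(77)
        ideal = [
            straight_track(40, step_px=2.7, direction_deg=rng.uniform(0, 360),
                           start=(5000.0, 5000.0), cell_id=i)
            for i in range(150)
        ]
        tracks = add_positional_jitter(ideal, sigma_px=0.5, seed=78)
        means, sds = [], []
        for a in (1, 2, 3, 4, 5):
            cfg = AcquisitionConfig(interval_size=a)
            kin = compute_kinematics(tracks, cfg)
            defl = kin.table["theta_deflection_deg"].dropna().abs()
            means.append(defl.mean())
            sds.append(defl.std())
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))
        assert all(s1 >= s2 for s1, s2 in zip(sds, sds[1:]))
        assert means[0] - means[2] > means[2] - means[4]
        assert sds[0] - sds[2] > sds[2] - sds[4]

    def test_abs_deflection_increases_with_turn_noise(self):
        """⟨|deflection|⟩ tracks the simulator's ground-truth turning noise."""
        values = []
        for sigma in (5.0, 20.0, 45.0, 80.0):
            params = PRWSimParams(n_cells=100, n_frames=30, turn_sigma_deg=sigma,
                                  arena_um=(3000.0, 3000.0), seed=5)
            kin = compute_kinematics(simulate_prw(params), AcquisitionConfig(interval_size=1))
            values.append(kin.table["theta_deflection_deg"].dropna().abs().mean())
        assert values == sorted(values)
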