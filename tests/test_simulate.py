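"""Synthetic cage simulator: profiles, movement and acquisition physics."""

import numpy as np
import pytest

from cagetrack import (
    AcquisitionConfig,
    ActivityProfile,
    LightSchedule,
    MovementParams,
    Trajectory,
    constant_profile,
    make_profile,
    simulate_acquisition,
    simulate_activity_series,
    simulate_movement,
)
from cagetrack.geometry import BaseplateGeometry
from cagetrack.simulate import (
    programmed_offset_anticipation_min,
    programmed_onset_anticipation_min,
)

DAY_S = 86_400.0


class TestActivityProfile:
    def test_constant_when_no_structure(self, schedule):
        p = constant_profile(0.4, schedule)
        t = np.linspace(0, 2 * DAY_S, 500)
        assert np.all(p.intensity(t) == 0.4)

    def test_nocturnal_dark_exceeds_light(self, schedule):
        p = make_profile(schedule, strain="high")
        assert p.intensity(8 * 3600.0) > p.intensity(2 * 3600.0)  # 20:00 vs 14:00

    def test_settling_bout_elevates_start(self, schedule):
        p = make_profile(schedule, strain="high")
        assert p.intensity(10 * 60.0) == pytest.approx(p.settle_level)
        assert p.intensity(p.settle_duration_min * 60.0 + 60.0) < p.settle_level

    def test_ramp_longer_than_phase_rejected(self, schedule):
        with pytest.raises(ValueError):
            ActivityProfile(schedule=schedule, ramp_before_off_min=13 * 60.0)
        with pytest.raises(ValueError):
            ActivityProfile(schedule=schedule, ramp_before_on_min=13 * 60.0)

    @pytest.mark.parametrize("bad", [dict(dark_level=1.2), dict(light_level=-0.1)])
    def test_levels_outside_unit_interval_rejected(self, schedule, bad):
        with pytest.raises(ValueError):
            ActivityProfile(schedule=schedule, **bad)

    def test_profile_periodic_after_settling(self, schedule):
        p = make_profile(schedule, strain="intermediate")
        t = np.linspace(2 * DAY_S, 3 * DAY_S, 1000, endpoint=False)
        assert np.allclose(p.intensity(t), p.intensity(t + DAY_S))

    def test_make_profile_deterministic_given_seed(self, schedule):
        a = make_profile(schedule, strain="low", seed=5)
        b = make_profile(schedule, strain="low", seed=5)
        assert a == b
        assert a != make_profile(schedule, strain="low", seed=6)


class TestProgrammedAnticipation:
    @pytest.mark.parametrize("ramp_min", [30.0, 60.0, 85.0, 120.0])
    def test_matches_closed_form(self, schedule, ramp_min):
        """The 1-min-grid mean-crossing agrees with the analytic crossing of
        the piecewise-linear profile (independent closed form)."""
        L, D, P, r_on = 0.08, 0.40, 0.80, 90.0
        p = ActivityProfile(
            schedule=schedule, light_level=L, dark_level=D, ramp_peak=P,
            ramp_before_off_min=ramp_min, ramp_before_on_min=r_on,
            settle_duration_min=0.0,
        )
        light_s, dark_s = 12 * 3600.0, 12 * 3600.0
        mean = (
            L * (light_s - ramp_min * 60.0)
            + (L + P) / 2.0 * ramp_min * 60.0
            + D * (dark_s - r_on * 60.0)
            + (D + L) / 2.0 * r_on * 60.0
        ) / DAY_S
        expected = ramp_min * (1.0 - (mean - L) / (P - L))
        assert programmed_onset_anticipation_min(p) == pytest.approx(expected, abs=1.2)

    def test_independent_of_seeded_level_jitter_scale(self, schedule):
        # a pure rescale of all levels leaves the mean-crossing unchanged
        base = dict(light_level=0.1, dark_level=0.4, ramp_peak=0.8,
                    ramp_before_off_min=85.0, ramp_before_on_min=60.0,
                    settle_duration_min=0.0)
        p1 = ActivityProfile(schedule=schedule, **base)
        p2 = ActivityProfile(
            schedule=schedule,
            **{k: (v * 1.2 if k.endswith("level") or k == "ramp_peak" else v)
               for k, v in base.items()},
        )
        assert programmed_onset_anticipation_min(p1) == pytest.approx(
            programmed_onset_anticipation_min(p2), abs=1.1
        )

    def test_offset_anticipation_positive_for_wind_down(self, schedule):
        p = make_profile(schedule, strain="intermediate")
        assert programmed_offset_anticipation_min(p) > 0


class TestMovement:
    def test_same_seed_bit_identical(self, geometry):
        p = constant_profile(0.6)
        a = simulate_movement(p, geometry, duration_s=60.0, seed=11)
        b = simulate_movement(p, geometry, duration_s=60.0, seed=11)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.xy, tb.xy) and np.array_equal(ta.t, tb.t)

    def test_rest_limit_huddles_at_nest(self, geometry):
        """With zero activity propensity the group converges into a huddle
        and accumulates almost no path length."""
        p = constant_profile(0.0)
        trajs = simulate_movement(p, geometry, duration_s=600.0, seed=2)
        finals = np.array([tr.xy[-1] for tr in trajs])
        pairwise = [
            np.hypot(*(finals[i] - finals[j]))
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert max(pairwise) < MovementParams().huddle_radius_mm
        # settled-phase path length is negligible next to an active animal's
        assert sum(tr.path_length(window=(300.0, 600.0)) for tr in trajs) < 500.0

    def test_active_group_more_dispersed_than_resting(self, geometry):
        def mean_pairwise(level):
            trajs = simulate_movement(
                constant_profile(level), geometry, duration_s=600.0, seed=3
            )
            xy = np.stack([tr.xy for tr in trajs])  # (3, n, 2)
            d = [
                np.hypot(*(xy[i] - xy[j]).T).mean()
                for i in range(3)
                for j in range(i + 1, 3)
            ]
            return np.mean(d)

        assert mean_pairwise(1.0) > mean_pairwise(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_positions_stay_inside_cage(self, geometry, seed):
        trajs = simulate_movement(
            constant_profile(1.0), geometry, duration_s=120.0, seed=seed,
            params=MovementParams(mean_speed_mm_s=80.0),
        )
        for tr in trajs:
            assert tr.xy[:, 0].min() >= 0 and tr.xy[:, 0].max() <= geometry.width_mm
            assert tr.xy[:, 1].min() >= 0 and tr.xy[:, 1].max() <= geometry.height_mm

    def test_invalid_arguments(self, geometry):
        with pytest.raises(ValueError):
            simulate_movement(constant_profile(0.5), geometry, duration_s=0.0)
        with pytest.raises(ValueError):
            simulate_movement(constant_profile(0.5), geometry, n_animals=0,
                              duration_s=10.0)

    def test_distance_per_bin_sums_to_path_length(self, geometry):
        tr = simulate_movement(
            constant_profile(0.8), geometry, n_animals=1, duration_s=500.0, seed=4
        )[0]
        assert tr.distance_per_bin(60.0).sum() == pytest.approx(tr.path_length())


def _stationary(tag, xy, duration=60.0, rate=25.0):
    t = np.arange(int(duration * rate) + 1) / rate
    return Trajectory(tag_id=tag, t=t, xy=np.tile(xy, (len(t), 1)))


class TestAcquisition:
    def test_stationary_tag_read_once_per_cycle(self, geometry):
        tr = _stationary("m1", np.array([25.0, 25.0]))
        acq = AcquisitionConfig(scan_rate_hz=2.0, p_read=1.0)
        reads = simulate_acquisition([tr], geometry, acq, seed=0)
        assert len(reads) == 120  # 60 s * 2 Hz
        assert (reads["antenna_col"] == 0).all() and (reads["antenna_row"] == 0).all()

    def test_tile_sharing_hides_farther_tag(self, geometry):
        near = _stationary("near", np.array([25.0, 25.0]))
        far = _stationary("far", np.array([40.0, 40.0]))  # same tile, farther out
        reads = simulate_acquisition(
            [near, far], geometry, AcquisitionConfig(p_read=1.0), seed=0
        )
        assert set(reads["tag_id"]) == {"near"}

    def test_timestamps_strictly_increasing(self, small_cage):
        _, reads = small_cage
        assert np.all(np.diff(reads["t_s"].to_numpy()) > 0)

    def test_at_most_one_read_per_antenna_per_cycle(self, small_cage):
        _, reads = small_cage
        cycle = np.floor(reads["t_s"] * 3.0 + 1e-9).astype(int)  # 3 Hz scan
        counts = reads.groupby([cycle, "antenna_col", "antenna_row"]).size()
        assert counts.max() == 1

    def test_fast_mover_missed_for_whole_cycles(self, geometry):
        # tag sweeping the cage much faster than the scan visits its tiles
        rate = 25.0
        t = np.arange(int(60 * rate) + 1) / rate
        y = 150.0 + 140.0 * np.sin(2 * np.pi * 2.0 * t)  # 2 full sweeps/s
        xy = np.column_stack([np.full_like(t, 75.0), y])
        reads = simulate_acquisition(
            [Trajectory("fast", t, xy)], geometry,
            AcquisitionConfig(scan_rate_hz=3.0, p_read=1.0), seed=0,
        )
        cycles_with_reads = set((reads["t_s"] * 3.0).astype(int))
        assert len(cycles_with_reads) < 180  # some cycles missed entirely

    def test_empty_trajectory_list_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_acquisition([], geometry)

    def test_snapped_polyline_recovered_at_high_scan_rate(self, geometry):
        """With p_read = 1 and a slow tag, the estimated polyline length
        approaches the true path length snapped to antenna centers."""
        from cagetrack import assemble_tracks, estimate_distance, interpolate_track

        rate = 25.0
        t = np.arange(int(600 * rate) + 1) / rate
        y = 10.0 + 4.0 * t  # 4 mm/s straight run up the cage and off the top
        y = np.where(y > 290.0, 290.0, y)
        xy = np.column_stack([np.full_like(t, 75.0), y])
        traj = Trajectory("slow", t, xy)
        sx, sy = geometry.snap(xy[:, 0], xy[:, 1])
        snapped = np.column_stack([sx, sy])
        true_snapped = np.hypot(*np.diff(snapped, axis=0).T).sum()

        reads = simulate_acquisition(
            [traj], geometry, AcquisitionConfig(scan_rate_hz=8.0, p_read=1.0), seed=0
        )
        track = interpolate_track(assemble_tracks(reads, geometry)[0], t_end=600.0)
        assert estimate_distance(track) == pytest.approx(true_snapped, rel=0.1)

    @pytest.mark.parametrize(
        "kwargs", [dict(scan_rate_hz=0.0), dict(scan_rate_hz=9.0), dict(p_read=0.0),
                   dict(p_read=1.5)]
    )
    def test_invalid_acquisition_config(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionConfig(**kwargs)


class TestActivitySeriesGenerator:
    def test_noise_free_values_follow_profile(self, schedule):
        p = make_profile(schedule, strain="low")
        s = simulate_activity_series(p, n_days=1, scale_mm=2000.0, noise_shape=None)
        mids = s.bin_mids()
        assert np.allclose(s.values, 2000.0 * p.intensity(mids))

    def test_seeded_noise_reproducible_with_unit_mean(self, schedule):
        p = make_profile(schedule, strain="low")
        a = simulate_activity_series(p, n_days=7, seed=9)
        b = simulate_activity_series(p, n_days=7, seed=9)
        assert np.array_equal(a.values, b.values)
        noise_free = simulate_activity_series(p, n_days=7, noise_shape=None)
        ratio = a.values.sum() / noise_free.values.sum()
        assert ratio == pytest.approx(1.0, abs=0.05)
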