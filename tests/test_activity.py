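"""Binned activity, actograms, phase totals, settling bout, anticipation
and the bespoke ANOVA/ANCOVA group comparison."""

import numpy as np
import pytest
from scipy import stats

from cagetrack import LightSchedule, make_profile, simulate_activity_series
from cagetrack.activity import (
    ActivitySeries,
    anticipatory_index,
    bin_activity,
    compare_groups,
    detect_settling_bout,
    double_plot_actogram,
    phase_totals,
)
from cagetrack.tracking import LocationTrack

DAY_S = 86_400.0


def _triangle_track(duration_s=3600.0, speed_mm_s=50.0 / 60.0):
    """Constant-speed track bouncing along y so each 1 s step has equal length."""
    n = int(duration_s)
    t = np.arange(n + 1, dtype=float)
    amplitude = 250.0  # multiple of the per-step distance, so folds are exact
    phase = (t * speed_mm_s) % (2 * amplitude)
    y = 25.0 + np.where(phase <= amplitude, phase, 2 * amplitude - phase)
    xy = np.column_stack([np.full_like(t, 75.0), y])
    return LocationTrack("a", t, xy, np.ones(len(t), bool))


class TestBinning:
    def test_constant_speed_gives_constant_bins(self):
        # 50 mm/min for an hour -> 300 mm in every full 6-min bin
        series = bin_activity(_triangle_track(), bin_width_s=360.0)
        assert np.allclose(series.values[:10], 300.0)

    def test_bin_sums_conserve_total_distance(self):
        from cagetrack.tracking import estimate_distance

        track = _triangle_track(duration_s=5000.0)
        series = bin_activity(track, bin_width_s=360.0)
        assert series.values.sum() == pytest.approx(estimate_distance(track))

    def test_stationary_track_all_zero(self):
        t = np.arange(100.0)
        track = LocationTrack("a", t, np.tile([25.0, 25.0], (100, 1)), np.ones(100, bool))
        assert np.all(bin_activity(track, 360.0).values == 0.0)

    def test_bin_width_must_divide_day(self):
        with pytest.raises(ValueError):
            bin_activity(_triangle_track(), bin_width_s=7 * 60.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ActivitySeries("a", 360.0, np.array([1.0, -2.0]))


class TestActogram:
    def _series(self, n_days, bins_per_day=240):
        rng = np.random.default_rng(1)
        return ActivitySeries("a", DAY_S / bins_per_day,
                              rng.uniform(0, 100, int(n_days * bins_per_day)))

    def test_two_day_layout(self):
        s = self._series(2)
        mat = double_plot_actogram(s)
        assert mat.shape == (2, 480)
        assert np.array_equal(mat[0, :240], s.values[:240])
        assert np.array_equal(mat[0, 240:], s.values[240:])
        assert np.all(np.isnan(mat[1, 240:]))

    def test_right_half_equals_next_left_half(self):
        mat = double_plot_actogram(self._series(5))
        for d in range(4):
            assert np.array_equal(mat[d, 240:], mat[d + 1, :240])

    def test_seven_days_seven_rows(self):
        assert double_plot_actogram(self._series(7)).shape[0] == 7

    def test_under_one_day_rejected(self):
        with pytest.raises(ValueError):
            double_plot_actogram(self._series(0.5))


class TestPhaseTotals:
    def test_nocturnal_simulation_dark_exceeds_light(self, schedule):
        p = make_profile(schedule, strain="high")
        s = simulate_activity_series(p, n_days=3, seed=0)
        pt = phase_totals(s, schedule)
        assert pt.dark_total_mm > pt.light_total_mm

    def test_uniform_activity_balances_phases(self, schedule):
        s = ActivitySeries("a", 360.0, np.full(3 * 240, 10.0))
        pt = phase_totals(s, schedule)
        assert pt.dark_total_mm / pt.dark_hours == pytest.approx(
            pt.light_total_mm / pt.light_hours
        )

    def test_standard_exclusions_use_60_of_72_hours(self, schedule):
        s = ActivitySeries("a", 360.0, np.ones(720))  # 72 h of 6-min bins
        window = schedule.retained_window(72 * 3600.0, n_lights_on=3)
        pt = phase_totals(s, schedule, window=window)
        assert pt.light_hours + pt.dark_hours == pytest.approx(60.0)
        assert (pt.dark_hours, pt.light_hours) == (36.0, 24.0)


class TestSettlingBout:
    def test_programmed_bout_recovered_exactly(self, schedule):
        p = make_profile(schedule, strain="high", settle_duration_min=60.0, jitter=0)
        s = simulate_activity_series(p, n_days=2, noise_shape=None)
        bout = detect_settling_bout(s, schedule)
        assert bout.detected
        assert abs(bout.duration_min - 60.0) <= 6.0

    def test_no_bout_detected_when_none_programmed(self, schedule):
        p = make_profile(schedule, strain="high", settle_duration_min=0.0, jitter=0)
        s = simulate_activity_series(p, n_days=2, noise_shape=None)
        assert detect_settling_bout(s, schedule).duration_min <= 6.0

    def test_never_settling_returns_full_span_with_warning(self, schedule):
        # alternating high/low: never two consecutive bins at or below median
        vals = np.tile([100.0, 10.0], 240)
        s = ActivitySeries("a", 360.0, vals)
        with pytest.warns(UserWarning, match="never settled"):
            bout = detect_settling_bout(s, schedule)
        assert not bout.detected
        assert bout.duration_min == pytest.approx(480 * 6.0)


class TestAnticipatoryIndex:
    def test_zero_window_activity(self, schedule):
        vals = np.ones(240) * 5.0
        # zero out the 18:00-19:00 bins (recording starts at noon -> 6-7 h)
        mids = (np.arange(240) + 0.5) * 360.0
        vals[schedule.clock_window_mask(mids, "18:00", "19:00")] = 0.0
        anticip, daytime = anticipatory_index(ActivitySeries("a", 360.0, vals), schedule)
        assert anticip == 0.0
        assert daytime > 0.0

    def test_linear_in_activity(self, schedule):
        p = make_profile(schedule, strain="intermediate")
        s = simulate_activity_series(p, n_days=7, seed=1)
        a1, d1 = anticipatory_index(s, schedule)
        doubled = ActivitySeries(s.tag_id, s.bin_width_s, 2.0 * s.values)
        a2, d2 = anticipatory_index(doubled, schedule)
        assert (a2, d2) == (pytest.approx(2 * a1), pytest.approx(2 * d1))

    def test_taller_ramp_raises_index_at_matched_covariate(self, schedule):
        """Profiles differing only in anticipatory-ramp height produce
        ordered pre-dark sums while the daytime covariate stays matched."""
        sums = []
        for peak in (0.3, 0.6, 0.9):
            p = make_profile(schedule, strain="low", ramp_peak=peak, jitter=0)
            s = simulate_activity_series(p, n_days=7, noise_shape=None)
            sums.append(anticipatory_index(s, schedule))
        anticip = [a for a, _ in sums]
        assert anticip == sorted(anticip)
        assert anticip[0] < anticip[2]


class TestCompareGroups:
    def test_identical_groups_give_zero_f(self):
        res = compare_groups([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                             ["a", "a", "a", "b", "b", "b"])
        assert res.F == pytest.approx(0.0)
        assert (res.tukey["p_adj"] > 0.9).all()

    def test_matches_brute_force_sums_of_squares(self):
        """F equals a hand-computed decomposition on random small datasets."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            sizes = rng.integers(3, 8, size=3)
            y = np.concatenate([rng.normal(m, 1.0, n) for m, n in zip((0, 1, 3), sizes)])
            g = np.repeat(["a", "b", "c"], sizes)
            res = compare_groups(y, g)
            # brute force: explicit loops over groups and observations
            grand = sum(y) / len(y)
            ssb = ssw = 0.0
            for lab in ("a", "b", "c"):
                vals = [v for v, gg in zip(y, g) if gg == lab]
                m = sum(vals) / len(vals)
                ssb += len(vals) * (m - grand) ** 2
                ssw += sum((v - m) ** 2 for v in vals)
            f_oracle = (ssb / 2) / (ssw / (len(y) - 3))
            assert abs(res.F - f_oracle) <= 1e-10
            # cross-check against the standard library implementation
            f_scipy, p_scipy = stats.f_oneway(*[y[g == lab] for lab in "abc"])
            assert res.F == pytest.approx(f_scipy)
            assert res.p == pytest.approx(p_scipy)

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        y = np.concatenate([rng.normal(m, 1.0, 9) for m in (0.0, 0.8, 2.0)])
        g = np.repeat(["a", "b", "c"], 9)
        res = compare_groups(y, g)
        sm = pairwise_tukeyhsd(y, g)
        assert np.allclose(res.tukey["p_adj"].to_numpy(), sm.pvalues, atol=1e-6)

    def test_ancova_matches_statsmodels_ols(self):
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 12
        g = np.repeat(["a", "b", "c"], n)
        x = rng.uniform(10, 20, 3 * n)
        effects = {"a": 0.0, "b": 1.5, "c": 3.0}
        y = np.array([effects[gg] for gg in g]) + 0.4 * x + rng.normal(0, 0.5, 3 * n)
        res = compare_groups(y, g, covariate=x)
        df = pd.DataFrame({"y": y, "g": g, "x": x})
        fit = smf.ols("y ~ C(g) + x", data=df).fit()
        table = smapi.stats.anova_lm(fit, typ=2)
        assert res.F == pytest.approx(table.loc["C(g)", "F"])
        assert res.p == pytest.approx(table.loc["C(g)", "PR(>F)"])
        # adjusted means recover the programmed group offsets
        assert res.group_means["b"] - res.group_means["a"] == pytest.approx(1.5, abs=0.5)

    def test_shifted_groups_detected_at_modest_n(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([rng.normal(m, 1.0, 12) for m in (0.0, 1.2, 2.4)])
        g = np.repeat(["a", "b", "c"], 12)
        assert compare_groups(y, g).p < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])  # zero variance
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])  # one group
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])  # group of one
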