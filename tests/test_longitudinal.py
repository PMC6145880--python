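"""Tests of normalization, growth regression, and per-day statistics."""

import math

import numpy as np
import pytest

from plaquetrack.longitudinal import (
    LongitudinalSeries,
    compare_size_classes,
    fit_linear_growth,
    normalize_to_day0,
    significance_stars,
    summarize_by_day,
    test_days_vs_day0,
)
from plaquetrack.segmentation import PlaqueMeasurement
from plaquetrack.synthetic import make_normalized_trajectories


def measurement(pid, day, volume, area=None):
    return PlaqueMeasurement(
        plaque_id=pid,
        day=day,
        volume=volume,
        max_xs_area=area if area is not None else volume / 10.0,
        voxel_count=int(volume),
        threshold_used=150.0,
        laser_power=10.0,
    )


def series(pid, days, values, baseline=1000.0):
    return LongitudinalSeries(
        plaque_id=pid,
        days=list(days),
        volume_pct=list(values),
        baseline_volume=baseline,
    )


def frame_to_series(df):
    out = []
    for pid, sub in df.groupby("plaque_id"):
        sub = sub.sort_values("day")
        out.append(series(pid, sub["day"].tolist(), sub["value"].tolist()))
    return out


class TestNormalize:
    def test_day0_is_100_and_ratios_in_percent(self):
        ms = [measurement("a", 0, 1000.0), measurement("a", 2, 620.0)]
        s = normalize_to_day0(ms)
        assert s.volume_pct == pytest.approx([100.0, 62.0])

    def test_equal_sizes_give_100(self):
        ms = [measurement("a", 0, 500.0), measurement("a", 2, 500.0)]
        assert normalize_to_day0(ms).volume_pct[1] == pytest.approx(100.0)

    def test_missing_day0_raises(self):
        with pytest.raises(ValueError, match="day-0"):
            normalize_to_day0([measurement("a", 2, 500.0)])

    def test_idempotent(self):
        """Normalizing an already-normalized series changes nothing."""
        ms = [measurement("a", 0, 1000.0), measurement("a", 7, 1300.0)]
        s1 = normalize_to_day0(ms)
        ms2 = [
            measurement("a", d, v, area=a)
            for d, v, a in zip(s1.days, s1.volume_pct, s1.area_pct)
        ]
        s2 = normalize_to_day0(ms2)
        assert s2.volume_pct == pytest.approx(s1.volume_pct)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        ss = [series("a", [0, 2], [100, 50]), series("b", [0, 2], [100, 74])]
        day2 = [d for d in summarize_by_day(ss) if d.day == 2][0]
        assert day2.mean == pytest.approx(62.0)
        assert day2.sd == pytest.approx(16.97, abs=0.01)

    def test_single_plaque_day_reports_zero_sd(self):
        ss = [series("a", [0, 4], [100, 120])]
        day4 = [d for d in summarize_by_day(ss) if d.day == 4][0]
        assert day4.sd == 0.0 and day4.n == 1

    def test_identical_values_zero_sd(self):
        ss = [series(p, [0, 2], [100, 80]) for p in "abc"]
        assert [d for d in summarize_by_day(ss) if d.day == 2][0].sd == 0.0


class TestGrowthFit:
    def test_exact_line(self):
        fit = fit_linear_growth(np.array([(0, 0), (1, 2), (2, 4)], dtype=float))
        assert fit.slope == pytest.approx(2.0)
        assert fit.syx == pytest.approx(0.0, abs=1e-9)

    def test_flat_series_zero_slope(self):
        fit = fit_linear_growth(np.array([(0, 100), (10, 100), (21, 100)], dtype=float))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        """Slope, CI and Sy.x agree with the hand-computed OLS formulas."""
        pts = np.array([(0, 101.0), (2, 97.0), (7, 135.0), (14, 142.0), (21, 177.0)])
        x, y = pts[:, 0], pts[:, 1]
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        syx = math.sqrt((resid**2).sum() / (n - 2))
        se_slope = syx / math.sqrt(sxx)
        from scipy import stats

        tcrit = stats.t.ppf(0.975, n - 2)
        fit = fit_linear_growth(pts)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.syx == pytest.approx(syx, rel=1e-9)
        assert fit.slope_ci[0] == pytest.approx(slope - tcrit * se_slope, rel=1e-9)
        assert fit.slope_ci[1] == pytest.approx(slope + tcrit * se_slope, rel=1e-9)

    def test_day_range_restriction(self):
        pts = np.array([(0, 500.0), (2, 100.0), (7, 110.0), (14, 124.0), (21, 138.0)])
        fit = fit_linear_growth(pts, day_range=(2, 21))
        assert fit.n_points == 4
        assert fit.slope == pytest.approx(2.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_growth(np.array([(0, 1.0), (0, 2.0), (0, 3.0)]))
        with pytest.raises(ValueError):
            fit_linear_growth(np.array([(0, 1.0), (1, 2.0)]))


class TestDaysVsDay0:
    def test_identical_values_not_significant(self):
        ss = [series(p, [0, 2, 4], [100, 100, 100]) for p in "abcd"]
        for d in test_days_vs_day0(ss):
            if d.day != 0:
                assert d.p_adjusted == pytest.approx(1.0)

    def test_single_comparison_adjustment_is_identity(self):
        """With m=1 the Holm-Sidak adjusted p equals the raw p."""
        rng = np.random.default_rng(3)
        ss = [
            series(f"p{i}", [0, 2], [100, 100 + rng.normal(5, 10)]) for i in range(6)
        ]
        (day2,) = [d for d in test_days_vs_day0(ss) if d.day == 2]
        assert day2.p_adjusted == pytest.approx(day2.p_raw)

    def test_adjusted_p_dominates_raw_and_is_monotone(self):
        rng = np.random.default_rng(11)
        ss = [
            series(
                f"p{i}",
                [0, 2, 7, 14, 21],
                [100] + list(100 + rng.normal([0, 3, 10, 40], 12)),
            )
            for i in range(8)
        ]
        days = [d for d in test_days_vs_day0(ss) if d.day != 0]
        for d in days:
            assert d.p_adjusted >= d.p_raw - 1e-12
        by_raw = sorted(days, key=lambda d: d.p_raw)
        adj = [d.p_adjusted for d in by_raw]
        assert adj == sorted(adj)

    def test_large_separation_highly_significant(self):
        """A 10-SD day-2 effect with n=10/day is detected at p<0.0001."""
        for seed in range(20):
            df = make_normalized_trajectories(10, (0, 2), -50.0, 5.0, seed=seed)
            ss = frame_to_series(df)
            (day2,) = [d for d in test_days_vs_day0(ss) if d.day == 2]
            assert day2.p_adjusted < 0.0001

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            test_days_vs_day0([series("a", [0, 2], [100, 90])])


class TestSizeClasses:
    def test_median_split_ties_go_to_smaller(self):
        ss = [
            series("a", [0, 2], [100, 110], baseline=1.0),
            series("b", [0, 2], [100, 112], baseline=2.0),
            series("c", [0, 2], [100, 120], baseline=3.0),
            series("d", [0, 2], [100, 122], baseline=4.0),
        ]
        cmp = compare_size_classes(ss)
        assert sorted(cmp.smaller_ids) == ["a", "b"]
        assert sorted(cmp.larger_ids) == ["c", "d"]

    def test_identical_trajectories_p_near_one(self):
        ss = [
            series(p, [0, 2, 4], [100, 105, 110], baseline=b)
            for p, b in zip("abcd", (1, 2, 3, 4))
        ]
        cmp = compare_size_classes(ss)
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.larger_rate_mean == pytest.approx(cmp.smaller_rate_mean)

    def test_too_few_plaques_rejected(self):
        with pytest.raises(ValueError):
            compare_size_classes(
                [series("a", [0, 2], [100, 90]), series("b", [0, 2], [100, 95])]
            )

    def test_type_i_error_rate_near_alpha(self):
        """Equal true slopes in both classes: ~5% false-positive rate."""
        rejections = 0
        n_reps = 500
        rng = np.random.default_rng(77)
        for _ in range(n_reps):
            ss = []
            for i in range(10):
                days = [0, 2, 4, 7, 10, 12, 14, 21]
                vals = [100.0] + [
                    100 + 2.0 * d + rng.normal(0, 15) for d in days[1:]
                ]
                ss.append(series(f"p{i}", days, vals, baseline=rng.uniform(500, 2000)))
            if compare_size_classes(ss).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_reps - 0.05) <= 0.03


def test_significance_star_thresholds():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.00009) == "****"


def test_end_to_end_control_scenario_day14_mean():
    """Control-like growth (3.6%/day, 36 plaques): day-14 mean near 150.4%."""
    df = make_normalized_trajectories(36, (0, 2, 4, 7, 10, 12, 14, 21), 3.6, 25.0, seed=5)
    ss = frame_to_series(df)
    (day14,) = [d for d in summarize_by_day(ss) if d.day == 14]
    expected = 100 * (1 + 3.6 * 14 / 100)
    # 3-sigma band on the mean of n noisy observations
    assert abs(day14.mean - expected) <= 3 * 25.0 / math.sqrt(day14.n)
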