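"""Longitudinal statistics for tracked plaques.

All sizes are first normalized to the plaque's own day-0 measurement and
expressed as a percentage, so every plaque starts at exactly 100% and the
statistics below operate on dimensionless trajectories:

* per-day mean and SD across plaques;
* a pooled ordinary-least-squares growth line (slope in percent per day,
  95% CI of the slope, and Sy.x, the standard error of the estimate);
* comparisons of each later imaging day against day 0 after a one-way
  ANOVA, with Holm-Sidak adjustment of the per-day p-values;
* a comparison of per-plaque growth rates between plaques larger and
  smaller than the median baseline volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .segmentation import PlaqueMeasurement

__all__ = [
    "LongitudinalSeries",
    "GrowthFit",
    "DaySummary",
    "SizeClassComparison",
    "normalize_to_day0",
    "summarize_by_day",
    "fit_linear_growth",
    "test_days_vs_day0",
    "compare_size_classes",
    "significance_stars",
]

#: significance thresholds, most stringent last
STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


def significance_stars(p: float) -> str:
    """Star notation for an adjusted p-value ('' if not significant)."""
    return "*" * sum(p <= level for level in STAR_LEVELS)


@dataclass
class LongitudinalSeries:
    """Day-0-normalized trajectory of one plaque (values in percent)."""

    plaque_id: str
    days: List[int]
    volume_pct: List[float]
    area_pct: Optional[List[float]] = None
    group: Optional[str] = None
    baseline_volume: Optional[float] = None  # um^3, day-0 absolute size
    baseline_area: Optional[float] = None  # um^2

    def __post_init__(self) -> None:
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        if 0 not in self.days:
            raise ValueError("day 0 must be present")
        i0 = self.days.index(0)
        if abs(self.volume_pct[i0] - 100.0) > 1e-9:
            raise ValueError("day-0 normalized volume must be exactly 100%")

    def values(self, metric: str = "volume") -> List[float]:
        if metric == "volume":
            return list(self.volume_pct)
        if metric == "area":
            if self.area_pct is None:
                raise ValueError("series has no area values")
            return list(self.area_pct)
        raise ValueError(f"unknown metric {metric!r}")


@dataclass
class GrowthFit:
    """Pooled OLS growth line: slope (%/day), its 95% CI, and Sy.x (%)."""

    slope: float
    slope_ci: Tuple[float, float]
    syx: float
    n_points: int
    intercept: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "slope_pct_per_day": self.slope,
            "slope_ci95": list(self.slope_ci),
            "syx_pct": self.syx,
            "n_points": self.n_points,
            "intercept_pct": self.intercept,
        }


@dataclass
class DaySummary:
    """Across-plaque mean and SD of normalized size on one day."""

    day: int
    mean: float
    sd: float
    n: int
    p_raw: Optional[float] = None
    p_adjusted: Optional[float] = None

    @property
    def stars(self) -> str:
        return "" if self.p_adjusted is None else significance_stars(self.p_adjusted)


@dataclass
class SizeClassComparison:
    """Welch t-test of per-plaque growth rates, larger vs smaller plaques."""

    larger_rate_mean: float
    smaller_rate_mean: float
    t_statistic: float
    p_value: float
    larger_ids: List[str]
    smaller_ids: List[str]


def normalize_to_day0(
    measurements: Sequence[PlaqueMeasurement], group: Optional[str] = None
) -> LongitudinalSeries:
    """Normalize one plaque's measurements to its day-0 values (percent).

    The day-0 measurement must exist and be positive; if the plaque was
    imaged at elevated power on day 0, pass the power-corrected row.
    """
    ms = sorted(measurements, key=lambda m: m.day)
    ids = {m.plaque_id for m in ms}
    if len(ids) != 1:
        raise ValueError(f"measurements span multiple plaques: {ids}")
    day0 = [m for m in ms if m.day == 0]
    if not day0:
        raise ValueError("missing day-0 measurement")
    base = day0[0]
    if base.volume <= 0 or base.max_xs_area <= 0:
        raise ValueError("day-0 size must be positive")
    return LongitudinalSeries(
        plaque_id=base.plaque_id or "",
        days=[m.day for m in ms],
        volume_pct=[100.0 * m.volume / base.volume for m in ms],
        area_pct=[100.0 * m.max_xs_area / base.max_xs_area for m in ms],
        group=group,
        baseline_volume=base.volume,
        baseline_area=base.max_xs_area,
    )


def _pooled_points(
    series: Sequence[LongitudinalSeries],
    metric: str,
    day_range: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    days, values = [], []
    for s in series:
        for d, v in zip(s.days, s.values(metric)):
            if day_range is None or day_range[0] <= d <= day_range[1]:
                days.append(d)
                values.append(v)
    return np.asarray(days, dtype=float), np.asarray(values, dtype=float)


def summarize_by_day(
    series: Sequence[LongitudinalSeries], metric: str = "volume"
) -> List[DaySummary]:
    """Arithmetic mean and sample SD (n-1 denominator) per imaging day.

    A day observed in a single plaque reports SD 0 with n = 1.
    """
    by_day: Dict[int, List[float]] = {}
    for s in series:
        for d, v in zip(s.days, s.values(metric)):
            by_day.setdefault(d, []).append(v)
    out = []
    for day in sorted(by_day):
        vals = np.asarray(by_day[day])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(DaySummary(day=day, mean=float(vals.mean()), sd=sd, n=len(vals)))
    return out


def fit_linear_growth(
    points_or_series,
    metric: str = "volume",
    day_range: Optional[Tuple[int, int]] = None,
) -> GrowthFit:
    """OLS fit of pooled (day, normalized size) points.

    Accepts either a sequence of :class:`LongitudinalSeries` or an array of
    ``(day, value)`` pairs.  Returns the slope in percent per day with its
    95% t-based confidence interval (n - 2 df) and Sy.x, the standard error
    of the estimate ``sqrt(SS_res / (n - 2))``.  ``day_range=(lo, hi)``
    restricts the fit, e.g. to days 2-21 of a treated group.
    """
    if len(points_or_series) and isinstance(points_or_series[0], LongitudinalSeries):
        x, y = _pooled_points(points_or_series, metric, day_range)
    else:
        arr = np.asarray(points_or_series, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (day, value) pairs")
        if day_range is not None:
            keep = (arr[:, 0] >= day_range[0]) & (arr[:, 0] <= day_range[1])
            arr = arr[keep]
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit a growth line")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct days")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return GrowthFit(
        slope=float(model.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        syx=float(np.sqrt(model.mse_resid)),
        n_points=int(model.nobs),
        intercept=float(model.params[0]),
    )


def test_days_vs_day0(
    series: Sequence[LongitudinalSeries], metric: str = "volume"
) -> List[DaySummary]:
    """One-way ANOVA across days, then each later day vs day 0 (Holm-Sidak).

    Per-day comparisons use t statistics built on the ANOVA's pooled
    residual mean square (all-days error df), and the per-comparison
    p-values are Holm-Sidak adjusted.  Returns the per-day summaries with
    raw and adjusted p filled in for every day except day 0.
    """
    summaries = summarize_by_day(series, metric)
    by_day: Dict[int, List[float]] = {}
    for s in series:
        for d, v in zip(s.days, s.values(metric)):
            by_day.setdefault(d, []).append(v)
    days = sorted(by_day)
    if 0 not in by_day:
        raise ValueError("no day-0 observations")
    groups = [np.asarray(by_day[d], dtype=float) for d in days]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 days with >= 2 observations each")

    n_total = sum(len(g) for g in groups)
    k = len(groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_error = n_total - k
    mse = ss_within / df_error

    base = np.asarray(by_day[0], dtype=float)
    later = [d for d in days if d != 0]
    p_raw = []
    for d in later:
        g = np.asarray(by_day[d], dtype=float)
        if mse == 0.0:
            p = 1.0 if g.mean() == base.mean() else 0.0
        else:
            t = (g.mean() - base.mean()) / math.sqrt(mse * (1 / len(g) + 1 / len(base)))
            p = 2.0 * stats.t.sf(abs(t), df_error)
        p_raw.append(p)
    # clip away from exactly 1 to keep the Sidak log1p transform finite
    _, p_adj, _, _ = multipletests(
        np.clip(p_raw, 0.0, 1.0 - 1e-15), alpha=0.05, method="holm-sidak"
    )

    lookup = {d: (pr, pa) for d, pr, pa in zip(later, p_raw, p_adj)}
    for s in summaries:
        if s.day in lookup:
            s.p_raw, s.p_adjusted = (float(v) for v in lookup[s.day])
    return summaries


# despite the name, this is a statistical procedure, not a pytest test
test_days_vs_day0.__test__ = False  # type: ignore[attr-defined]


def _per_plaque_slope(s: LongitudinalSeries, metric: str) -> float:
    x = np.asarray(s.days, dtype=float)
    y = np.asarray(s.values(metric), dtype=float)
    if len(x) < 2:
        raise ValueError(f"plaque {s.plaque_id} has fewer than 2 time points")
    return float(stats.linregress(x, y).slope)


def compare_size_classes(
    series: Sequence[LongitudinalSeries], metric: str = "volume"
) -> SizeClassComparison:
    """Compare growth rates of plaques larger vs smaller than the median.

    Plaques are binned by their day-0 absolute volume: strictly above the
    median is 'larger', at or below the median is 'smaller'.  Each plaque's
    rate of change is the OLS slope of its own normalized trajectory, and
    the two classes are compared with a Welch two-sample t-test.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 plaques for a size-class comparison")
    baselines = [s.baseline_volume for s in series]
    if any(b is None for b in baselines):
        raise ValueError("series lack baseline volumes")
    median = float(np.median(baselines))
    larger = [s for s in series if s.baseline_volume > median]
    smaller = [s for s in series if s.baseline_volume <= median]
    if len(larger) < 2 or len(smaller) < 2:
        raise ValueError("need at least 2 plaques per size class")
    r_large = np.asarray([_per_plaque_slope(s, metric) for s in larger])
    r_small = np.asarray([_per_plaque_slope(s, metric) for s in smaller])
    if np.allclose(r_large, r_large.mean()) and np.allclose(r_small, r_small.mean()) \
            and np.isclose(r_large.mean(), r_small.mean()):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(r_large, r_small, equal_var=False)
    return SizeClassComparison(
        larger_rate_mean=float(r_large.mean()),
        smaller_rate_mean=float(r_small.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        larger_ids=[s.plaque_id for s in larger],
        smaller_ids=[s.plaque_id for s in smaller],
    )
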