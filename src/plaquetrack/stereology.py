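"""Design-based stereology estimators for plaque counts and areas.

The histological endpoint counts amyloid plaques on serial sections with
an optical-fractionator design and measures their maximum cross-sectional
area with a nucleator probe.  The fractionator samples a fraction of the
tissue three ways -- every ``1/ssf``-th section (section sampling
fraction), a systematic-uniform-random grid of counting frames covering
``asf = frame_area / grid_area`` of each sampled section, and an optical
disector spanning ``hsf = disector_height / section_thickness`` of the
section depth (guard zones excluded) -- and scales the raw count back up:

    N_est = sum_Q / (ssf * asf * hsf)

The precision rule of thumb for such counts is the Schmitz-Hof coefficient
of error, ``CE = 1 / sqrt(sum_Q)``.  The nucleator estimates a profile's
area from four rays radiating from its centre, ``area = pi * mean(l_i^2)``,
which is exact for circular profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SectionPopulation

__all__ = [
    "SamplingDesign",
    "StereologyResult",
    "default_design",
    "fractionator_count",
    "fractionator_count_at",
    "estimate_total",
    "schmitz_hof_ce",
    "nucleator_area",
    "surface_area_per_section",
    "percent_decrease",
    "group_comparisons",
]


@dataclass(frozen=True)
class SamplingDesign:
    """Optical-fractionator sampling parameters (all lengths in um)."""

    counting_frame: Tuple[float, float] = (200.0, 200.0)
    grid: Tuple[float, float] = (500.0, 500.0)
    disector_height: float = 20.0
    guard_zone: float = 2.0
    section_thickness: float = 40.0
    ssf: float = 0.25  # section sampling fraction

    def __post_init__(self) -> None:
        if self.counting_frame[0] > self.grid[0] or self.counting_frame[1] > self.grid[1]:
            raise ValueError("counting frame must fit inside the sampling grid cell")
        if self.disector_height + 2 * self.guard_zone > self.section_thickness:
            raise ValueError("disector plus guard zones exceed section thickness")
        if not 0.0 < self.ssf <= 1.0:
            raise ValueError("ssf must be in (0, 1]")

    @property
    def asf(self) -> float:
        """Area sampling fraction: frame area / grid area."""
        return (self.counting_frame[0] * self.counting_frame[1]) / (
            self.grid[0] * self.grid[1]
        )

    @property
    def hsf(self) -> float:
        """Height sampling fraction: disector height / section thickness."""
        return self.disector_height / self.section_thickness


def default_design() -> SamplingDesign:
    """The hippocampal plaque-counting design: 200x200 um frames on a
    500x500 um grid (asf 0.16), 20 um disector with 2 um guard zones in
    40 um sections (hsf 0.5), every fourth section (ssf 1/4)."""
    return SamplingDesign()


@dataclass
class StereologyResult:
    """Fractionator output for one subject."""

    sum_Q: int
    N_est: float
    CE: Optional[float]
    sections_sampled: int
    mean_profile_area: Optional[float] = None  # um^2, nucleator
    surface_area_per_section: Optional[float] = None  # um^2

    def to_dict(self) -> dict:
        return {
            "sum_Q": self.sum_Q,
            "N_est": self.N_est,
            "CE_schmitz_hof": self.CE,
            "sections_sampled": self.sections_sampled,
            "mean_profile_area_um2": self.mean_profile_area,
            "surface_area_per_section_um2": self.surface_area_per_section,
        }


def _counted_mask(
    pop: SectionPopulation,
    design: SamplingDesign,
    sampled_sections: np.ndarray,
    grid_offset: Tuple[float, float],
) -> np.ndarray:
    """Boolean per profile: counted under the fractionator rules.

    A profile is counted iff (1) its section is sampled, (2) its counting
    point falls in a counting frame of the tiled grid, where the frame's
    left and bottom edges are exclusion lines (a point exactly on them is
    not counted) and the right and top edges are inclusion lines, (3) its
    counting z lies inside the optical disector (guard zone excluded), and
    (4) it is entirely contained within the section.
    """
    df = pop.frame
    if len(df) == 0:
        return np.zeros(0, dtype=bool)
    fw, fh = design.counting_frame
    gx, gy = design.grid
    ox, oy = grid_offset
    in_section = np.isin(df["section"].to_numpy(), sampled_sections)
    u = np.mod(df["x"].to_numpy() - ox, gx)
    v = np.mod(df["y"].to_numpy() - oy, gy)
    in_frame = (u > 0) & (u <= fw) & (v > 0) & (v <= fh)
    z = df["z"].to_numpy()
    z0 = design.guard_zone
    in_disector = (z >= z0) & (z < z0 + design.disector_height)
    contained = (df["z_lo"].to_numpy() >= 0.0) & (
        df["z_hi"].to_numpy() <= pop.thickness_um
    )
    return in_section & in_frame & in_disector & contained


def fractionator_count_at(
    pop: SectionPopulation,
    design: SamplingDesign,
    section_start: int,
    grid_offset: Tuple[float, float],
) -> int:
    """Raw fractionator count for explicit section start and grid offset.

    ``section_start`` indexes the first sampled section; every
    ``round(1/ssf)``-th section after it is sampled.  ``grid_offset`` is
    the (x, y) origin of the frame grid in um.
    """
    if design.counting_frame[0] > pop.region_um[0] or (
        design.counting_frame[1] > pop.region_um[1]
    ):
        raise ValueError("counting frame is larger than the section region")
    period = max(int(round(1.0 / design.ssf)), 1)
    sampled = np.arange(section_start % period, pop.n_sections, period)
    return int(_counted_mask(pop, design, sampled, grid_offset).sum())


def fractionator_count(
    pop: SectionPopulation, design: SamplingDesign, seed: int = 0
) -> Tuple[int, int]:
    """Systematic-uniform-random fractionator count of one subject.

    The section start and the frame-grid origin are drawn uniformly from
    the seeded RNG, making the design unbiased for populations whose
    counting points are uniform in the sampled volume.  Returns
    ``(sum_Q, n_sections_sampled)``.
    """
    rng = np.random.default_rng(seed)
    period = max(int(round(1.0 / design.ssf)), 1)
    start = int(rng.integers(period))
    offset = (
        float(rng.uniform(0.0, design.grid[0])),
        float(rng.uniform(0.0, design.grid[1])),
    )
    sum_q = fractionator_count_at(pop, design, start, offset)
    n_sampled = len(np.arange(start % period, pop.n_sections, period))
    return sum_q, n_sampled


def estimate_total(sum_Q: float, design: SamplingDesign) -> float:
    """Scale a raw fractionator count to an estimated total:
    ``N_est = sum_Q / (ssf * asf * hsf)``."""
    if sum_Q < 0:
        raise ValueError("sum_Q must be nonnegative")
    return sum_Q / (design.ssf * design.asf * design.hsf)


def schmitz_hof_ce(sum_Q: float) -> float:
    """Schmitz-Hof coefficient of error of a fractionator count:
    ``1 / sqrt(sum_Q)``; undefined for a zero count."""
    if sum_Q <= 0:
        raise ValueError("CE is undefined for sum_Q <= 0")
    return 1.0 / math.sqrt(sum_Q)


def nucleator_area(ray_lengths: Sequence[float]) -> float:
    """Nucleator profile-area estimate from 4 ray lengths (um):
    ``pi * mean(l_i^2)``.  Exact for circular profiles."""
    rays = np.asarray(ray_lengths, dtype=float)
    if rays.shape != (4,):
        raise ValueError("exactly 4 ray lengths required")
    if np.any(rays < 0):
        raise ValueError("ray lengths must be nonnegative")
    return float(math.pi * np.mean(rays**2))


def nucleator_rays_for_disk(radius: float, seed: int = 0) -> np.ndarray:
    """Rays of an orthogonal nucleator probe on a circular profile.

    The rotation is drawn uniformly, but a circle returns its radius in
    every direction; the randomness matters only for non-circular
    profiles (not modelled here).
    """
    _ = np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi)
    return np.full(4, float(radius))


def surface_area_per_section(
    avg_plaques_per_section: float, mean_max_xs_area: float
) -> float:
    """Plaque-covered area per section: the product of the average
    fractionator plaque count per section and the mean nucleator area."""
    if avg_plaques_per_section < 0 or mean_max_xs_area < 0:
        raise ValueError("inputs must be nonnegative")
    return avg_plaques_per_section * mean_max_xs_area


def percent_decrease(control_mean: float, treated_mean: float) -> float:
    """Percent decrease of the treated group mean relative to control:
    ``100 * (CTL - FUS) / CTL``."""
    if control_mean == 0:
        raise ValueError("control mean is zero")
    return 100.0 * (control_mean - treated_mean) / control_mean


def analyze_subject(
    pop: SectionPopulation, design: SamplingDesign, seed: int = 0
) -> StereologyResult:
    """Full fractionator + nucleator readout of one subject's sections."""
    sum_q, n_sampled = fractionator_count(pop, design, seed=seed)
    mean_area = (
        float(pop.frame["area"].mean()) if len(pop.frame) else None
    )
    per_section = sum_q / n_sampled if n_sampled else 0.0
    return StereologyResult(
        sum_Q=sum_q,
        N_est=estimate_total(sum_q, design),
        CE=schmitz_hof_ce(sum_q) if sum_q > 0 else None,
        sections_sampled=n_sampled,
        mean_profile_area=mean_area,
        surface_area_per_section=(
            surface_area_per_section(per_section, mean_area)
            if mean_area is not None
            else None
        ),
    )


def group_comparisons(
    subject_metrics: Optional[pd.DataFrame] = None,
    mortality_tables: Optional[Dict[str, np.ndarray]] = None,
    weights: Optional[pd.DataFrame] = None,
    group_col: str = "group",
    control_label: str = "CTL",
    treated_label: str = "FUS",
) -> dict:
    """Group statistics for the histology endpoint.

    Parameters
    ----------
    subject_metrics
        One row per subject: a ``group`` column (control/treated labels)
        plus numeric metric columns (e.g. plaque number, area, surface
        area).  Each metric gets an unpaired two-tailed t-test and the
        percent difference of means, ``100 * (CTL - FUS) / CTL``.
    mortality_tables
        Named 2x2 contingency tables ``[[died_a, survived_a],
        [died_b, survived_b]]``; each gets a two-sided Fisher exact test.
    weights
        Long-format weight fluctuations with columns ``group``,
        ``treatment_number`` and ``value``; analyzed by a two-way ANOVA
        reporting the two main effects.
    """
    report: dict = {}
    if subject_metrics is not None:
        metrics = {}
        ctl = subject_metrics[subject_metrics[group_col] == control_label]
        fus = subject_metrics[subject_metrics[group_col] == treated_label]
        if len(ctl) < 2 or len(fus) < 2:
            raise ValueError("need >= 2 subjects per group for t-tests")
        for col in subject_metrics.columns:
            if col == group_col or not np.issubdtype(
                subject_metrics[col].dtype, np.number
            ):
                continue
            a, b = ctl[col].to_numpy(float), fus[col].to_numpy(float)
            if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(
                a.mean(), b.mean()
            ):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(a, b, equal_var=True)
            metrics[col] = {
                "mean_control": float(a.mean()),
                "mean_treated": float(b.mean()),
                "percent_decrease": percent_decrease(float(a.mean()), float(b.mean())),
                "t_statistic": float(t_stat),
                "p_value": float(p),
            }
        report["metrics"] = metrics
    if mortality_tables is not None:
        fisher = {}
        for name, table in mortality_tables.items():
            table = np.asarray(table, dtype=int)
            if table.shape != (2, 2) or np.any(table < 0):
                raise ValueError(f"table {name!r} is not a nonnegative 2x2 table")
            _, p = stats.fisher_exact(table, alternative="two-sided")
            fisher[name] = {"table": table.tolist(), "p_value": float(p)}
        report["mortality"] = fisher
    if weights is not None:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        required = {group_col, "treatment_number", "value"}
        if not required <= set(weights.columns):
            raise ValueError(f"weights frame must have columns {sorted(required)}")
        model = smf.ols(
            f"value ~ C({group_col}) + C(treatment_number)", data=weights
        ).fit()
        table = anova_lm(model, typ=2)
        report["weights_anova"] = {
            "p_group": float(table.loc[f"C({group_col})", "PR(>F)"]),
            "p_treatment_number": float(table.loc["C(treatment_number)", "PR(>F)"]),
        }
    return report
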