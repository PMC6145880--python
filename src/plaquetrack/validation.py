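"""Ground-truth recovery experiments on synthetic data.

Each function simulates a study-like scenario with the synthetic-data
module, runs the corresponding analysis path, and returns how well the
known generating parameters are recovered.  They are used both by the test
suite and by ``scripts/acceptance.py``; all randomness flows from the
single ``seed`` argument.

Study-like defaults used throughout: 0.31 x 0.31 x 2 um voxels, plaque
radii of a few micrometres, the day grid 0, 2, 4, 7, 10, 12, 14, 21, a
control growth rate of 3.6% per day with ~25 percentage points of
per-observation scatter, a treated-group day-2 step shrinkage to 0.6 of
baseline, and the 200/500 um fractionator design on 40 um sections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grid import VoxelGrid3D
from .longitudinal import fit_linear_growth, normalize_to_day0, summarize_by_day
from .mri import relative_enhancement
from .power import PowerCalibration, correct_measurement, fit_power_response
from .segmentation import PlaqueMeasurement, segment_plaque
from .stereology import (
    SamplingDesign,
    default_design,
    estimate_total,
    fractionator_count,
)
from .synthetic import (
    Ellipsoid,
    StackSpec,
    apply_power_inflation,
    make_longitudinal_series,
    make_normalized_trajectories,
    make_plaque_stack,
    make_section_population,
    make_t1_slice,
)

__all__ = [
    "sphere_stack_spec",
    "sphere_volumetry_errors",
    "calibrate_power_response",
    "growth_ci_coverage",
    "shrinkage_recovery",
    "fractionator_bias",
    "enhancement_recovery",
]

#: imaging-day grid of the longitudinal experiment
DAY_GRID = (0, 2, 4, 7, 10, 12, 14, 21)

_SPACING = (0.31, 0.31, 2.0)


def sphere_stack_spec(
    radius_um: float,
    rng: np.random.Generator,
    noise_sd: float = 20.0,
    laser_power: float = 10.0,
    margin_xy_um: float = 3.0,
    margin_z_um: float = 4.0,
    align_z: bool = False,
) -> StackSpec:
    """Spec for one spherical calibration plaque with a snug operator ROI.

    The stack is sized like a tight ROI around the plaque (a few um of
    margin), the way an operator crops a tracked plaque.  The centre gets
    a random sub-voxel offset unless ``align_z`` pins it to a slice centre.
    """
    dx, dy, dz = _SPACING
    nx = ny = int((2 * radius_um + 2 * margin_xy_um) / dx) + 1
    nz = int((2 * radius_um + 2 * margin_z_um) / dz) + 2
    cx = (nx // 2) * dx + rng.uniform(0, dx)
    cy = (ny // 2) * dy + rng.uniform(0, dy)
    cz = (nz // 2 - 1) * dz + (0.0 if align_z else rng.uniform(0, dz))
    return StackSpec(
        shape_xyz=(nx, ny, nz),
        spacing=_SPACING,
        plaques=(Ellipsoid((cx, cy, cz), (radius_um,) * 3, 300.0),),
        background_mean=100.0,
        noise_sd=noise_sd,
        laser_power=laser_power,
        seed=int(rng.integers(2**31)),
    )


def sphere_volumetry_errors(
    seed: int,
    radii_um: Sequence[float] = (3, 4, 5, 6, 7, 8),
    noise_sd: float = 20.0,
) -> Dict[float, Tuple[float, float]]:
    """Segment synthetic spheres and report relative errors.

    ``noise_sd=20`` against a peak-background contrast of 200 gives an SNR
    of 10.  Sphere centres are aligned to a slice in z (plaques are centred
    in the stack by the operator) and randomly offset in XY.  Returns
    ``{radius: (volume_rel_err, area_rel_err)}`` where errors are signed
    fractions versus the analytic sphere volume and great-circle area.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for r in radii_um:
        spec = sphere_stack_spec(r, rng, noise_sd=noise_sd, align_z=True)
        grid, _, _ = make_plaque_stack(spec)
        m = segment_plaque(grid)
        v_true = 4.0 / 3.0 * math.pi * r**3
        a_true = math.pi * r**2
        out[r] = (m.volume / v_true - 1.0, m.max_xs_area / a_true - 1.0)
    return out


def calibrate_power_response(
    seed: int,
    beta_true: float = 0.04,
    p_ref: float = 8.0,
    powers: Sequence[float] = (8, 10, 12, 14, 16),
    replicates: int = 3,
    radius_um: float = 5.0,
) -> PowerCalibration:
    """Simulated laser-power calibration sweep.

    Renders ``replicates`` sphere stacks per power, applies the synthetic
    power inflation (true ``beta_true``), segments, and fits the linear
    power response.  Recovery of ``beta_true`` validates the calibration
    path end to end.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in powers:
        for _ in range(replicates):
            spec = sphere_stack_spec(radius_um, rng, noise_sd=15.0, laser_power=p)
            grid, _, _ = make_plaque_stack(spec)
            m = segment_plaque(apply_power_inflation(grid, beta_true, p_ref))
            rows.append((p, m.volume, m.max_xs_area))
    return fit_power_response(rows)


def growth_ci_coverage(
    seed: int,
    n_replicates: int = 100,
    n_plaques: int = 36,
    slope: float = 3.6,
    noise_sd: float = 25.0,
) -> Tuple[int, float]:
    """Coverage of the pooled-OLS slope CI under the control growth model.

    Each replicate simulates ``n_plaques`` day-0-normalized trajectories on
    the standard day grid with the true slope (percent per day) and
    per-observation noise, fits the pooled growth line, and checks whether
    the 95% CI covers the truth.  Returns ``(n_covered, mean_slope)``.
    """
    covered = 0
    slopes = []
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in ss:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        df = make_normalized_trajectories(n_plaques, DAY_GRID, slope, noise_sd, rep_seed)
        fit = fit_linear_growth(df[["day", "value"]].to_numpy())
        slopes.append(fit.slope)
        if fit.slope_ci[0] <= slope <= fit.slope_ci[1]:
            covered += 1
    return covered, float(np.mean(slopes))


def shrinkage_recovery(
    seed: int,
    n_plaques: int = 18,
    shrink_fraction: float = 0.6,
    beta_true: float = 0.04,
    p_ref: float = 8.0,
) -> Tuple[float, PowerCalibration]:
    """Full-pipeline recovery of a day-2 treatment shrinkage.

    Simulates ``n_plaques`` treated plaques imaged on days 0 and 2 whose
    true volume steps to ``shrink_fraction`` of baseline on day 2.  Day-0
    stacks are acquired at an elevated laser power and power-inflated with
    the true ``beta_true``; the pipeline then segments every stack,
    corrects the day-0 measurements with a calibration fitted from its own
    synthetic sweep, normalizes to day 0, and returns the day-2 mean
    normalized volume in percent (truth: ``100 * shrink_fraction``).
    """
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cal = calibrate_power_response(
            int(rng.integers(2**31)), beta_true=beta_true, p_ref=p_ref
        )
        series = []
        for i in range(n_plaques):
            radius = rng.uniform(3.5, 6.5)
            day0_power = rng.uniform(12.0, 16.0)
            spec = sphere_stack_spec(radius, rng, noise_sd=15.0, laser_power=day0_power)
            per_day = make_longitudinal_series(
                spec, [0, 2], growth_rate=0.0, shrink_event=(2, shrink_fraction)
            )
            ms: List[PlaqueMeasurement] = []
            for day, (plaque_grid, _), _ in per_day:
                if day == 0:
                    plaque_grid = apply_power_inflation(plaque_grid, beta_true, p_ref)
                else:
                    plaque_grid = replace(plaque_grid, laser_power=p_ref)
                m = segment_plaque(plaque_grid)
                m.plaque_id = f"p{i:03d}"
                m.day = day
                if day == 0:
                    m = correct_measurement(m, cal)
                ms.append(m)
            series.append(normalize_to_day0(ms))
    day2 = [s for s in summarize_by_day(series) if s.day == 2][0]
    return day2.mean, cal


def fractionator_bias(
    seed: int,
    n_offsets: int = 200,
    design: Optional[SamplingDesign] = None,
    n_sections: int = 24,
    region_um: Tuple[float, float] = (2000.0, 2000.0),
    density_per_mm2: float = 10.0,
) -> Tuple[float, int]:
    """Mean fractionator estimate over systematic-random designs.

    Generates one fixed section population, runs the optical fractionator
    with ``n_offsets`` independent section starts and grid offsets, and
    returns ``(mean_N_est, true_total)``.  With uniform counting points the
    estimator is unbiased, so the mean should approach the true total.
    """
    design = design or default_design()
    pop = make_section_population(
        n_sections=n_sections,
        region_um=region_um,
        density_per_mm2=density_per_mm2,
        seed=seed,
    )
    ests = []
    children = np.random.SeedSequence(seed + 1).spawn(n_offsets)
    for child in children:
        q, _ = fractionator_count(pop, design, seed=int(child.generate_state(1)[0] % 2**31))
        ests.append(estimate_total(q, design))
    return float(np.mean(ests)), pop.total_count


def enhancement_recovery(
    seed: int,
    enhancement_factor: float = 1.46,
    noise_sd: float = 5.0,
    background_mean: float = 100.0,
) -> float:
    """Relative enhancement measured on one synthetic T1-weighted slice.

    Four targeted spots with plateau intensity ``factor * background`` are
    placed well inside a 96 x 96 slice; the background ROI is an untargeted
    rectangle.  Returns the measured relative enhancement in percent
    (truth: ``100 * enhancement_factor``).
    """
    targets = [(24, 24), (24, 72), (72, 24), (72, 72)]
    image, _ = make_t1_slice(
        (96, 96), background_mean, targets, enhancement_factor,
        noise_sd=noise_sd, seed=seed,
    )
    result = relative_enhancement(image, targets, (44, 56, 34, 62))
    return result.relative_enhancement
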