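"""Synthetic data with known ground truth for every pipeline input.

No raw acquisitions are distributed with this package, so each analysis
stage is exercised on simulated data that emulates the relevant acquisition
geometry and artifacts:

* two-channel 3D two-photon stacks -- bright ellipsoidal plaques
  (methoxy-X04-like channel) over a noisy background, plus a vessel
  channel (TR70-like) whose signal can bleed into the plaque channel,
  as happens after ultrasound-induced blood-brain-barrier opening;
* laser-power-dependent apparent size inflation of the imaged objects;
* longitudinal series in which plaque volume follows a linear
  percent-per-day growth model, optionally with a step shrinkage event;
* 2D histological sections populated with plaque profiles at a known
  density, for the stereology estimators;
* post-contrast T1-weighted slices with four enhanced focal spots, for
  the MR enhancement metric.

Every generator takes one explicit integer seed and is bit-reproducible;
no global RNG state is used.  Ground truth (masks, volumes, rates,
densities, enhancement factors) is returned alongside the data and, when
written to disk, goes to a separate file so analysis code cannot read it
by accident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid3D

__all__ = [
    "Ellipsoid",
    "VesselTube",
    "StackSpec",
    "SyntheticTruth",
    "SectionPopulation",
    "make_plaque_stack",
    "make_longitudinal_series",
    "apply_power_inflation",
    "make_section_population",
    "make_t1_slice",
    "make_normalized_trajectories",
]


@dataclass(frozen=True)
class Ellipsoid:
    """One plaque: centre and semi-axes in micrometres, peak intensity."""

    center: Tuple[float, float, float]  # (x, y, z) um
    semi_axes: Tuple[float, float, float]  # (a, b, c) um
    peak_intensity: float


@dataclass(frozen=True)
class VesselTube:
    """A vessel as a polyline of (x, y, z) um points with a radius."""

    points: Tuple[Tuple[float, float, float], ...]
    radius: float
    intensity: float


@dataclass
class StackSpec:
    """Geometry and artifact parameters of one simulated two-photon stack.

    Defaults follow a typical plaque acquisition: 0.31 um XY pixels with a
    2 um axial step.  ``psf_sigma_lateral``/``psf_sigma_axial`` are the
    Gaussian-blur sigmas (um) standing in for the two-photon point-spread
    function; the defaults correspond to a 0.5 um lateral / 2.0 um axial
    FWHM (sigma = FWHM / 2.355), typical of a high-NA water-immersion
    objective.  ``noise_sd=None`` uses 10% of the brightest plaque's
    peak-minus-background contrast.
    """

    shape_xyz: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (0.31, 0.31, 2.0)
    plaques: Tuple[Ellipsoid, ...] = ()
    vessel_tubes: Tuple[VesselTube, ...] = ()
    background_mean: float = 100.0
    noise_sd: Optional[float] = None
    bleedthrough_fraction: float = 0.0
    laser_power: float = 10.0
    psf_sigma_lateral: float = 0.21  # 0.5 um FWHM
    psf_sigma_axial: float = 0.85  # 2.0 um FWHM
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not 0.0 <= self.bleedthrough_fraction < 1.0:
            raise ValueError("bleedthrough_fraction must be in [0, 1)")
        for p in self.plaques:
            if any(a <= 0 for a in p.semi_axes):
                raise ValueError("plaque semi-axes must be positive")
            if p.peak_intensity <= self.background_mean:
                raise ValueError("plaque peak intensity must exceed background_mean")

    @property
    def extent_um(self) -> Tuple[float, float, float]:
        """Physical span of voxel centres along (x, y, z)."""
        nx, ny, nz = self.shape_xyz
        dx, dy, dz = self.spacing
        return ((nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz)

    def default_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        if not self.plaques:
            return 0.0
        contrast = max(p.peak_intensity - self.background_mean for p in self.plaques)
        return 0.1 * contrast


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated dataset.

    Only the fields relevant to the generating call are populated; e.g. a
    single stack has masks and volumes but no growth rate.
    """

    true_masks: Optional[List[np.ndarray]] = None
    true_volumes: Optional[List[float]] = None
    analytic_volumes: Optional[List[float]] = None
    growth_rate: Optional[float] = None  # percent per day
    shrink_fraction: Optional[float] = None
    section_density: Optional[float] = None  # plaques per mm^2 per section
    enhancement_factor: Optional[float] = None

    def summary(self) -> dict:
        """JSON-serializable truth without the (possibly large) masks."""
        return {
            "true_volumes_um3": self.true_volumes,
            "analytic_volumes_um3": self.analytic_volumes,
            "growth_rate_pct_per_day": self.growth_rate,
            "shrink_fraction": self.shrink_fraction,
            "section_density_per_mm2": self.section_density,
            "enhancement_factor": self.enhancement_factor,
        }


def _coordinate_axes(spec: StackSpec):
    nx, ny, nz = spec.shape_xyz
    dx, dy, dz = spec.spacing
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    zs = np.arange(nz) * dz
    return xs, ys, zs


def _render_ellipsoid(spec: StackSpec, plaque: Ellipsoid):
    """Truth mask (centre-in-ellipsoid test) and anti-aliased coverage field."""
    xs, ys, zs = _coordinate_axes(spec)
    cx, cy, cz = plaque.center
    a, b, c = plaque.semi_axes
    # normalized radius rho on the (z, y, x) grid
    u = ((xs - cx) / a) ** 2
    v = ((ys - cy) / b) ** 2
    w = ((zs - cz) / c) ** 2
    rho2 = w[:, None, None] + v[None, :, None] + u[None, None, :]
    mask = rho2 <= 1.0
    # soft ~1-voxel edge ramp for anti-aliasing: full inside, 0.5 on the surface
    rho = np.sqrt(rho2)
    edge = float(np.mean(spec.spacing)) / float(min(plaque.semi_axes))
    coverage = np.clip(0.5 + (1.0 - rho) / edge, 0.0, 1.0)
    return mask, coverage


def _render_tube(spec: StackSpec, tube: VesselTube) -> np.ndarray:
    """Soft indicator of a tube around a polyline, on the (z, y, x) grid."""
    xs, ys, zs = _coordinate_axes(spec)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # physical (x, y, z) per voxel
    dist = np.full(pts.shape[:3], np.inf)
    nodes = [np.asarray(p, dtype=float) for p in tube.points]
    if len(nodes) == 1:
        dist = np.linalg.norm(pts - nodes[0], axis=-1)
    for p0, p1 in zip(nodes[:-1], nodes[1:]):
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0.0:
            seg = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
            seg = np.linalg.norm(pts - (p0 + t[..., None] * d), axis=-1)
        dist = np.minimum(dist, seg)
    edge = float(np.mean(spec.spacing))
    return np.clip(0.5 + (tube.radius - dist) / edge, 0.0, 1.0)


def _blur(field: np.ndarray, spec: StackSpec) -> np.ndarray:
    dx, dy, dz = spec.spacing
    sigma_vox = (
        spec.psf_sigma_axial / dz,
        spec.psf_sigma_lateral / dy,
        spec.psf_sigma_lateral / dx,
    )
    return ndimage.gaussian_filter(field, sigma=sigma_vox)


def make_plaque_stack(
    spec: StackSpec,
) -> Tuple[VoxelGrid3D, VoxelGrid3D, SyntheticTruth]:
    """Render one two-channel stack plus ground truth.

    Each plaque is an anti-aliased ellipsoid blurred with the Gaussian PSF;
    the truth masks are the *pre-blur* centre-in-ellipsoid voxelizations.
    The vessel channel is rendered from the tube list, and
    ``bleedthrough_fraction`` of its above-background signal is added to
    the plaque channel.  Gaussian noise is then added to both channels.

    Raises
    ------
    ValueError
        If any plaque extends beyond the stack bounds.
    """
    ex, ey, ez = spec.extent_um
    for p in spec.plaques:
        for coord, ax, extent in zip(p.center, p.semi_axes, (ex, ey, ez)):
            if coord - ax < 0 or coord + ax > extent:
                raise ValueError(
                    f"plaque at {p.center} with semi-axes {p.semi_axes} "
                    "extends beyond stack bounds"
                )

    nz = spec.shape_xyz[2]
    shape_zyx = (nz, spec.shape_xyz[1], spec.shape_xyz[0])
    plaque_signal = np.zeros(shape_zyx)
    masks: List[np.ndarray] = []
    volumes: List[float] = []
    analytic: List[float] = []
    voxel_volume = float(np.prod(spec.spacing))
    for p in spec.plaques:
        mask, coverage = _render_ellipsoid(spec, p)
        masks.append(mask)
        volumes.append(float(mask.sum()) * voxel_volume)
        analytic.append(4.0 / 3.0 * math.pi * float(np.prod(p.semi_axes)))
        plaque_signal = np.maximum(
            plaque_signal, (p.peak_intensity - spec.background_mean) * coverage
        )

    vessel_signal = np.zeros(shape_zyx)
    for tube in spec.vessel_tubes:
        vessel_signal = np.maximum(vessel_signal, tube.intensity * _render_tube(spec, tube))

    if spec.plaques:
        plaque_signal = _blur(plaque_signal, spec)
    if spec.vessel_tubes:
        vessel_signal = _blur(vessel_signal, spec)

    plaque_data = (
        spec.background_mean
        + plaque_signal
        + spec.bleedthrough_fraction * vessel_signal
    )
    vessel_data = spec.background_mean + vessel_signal

    rng = np.random.default_rng(spec.seed)
    noise_sd = spec.default_noise_sd()
    if noise_sd > 0:
        plaque_data = plaque_data + rng.normal(0.0, noise_sd, shape_zyx)
        vessel_data = vessel_data + rng.normal(0.0, noise_sd, shape_zyx)
    plaque_data = np.clip(plaque_data, 0.0, None)
    vessel_data = np.clip(vessel_data, 0.0, None)

    meta = dict(spacing=spec.spacing, laser_power=spec.laser_power)
    plaque_grid = VoxelGrid3D(plaque_data, channel="plaque", **meta)
    vessel_grid = VoxelGrid3D(vessel_data, channel="vessel", **meta)
    truth = SyntheticTruth(
        true_masks=masks, true_volumes=volumes, analytic_volumes=analytic
    )
    return plaque_grid, vessel_grid, truth


def _volume_factor(
    day: int, growth_rate: float, shrink_event: Optional[Tuple[int, float]]
) -> float:
    f = 1.0 + growth_rate * day / 100.0
    if shrink_event is not None and day >= shrink_event[0]:
        f *= shrink_event[1]
    return f


def make_longitudinal_series(
    spec: StackSpec,
    days: Sequence[int],
    growth_rate: float,
    shrink_event: Optional[Tuple[int, float]] = None,
) -> List[Tuple[int, Tuple[VoxelGrid3D, VoxelGrid3D], SyntheticTruth]]:
    """Longitudinal stacks under linear volume growth plus optional shrinkage.

    True plaque volume follows ``v(t) = v0 * (1 + growth_rate * t / 100)``,
    with an optional multiplicative step ``shrink_event=(day, fraction)``
    applied from the event day onward (emulating a treatment effect).
    Linear dimensions scale as the cube root of the volume factor.  Each
    day's stack gets an independent child seed derived from ``spec.seed``.

    Returns a list of ``(day, (plaque_grid, vessel_grid), truth)``.
    """
    days = list(days)
    if days != sorted(days) or len(set(days)) != len(days):
        raise ValueError("days must be strictly ascending")
    if not days or days[0] != 0:
        raise ValueError("first day must be 0")
    if shrink_event is not None and not 0.0 < shrink_event[1] <= 1.0:
        raise ValueError("shrink fraction must be in (0, 1]")

    children = np.random.SeedSequence(spec.seed).spawn(len(days))
    out = []
    for day, child in zip(days, children):
        f = _volume_factor(day, growth_rate, shrink_event)
        if f <= 0.0:
            raise ValueError(f"volume factor {f} <= 0 on day {day}")
        scale = f ** (1.0 / 3.0)
        scaled = replace(
            spec,
            plaques=tuple(
                replace(p, semi_axes=tuple(a * scale for a in p.semi_axes))
                for p in spec.plaques
            ),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        plaque_grid, vessel_grid, truth = make_plaque_stack(scaled)
        truth.growth_rate = growth_rate
        truth.shrink_fraction = None if shrink_event is None else shrink_event[1]
        for g in (plaque_grid, vessel_grid):
            g.day = day
        out.append((day, (plaque_grid, vessel_grid), truth))
    return out


def apply_power_inflation(
    stack: VoxelGrid3D, beta: float, p_ref: float
) -> VoxelGrid3D:
    """Inflate apparent object size with laser power.

    Measured plaque size grows with excitation power; this emulates that
    artifact by magnifying each XY slice about the stack centre by
    ``sqrt(1 + beta * (P - p_ref))`` per in-plane axis, so the footprint of
    a calibration object on every slice -- and hence its segmented volume --
    scales by ``1 + beta * (P - p_ref)``, monotonically in P.  The axial
    direction is left untouched: at a 2 um slice spacing the z profile is
    sampled too coarsely for resampling to express sub-slice size changes.
    Identity when ``beta == 0`` or ``P == p_ref``.
    """
    power = stack.laser_power
    if power is None:
        raise ValueError("stack has no laser_power metadata")
    factor = 1.0 + beta * (power - p_ref)
    if factor <= 0.0:
        raise ValueError(f"inflation factor {factor} <= 0")
    if factor == 1.0:
        return stack.with_data(stack.data.copy())
    s = factor**0.5
    center = (np.array(stack.data.shape[1:]) - 1) / 2.0
    matrix = np.eye(2) / s
    offset = center - matrix @ center
    data = np.empty_like(stack.data, dtype=float)
    for k in range(stack.data.shape[0]):
        data[k] = ndimage.affine_transform(
            stack.data[k], matrix, offset=offset, order=1, mode="nearest"
        )
    return stack.with_data(data)


@dataclass
class SectionPopulation:
    """Plaque profiles on serial 2D sections, with ground truth.

    ``frame`` holds one row per plaque profile: ``section`` (0-based
    index), ``x``/``y`` centroid in um within the region, ``z`` counting
    point within the section thickness, ``z_lo``/``z_hi`` the profile's
    z-extent (always inside the section), ``radius`` and ``area`` of the
    circular profile.
    """

    frame: pd.DataFrame
    n_sections: int
    region_um: Tuple[float, float]
    thickness_um: float = 40.0
    density_per_mm2: Optional[float] = None

    @property
    def total_count(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def make_section_population(
    n_sections: int,
    region_um: Tuple[float, float],
    density_per_mm2: float,
    area_dist: Tuple[float, float] = (300.0, 60.0),
    seed: int = 0,
    thickness_um: float = 40.0,
) -> SectionPopulation:
    """Populate serial sections with circular plaque profiles.

    Placement is homogeneous Poisson: each section draws a Poisson count
    with mean ``density_per_mm2 * region_area_mm2`` and uniform positions.
    Profile areas are Gaussian ``area_dist=(mean, sd)`` truncated to be
    positive.  The counting point ``z`` is uniform over the section
    thickness, and the recorded z-extent is the sphere of radius ``radius``
    around it clipped to the section, so every generated profile is
    entirely contained within its section.
    """
    if density_per_mm2 < 0:
        raise ValueError("density must be nonnegative")
    rng = np.random.default_rng(seed)
    w, h = region_um
    area_mm2 = (w / 1000.0) * (h / 1000.0)
    rows = []
    for s in range(n_sections):
        n = int(rng.poisson(density_per_mm2 * area_mm2))
        x = rng.uniform(0.0, w, n)
        y = rng.uniform(0.0, h, n)
        z = rng.uniform(0.0, thickness_um, n)
        area = rng.normal(area_dist[0], area_dist[1], n)
        area = np.clip(area, 1.0, None)
        radius = np.sqrt(area / math.pi)
        rows.append(
            pd.DataFrame(
                {
                    "section": s,
                    "x": x,
                    "y": y,
                    "z": z,
                    "z_lo": np.clip(z - radius, 0.0, None),
                    "z_hi": np.clip(z + radius, None, thickness_um),
                    "radius": radius,
                    "area": area,
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["section", "x", "y", "z", "z_lo", "z_hi", "radius", "area"]
        )
    )
    return SectionPopulation(
        frame=frame,
        n_sections=n_sections,
        region_um=(float(w), float(h)),
        thickness_um=float(thickness_um),
        density_per_mm2=float(density_per_mm2),
    )


def make_t1_slice(
    shape: Tuple[int, int],
    background_mean: float,
    targets: Sequence[Tuple[int, int]],
    enhancement_factor: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    core_radius: float = 1.0,
    shoulder_sigma: float = 2.0,
) -> Tuple[np.ndarray, SyntheticTruth]:
    """Post-contrast T1-weighted slice with four enhanced focal spots.

    Each target is a bright spot with a flat core of (Chebyshev) radius
    ``core_radius`` pixels -- so a centred 3x3 window reads the plateau --
    and a Gaussian shoulder beyond it.  The plateau intensity is
    ``enhancement_factor * background_mean``.
    """
    targets = [tuple(int(c) for c in t) for t in targets]
    if len(targets) != 4 or len(set(targets)) != 4:
        raise ValueError("exactly 4 distinct target coordinates required")
    nr, nc = shape
    for r, c in targets:
        if not (3 <= r < nr - 3 and 3 <= c < nc - 3):
            raise ValueError(f"target {(r, c)} must be at least 3 pixels inside bounds")
    if enhancement_factor < 1.0:
        raise ValueError("enhancement_factor must be >= 1")

    image = np.full(shape, float(background_mean))
    rr, cc = np.mgrid[0:nr, 0:nc]
    for r, c in targets:
        d = np.maximum(np.abs(rr - r), np.abs(cc - c)).astype(float)
        profile = np.where(
            d <= core_radius,
            1.0,
            np.exp(-((d - core_radius) ** 2) / (2.0 * shoulder_sigma**2)),
        )
        image += (enhancement_factor - 1.0) * background_mean * profile
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, shape)
    image = np.clip(image, 0.0, None)
    return image, SyntheticTruth(enhancement_factor=float(enhancement_factor))


def make_normalized_trajectories(
    n_plaques: int,
    days: Sequence[int],
    slope_pct_per_day: float,
    noise_sd_pct: float,
    seed: int = 0,
    shrink_event: Optional[Tuple[int, float]] = None,
) -> pd.DataFrame:
    """Measurement-level simulator of day-0-normalized plaque sizes.

    Skips the imaging layer entirely: each plaque's normalized size is
    ``100 * (1 + slope * t / 100)`` (times the step fraction after a shrink
    event) plus Gaussian measurement noise in percentage points.  Day 0 is
    exactly 100% by construction, matching the normalization convention.

    Returns a tidy frame with columns ``plaque_id``, ``day``, ``value``.
    """
    days = list(days)
    if not days or days[0] != 0:
        raise ValueError("first day must be 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_plaques):
        for day in days:
            expected = 100.0 * _volume_factor(day, slope_pct_per_day, shrink_event)
            value = 100.0 if day == 0 else expected + rng.normal(0.0, noise_sd_pct)
            rows.append({"plaque_id": f"p{i:03d}", "day": day, "value": value})
    return pd.DataFrame(rows)
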