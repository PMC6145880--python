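"""Laser-power correction of plaque size measurements.

In treated animals the first imaging session requires systematically higher
excitation power (dye bleed-through after blood-brain-barrier opening raises
the background), and measured plaque size grows with power.  Sizes measured
at a range of powers on the same plaques are used to calibrate a linear
relative-size response,

    s(P) / s(p_ref) = 1 + beta * (P - p_ref),

with ``p_ref`` the minimum calibrated power.  The fitted factor is then
divided out of measurements taken at elevated power; in the standard
pipeline this correction is applied to day-0 rows only, the day on which
the inflated powers occur.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .segmentation import PlaqueMeasurement

__all__ = ["PowerCalibration", "fit_power_response", "correct_measurement"]

logger = logging.getLogger(__name__)


@dataclass
class PowerCalibration:
    """Fitted linear power response for volume and area measurements."""

    p_ref: float  # mW; minimum calibrated power
    beta_volume: float  # fractional volume inflation per mW
    beta_area: float  # fractional area inflation per mW
    resid_sd_volume: float = 0.0
    resid_sd_area: float = 0.0
    n_points: int = 0
    power_range: Tuple[float, float] = (0.0, 0.0)

    def factor(self, power: float, which: str = "volume") -> float:
        beta = self.beta_volume if which == "volume" else self.beta_area
        return 1.0 + beta * (power - self.p_ref)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "p_ref_mW": self.p_ref,
                    "beta_volume_per_mW": self.beta_volume,
                    "beta_area_per_mW": self.beta_area,
                    "resid_sd_volume": self.resid_sd_volume,
                    "resid_sd_area": self.resid_sd_area,
                    "n_points": self.n_points,
                    "power_range_mW": list(self.power_range),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "PowerCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            p_ref=d["p_ref_mW"],
            beta_volume=d["beta_volume_per_mW"],
            beta_area=d["beta_area_per_mW"],
            resid_sd_volume=d.get("resid_sd_volume", 0.0),
            resid_sd_area=d.get("resid_sd_area", 0.0),
            n_points=d.get("n_points", 0),
            power_range=tuple(d.get("power_range_mW", (0.0, 0.0))),
        )


def _fit_beta(powers: np.ndarray, sizes: np.ndarray, p_ref: float) -> Tuple[float, float]:
    """No-intercept least squares of s/s_ref - 1 on P - p_ref."""
    s_ref = float(sizes[powers == p_ref].mean())
    x = powers - p_ref
    y = sizes / s_ref - 1.0
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        return 0.0, 0.0
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    dof = max(len(x) - 1, 1)
    return beta, float(np.sqrt(np.sum(resid**2) / dof))


def fit_power_response(
    calibration_measurements: Iterable[Tuple[float, float, float]],
) -> PowerCalibration:
    """Fit the linear power response from (power, volume, area) triples.

    The reference power is the minimum calibrated power; the model is
    constrained through ``s(p_ref)/s_ref = 1``, so only the slope ``beta``
    is estimated (separately for volume and area).  At least two distinct
    powers are required; fewer than three draws a warning since the
    linearity of the response is then unchecked.
    """
    data = np.asarray(list(calibration_measurements), dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("expected (power, volume, area) triples")
    powers, volumes, areas = data.T
    if np.any(volumes <= 0) or np.any(areas <= 0):
        raise ValueError("all calibration sizes must be positive")
    n_distinct = len(np.unique(powers))
    if n_distinct < 2:
        raise ValueError("need at least 2 distinct laser powers to calibrate")
    if n_distinct < 3:
        warnings.warn(
            "fewer than 3 distinct powers: linearity of the power response "
            "cannot be assessed",
            stacklevel=2,
        )
    p_ref = float(powers.min())
    beta_v, sd_v = _fit_beta(powers, volumes, p_ref)
    beta_a, sd_a = _fit_beta(powers, areas, p_ref)
    cal = PowerCalibration(
        p_ref=p_ref,
        beta_volume=beta_v,
        beta_area=beta_a,
        resid_sd_volume=sd_v,
        resid_sd_area=sd_a,
        n_points=len(powers),
        power_range=(float(powers.min()), float(powers.max())),
    )
    lo = 1.0 + min(cal.beta_volume, cal.beta_area) * (cal.power_range[1] - p_ref)
    if lo <= 0.0:
        raise ValueError("fitted correction factor is nonpositive inside the calibrated range")
    return cal


def correct_measurement(
    m: PlaqueMeasurement, cal: PowerCalibration
) -> PlaqueMeasurement:
    """Divide out the power-inflation factor from one measurement.

    Returns a new measurement with ``corrected=True``.  Powers outside the
    calibrated range extrapolate the linear model and draw a warning.
    """
    if m.laser_power is None:
        raise ValueError("measurement has no laser power; cannot correct")
    lo, hi = cal.power_range
    if not lo <= m.laser_power <= hi:
        warnings.warn(
            f"laser power {m.laser_power} mW outside calibrated range "
            f"[{lo}, {hi}] mW; extrapolating",
            stacklevel=2,
        )
    fv = cal.factor(m.laser_power, "volume")
    fa = cal.factor(m.laser_power, "area")
    if fv <= 0.0 or fa <= 0.0:
        raise ValueError("correction divisor is nonpositive")
    return replace(
        m, volume=m.volume / fv, max_xs_area=m.max_xs_area / fa, corrected=True
    )
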