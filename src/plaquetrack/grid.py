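"""Voxel-grid containers for anisotropic 3D fluorescence stacks.

Arrays are stored in ``(z, y, x)`` page order (the natural order of a
multi-page TIFF), while physical spacing is given as ``(dx, dy, dz)`` in
micrometres, matching how two-photon acquisition parameters are usually
reported (XY pixel size plus axial step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["VoxelGrid3D", "ROIBox"]


@dataclass
class VoxelGrid3D:
    """One channel of an anisotropic 3D intensity stack.

    Parameters
    ----------
    data
        Nonnegative intensities, shape ``(nz, ny, nx)``.
    spacing
        ``(dx, dy, dz)`` voxel size in micrometres; all strictly positive.
    channel
        Free-form channel label (e.g. ``"plaque"`` or ``"vessel"``).
    laser_power
        Acquisition laser power in mW, if known.
    day
        Imaging day relative to the first session (day 0).
    subject_id, plaque_id
        Identifiers used to join measurements across days.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    channel: str = ""
    laser_power: Optional[float] = None
    day: Optional[int] = None
    subject_id: Optional[str] = None
    plaque_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape_xyz(self) -> Tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def with_data(self, data: np.ndarray) -> "VoxelGrid3D":
        """Copy of this grid with the intensity array replaced."""
        return replace(self, data=np.asarray(data))


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned region of interest, half-open pixel/slice ranges.

    Ranges follow Python slicing: ``x=(x0, x1)`` selects columns
    ``x0 <= ix < x1``.
    """

    x: Tuple[int, int]
    y: Tuple[int, int]
    z: Tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("x", self.x), ("y", self.y), ("z", self.z)):
            if hi <= lo or lo < 0:
                raise ValueError(f"empty or negative ROI range {name}={lo}:{hi}")

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        """Slices in array ``(z, y, x)`` order."""
        return (slice(*self.z), slice(*self.y), slice(*self.x))

    def contained_in(self, shape_zyx: Tuple[int, int, int]) -> bool:
        nz, ny, nx = shape_zyx
        return self.x[1] <= nx and self.y[1] <= ny and self.z[1] <= nz

    @classmethod
    def full(cls, grid: VoxelGrid3D) -> "ROIBox":
        nz, ny, nx = grid.data.shape
        return cls(x=(0, nx), y=(0, ny), z=(0, nz))

    @classmethod
    def parse(cls, text: str) -> "ROIBox":
        """Parse ``"x0:x1,y0:y1,z0:z1"`` as used on the command line."""
        parts = text.split(",")
        if len(parts) != 3:
            raise ValueError(f"expected 'x0:x1,y0:y1,z0:z1', got {text!r}")
        ranges = []
        for part in parts:
            lo, _, hi = part.partition(":")
            ranges.append((int(lo), int(hi)))
        return cls(x=ranges[0], y=ranges[1], z=ranges[2])
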