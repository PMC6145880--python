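"""Reading and writing stacks, sidecar metadata, and measurement tables.

Stacks are stored as multi-page TIFFs (one page per z-slice) with a JSON
sidecar of the same basename carrying the acquisition metadata: voxel
spacing in um, laser power in mW, imaging day, and subject/plaque
identifiers.  Ground truth from the simulator is written to a separate
``*.truth.json`` so that analysis code cannot read it by accident.
Measurements travel as tidy CSV, one row per plaque per day.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .grid import VoxelGrid3D
from .segmentation import PlaqueMeasurement
from .synthetic import SyntheticTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth",
    "measurements_to_frame",
    "write_measurements",
    "read_measurements",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(grid: VoxelGrid3D, path) -> Path:
    """Write a grid as multi-page TIFF plus JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(grid.data, dtype=np.float32))
    meta = {
        "spacing_um": list(grid.spacing),
        "channel": grid.channel,
        "laser_power_mW": grid.laser_power,
        "day": grid.day,
        "subject_id": grid.subject_id,
        "plaque_id": grid.plaque_id,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_stack(path) -> VoxelGrid3D:
    """Read a multi-page TIFF and its JSON sidecar (if present)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return VoxelGrid3D(
        data=data,
        spacing=tuple(meta.get("spacing_um", (1.0, 1.0, 1.0))),
        channel=meta.get("channel", ""),
        laser_power=meta.get("laser_power_mW"),
        day=meta.get("day"),
        subject_id=meta.get("subject_id"),
        plaque_id=meta.get("plaque_id"),
    )


def write_truth(truth: SyntheticTruth, path) -> Path:
    """Write ground truth (without masks) to ``<path>``; keep it away from
    the measurement files consumed by the pipeline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth.summary(), fh, indent=2)
    return path


def measurements_to_frame(measurements: Sequence[PlaqueMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in measurements])


def write_measurements(measurements: Sequence[PlaqueMeasurement], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    measurements_to_frame(measurements).to_csv(path, index=False)
    return path


def read_measurements(path) -> List[PlaqueMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            PlaqueMeasurement(
                plaque_id=str(row["plaque_id"]),
                day=int(row["day"]),
                volume=float(row["volume_um3"]),
                max_xs_area=float(row["max_xs_area_um2"]),
                voxel_count=int(row["voxel_count"]),
                threshold_used=float(row["threshold_used"]),
                laser_power=(
                    float(row["laser_power_mW"])
                    if not pd.isna(row.get("laser_power_mW"))
                    else None
                ),
                corrected=bool(row.get("corrected", False)),
            )
        )
    return out
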