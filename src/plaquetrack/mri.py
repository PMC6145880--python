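"""Relative contrast enhancement of sonicated spots in T1-weighted images.

Blood-brain-barrier opening is confirmed on a post-sonication,
post-gadolinium T1-weighted image: each of the four targeted spots is read
out as the mean of a 3x3 pixel window centred on the target, the four
values are averaged, and the result is expressed as a percentage of the
mean intensity of an operator-chosen untargeted background region in the
same image.  A value of 150% means the targeted spots are 1.5x brighter
than untreated tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["EnhancementResult", "relative_enhancement"]


@dataclass
class EnhancementResult:
    """Per-target window means, background mean, and the ratio in percent."""

    target_means: List[float]
    background_mean: float
    relative_enhancement: float  # percent

    def to_dict(self) -> dict:
        return {
            "target_means": self.target_means,
            "background_mean": self.background_mean,
            "relative_enhancement_pct": self.relative_enhancement,
        }


def _window_bounds(r: int, c: int) -> Tuple[int, int, int, int]:
    return r - 1, r + 2, c - 1, c + 2


def relative_enhancement(
    image: np.ndarray,
    targets: Sequence[Tuple[int, int]],
    background_region: Tuple[int, int, int, int],
) -> EnhancementResult:
    """Relative enhancement of four targeted spots over background.

    Parameters
    ----------
    image
        2D intensity array (single T1-weighted slice).
    targets
        Four distinct ``(row, col)`` pixel coordinates (0-based); each 3x3
        window centred on a target must lie fully inside the image.
    background_region
        ``(r0, r1, c0, c1)`` half-open rectangle of untargeted tissue; must
        be inside the image and disjoint from every target window.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    targets = [tuple(int(v) for v in t) for t in targets]
    if len(targets) != 4 or len(set(targets)) != 4:
        raise ValueError("exactly 4 distinct targets required")
    nr, nc = image.shape
    r0, r1, c0, c1 = (int(v) for v in background_region)
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise ValueError("background region out of bounds or empty")

    target_means = []
    for r, c in targets:
        wr0, wr1, wc0, wc1 = _window_bounds(r, c)
        if wr0 < 0 or wc0 < 0 or wr1 > nr or wc1 > nc:
            raise ValueError(f"3x3 window at {(r, c)} extends beyond the image")
        if wr0 < r1 and r0 < wr1 and wc0 < c1 and c0 < wc1:
            raise ValueError(f"target window at {(r, c)} overlaps the background region")
        target_means.append(float(image[wr0:wr1, wc0:wc1].mean()))

    background = float(image[r0:r1, c0:c1].mean())
    if background <= 0:
        raise ValueError("background mean must be positive")
    combined = float(np.mean(target_means))
    return EnhancementResult(
        target_means=target_means,
        background_mean=background,
        relative_enhancement=100.0 * combined / background,
    )
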