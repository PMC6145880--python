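"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (triple loops, explicit BFS, exact
rational hypergeometric sums) so they share no code path with the
implementations they check.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force oracles


def bfs_component_oracle(mask: np.ndarray, seed: tuple) -> np.ndarray:
    """Face-connected component by explicit breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    if not mask[seed]:
        raise ValueError("seed not foreground")
    q = deque([seed])
    out[seed] = True
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in steps:
            n = (z + dz, y + dy, x + dx)
            if (
                0 <= n[0] < mask.shape[0]
                and 0 <= n[1] < mask.shape[1]
                and 0 <= n[2] < mask.shape[2]
                and mask[n]
                and not out[n]
            ):
                out[n] = True
                q.append(n)
    return out


def defragment_oracle(mask: np.ndarray, min_neighbors: int) -> np.ndarray:
    """Per-voxel 26-neighbourhood count by triple loop."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                count = 0
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                count += mask[zz, yy, xx]
                out[z, y, x] = count >= min_neighbors
    return out


def isodata_fixed_points(values: np.ndarray) -> list:
    """All isodata fixed points by scanning every distinct-value cut.

    For each cut between consecutive distinct values, compute
    t = (mean below + mean above) / 2 and keep it if it is consistent with
    the cut (i.e. the cut's upper group is exactly the values > t).
    """
    values = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(values)
    fixed = []
    for i in range(len(uniq) - 1):
        below = values[values <= uniq[i]]
        above = values[values > uniq[i]]
        t = 0.5 * (below.mean() + above.mean())
        if uniq[i] <= t < uniq[i + 1]:
            fixed.append(float(t))
    return fixed


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    Sums, in exact rational arithmetic, the probabilities of all tables
    with the observed margins whose point probability does not exceed the
    observed one (with the standard tiny relative gate for ties).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    gate = p_obs + p_obs / 10**7
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = pmf(x)
        if p <= gate:
            total += p
    return float(min(total, Fraction(1)))


def voxelized_sphere_count(center, radius, spacing, shape_zyx) -> int:
    """Centre-in-sphere voxel count by triple loop (small shapes only)."""
    dx, dy, dz = spacing
    cx, cy, cz = center
    count = 0
    for iz in range(shape_zyx[0]):
        for iy in range(shape_zyx[1]):
            for ix in range(shape_zyx[2]):
                if (
                    ((ix * dx - cx) / radius) ** 2
                    + ((iy * dy - cy) / radius) ** 2
                    + ((iz * dz - cz) / radius) ** 2
                ) <= 1.0:
                    count += 1
    return count


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
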