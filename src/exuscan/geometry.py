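"""Semicircular-region geometry: angular sectors, directions, radial samples.

Polar-to-grid rounding is half-up on each axis (``floor(x + 0.5)``).
Half-up commutes with integer translation, so offsets computed once per
direction are valid for every integer center pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ConfigError, InputError
from .image_io import GrayImage


@dataclass(frozen=True)
class PixelCoord:
    row: int
    col: int


@dataclass(frozen=True)
class SemiCircleSpec:
    """Angular sector ``i`` (1-based) covering [theta_lo, theta_hi]."""

    index: int
    theta_lo: float
    theta_hi: float

    @property
    def angle_range(self) -> tuple[float, float]:
        return self.theta_lo, self.theta_hi


@dataclass(frozen=True)
class DirectionSpec:
    """Direction ``j`` (1-based) inside semicircle ``semicircle``, at angle ``phi``."""

    semicircle: int
    j: int
    phi: float


@dataclass
class RadialSamples:
    """Ordered intensity samples along one direction from a center pixel."""

    direction: DirectionSpec
    radii: np.ndarray
    coords: list[PixelCoord]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def round_half_up(x: np.ndarray | float) -> np.ndarray | int:
    """Round half away from zero toward +inf: floor(x + 0.5)."""
    if np.isscalar(x):
        return int(math.floor(x + 0.5))
    return np.floor(np.asarray(x) + 0.5).astype(np.int64)


def make_semicircles(n_semi: int) -> list[SemiCircleSpec]:
    """Partition [0, 2π] into ``n_semi`` equal angular sectors."""
    if n_semi < 2:
        raise ConfigError(f"n_semi must be >= 2, got {n_semi}")
    width = 2.0 * math.pi / n_semi
    return [SemiCircleSpec(index=i, theta_lo=(i - 1) * width, theta_hi=i * width) for i in range(1, n_semi + 1)]


def make_directions(sc: SemiCircleSpec, n_dirs: int) -> list[DirectionSpec]:
    """Equally spaced directions at midpoints of ``n_dirs`` sub-intervals.

    Midpoint placement keeps every direction strictly inside the sector,
    so adjacent sectors never share a direction.
    """
    if n_dirs < 1:
        raise ConfigError(f"n_dirs must be >= 1, got {n_dirs}")
    width = (sc.theta_hi - sc.theta_lo) / n_dirs
    return [DirectionSpec(semicircle=sc.index, j=j, phi=sc.theta_lo + (j - 0.5) * width) for j in range(1, n_dirs + 1)]


@lru_cache(maxsize=4096)
def direction_offsets(phi: float, r0: float, r1: float, step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer (drow, dcol) offsets for radii r0, r0+step, …, ≤ r1 along ``phi``.

    Consecutive offsets that round to the same pixel are collapsed,
    keeping the first.  Returns (radii, drows, dcols); cached because
    offsets depend only on the direction, never on the center.
    """
    if r0 < 1:
        raise ConfigError(f"r0 must be >= 1, got {r0}")
    if r1 <= r0:
        raise ConfigError(f"r1 must be > r0, got r0={r0}, r1={r1}")
    if step <= 0:
        raise ConfigError(f"step must be > 0, got {step}")
    n = int(math.floor((r1 - r0) / step + 1e-9)) + 1
    radii = r0 + step * np.arange(n)
    # +y points up: moving along +phi decreases the row index.
    dcols = round_half_up(radii * math.cos(phi))
    drows = round_half_up(-radii * math.sin(phi))
    keep = np.ones(n, dtype=bool)
    keep[1:] = (drows[1:] != drows[:-1]) | (dcols[1:] != dcols[:-1])
    return radii[keep], drows[keep], dcols[keep]


def sample_direction(
    img: GrayImage,
    center: PixelCoord,
    d: DirectionSpec,
    r0: float,
    r1: float,
    step: float = 1.0,
) -> RadialSamples:
    """Collect the in-bounds intensity samples along direction ``d``.

    The sample list is truncated at the first out-of-bounds coordinate
    (a straight ray never re-enters the raster).
    """
    h, w = img.shape
    if not (0 <= center.row < h and 0 <= center.col < w):
        raise InputError(f"center {center} outside image of shape {(h, w)}")
    radii, drows, dcols = direction_offsets(d.phi, r0, r1, step)
    rows = center.row + drows
    cols = center.col + dcols
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    k = len(ok) if ok.all() else int(np.argmin(ok))
    rows, cols, radii = rows[:k], cols[:k], radii[:k]
    values = img.intensities[rows, cols]
    coords = [PixelCoord(int(r), int(c)) for r, c in zip(rows, cols)]
    return RadialSamples(direction=d, radii=radii, coords=coords, values=values)
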