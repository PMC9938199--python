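"""Core pixel-wise hard-exudate classifier.

For every pixel, each of ``n_semi`` angular sectors casts ``n_dirs``
rays over radii [r0, r1].  A ray is *non-constant* when some
consecutive-sample intensity difference is a drop strictly larger than
Th1.  A sector with strictly more than Th2 non-constant rays is an
*entrance* sector, and a pixel is positive when its entrance sectors
satisfy the Th3 rule (by default: the longest circular run of entrance
sectors reaches Th3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InputError
from .geometry import (
    DirectionSpec,
    PixelCoord,
    RadialSamples,
    SemiCircleSpec,
    direction_offsets,
    make_directions,
    make_semicircles,
)
from .image_io import BinaryMask, GrayImage

logger = logging.getLogger(__name__)

_COMPARATORS = ("at_least", "strict_greater")


@dataclass
class DetectionConfig:
    """All tunables of the detector.

    Defaults reproduce the reference operating point: Th1 = 0.015,
    Th2 = 2, Th3 = 3, r0 = 4, r1 = 25.
    """

    th1: float = 0.015
    th2: int = 2
    th3: int = 3
    r0: float = 4.0
    r1: float = 25.0
    n_semi: int = 8
    n_dirs: int = 5
    step: float = 1.0
    require_consecutive: bool = True
    comparator_th3: str = "at_least"
    fill_radius: bool = False  # also fill an r0-radius disc around each positive pixel

    def __post_init__(self) -> None:
        if self.th1 <= 0:
            raise ConfigError(f"th1 must be > 0, got {self.th1}")
        if not 0 <= self.th2 < self.n_dirs:
            raise ConfigError(f"th2 must satisfy 0 <= th2 < n_dirs, got th2={self.th2}, n_dirs={self.n_dirs}")
        if not 1 <= self.th3 <= self.n_semi:
            raise ConfigError(f"th3 must satisfy 1 <= th3 <= n_semi, got th3={self.th3}, n_semi={self.n_semi}")
        if self.r0 < 1 or self.r1 <= self.r0:
            raise ConfigError(f"need r1 > r0 >= 1, got r0={self.r0}, r1={self.r1}")
        if self.step <= 0:
            raise ConfigError(f"step must be > 0, got {self.step}")
        if self.n_semi < 2:
            raise ConfigError(f"n_semi must be >= 2, got {self.n_semi}")
        if self.n_dirs < 1:
            raise ConfigError(f"n_dirs must be >= 1, got {self.n_dirs}")
        if self.comparator_th3 not in _COMPARATORS:
            raise ConfigError(f"comparator_th3 must be one of {_COMPARATORS}, got {self.comparator_th3!r}")


@dataclass
class DiffSeries:
    """Consecutive-sample intensity differences along one ray."""

    diffs: np.ndarray

    def __len__(self) -> int:
        return len(self.diffs)


@dataclass
class PixelVerdict:
    center: PixelCoord
    nonconstant_counts: list[int]
    entrance_flags: list[bool]
    is_he: bool


def radial_differences(s: RadialSamples) -> DiffSeries:
    """df[n] = values[n] − values[n−1]; empty when fewer than 2 samples."""
    v = np.asarray(s.values, dtype=np.float64)
    if len(v) < 2:
        return DiffSeries(diffs=np.empty(0))
    return DiffSeries(diffs=v[1:] - v[:-1])


def is_nonconstant(d: DiffSeries, th1: float) -> bool:
    """True iff some difference is a drop strictly exceeding th1 in magnitude."""
    return bool(np.any(d.diffs < -th1))


def semicircle_entrance(
    img: GrayImage, center: PixelCoord, sc: SemiCircleSpec, cfg: DetectionConfig
) -> tuple[int, bool]:
    """Count non-constant rays in sector ``sc``; entrance iff count > Th2."""
    from .geometry import sample_direction

    count = 0
    for d in make_directions(sc, cfg.n_dirs):
        samples = sample_direction(img, center, d, cfg.r0, cfg.r1, cfg.step)
        if is_nonconstant(radial_differences(samples), cfg.th1):
            count += 1
    return count, count > cfg.th2


def _longest_circular_run(flags: np.ndarray) -> np.ndarray:
    """Longest circular run of True along axis 0, capped at the axis length."""
    n = flags.shape[0]
    doubled = np.concatenate([flags, flags], axis=0).astype(np.int32)
    run = np.zeros(flags.shape[1:], dtype=np.int32)
    best = np.zeros(flags.shape[1:], dtype=np.int32)
    for k in range(2 * n):
        run = (run + 1) * doubled[k]
        np.maximum(best, run, out=best)
    return np.minimum(best, n)


def _th3_rule(entrance: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Apply the Th3 decision to an (n_semi, ...) boolean stack."""
    if cfg.require_consecutive:
        score = _longest_circular_run(entrance)
    else:
        score = entrance.sum(axis=0, dtype=np.int32)
    if cfg.comparator_th3 == "at_least":
        return score >= cfg.th3
    return score > cfg.th3


def classify_pixel(img: GrayImage, center: PixelCoord, cfg: DetectionConfig) -> PixelVerdict:
    """Full per-pixel verdict with per-sector diagnostics."""
    h, w = img.shape
    if not (0 <= center.row < h and 0 <= center.col < w):
        raise InputError(f"center {center} outside image of shape {(h, w)}")
    counts: list[int] = []
    flags: list[bool] = []
    for sc in make_semicircles(cfg.n_semi):
        count, entrance = semicircle_entrance(img, center, sc, cfg)
        counts.append(count)
        flags.append(entrance)
    is_he = bool(_th3_rule(np.asarray(flags, dtype=bool).reshape(-1, 1), cfg)[0])
    return PixelVerdict(center=center, nonconstant_counts=counts, entrance_flags=flags, is_he=is_he)


def _all_directions(cfg: DetectionConfig) -> list[list[DirectionSpec]]:
    return [make_directions(sc, cfg.n_dirs) for sc in make_semicircles(cfg.n_semi)]


def detect(img: GrayImage, cfg: DetectionConfig, exclusion: BinaryMask | None = None) -> BinaryMask:
    """Classify every pixel of ``img``; returns the positive-pixel mask.

    Vectorized over the raster: out-of-bounds ray samples are padded
    with NaN, whose comparisons are always False, which is equivalent to
    truncating each ray at the image border.  ``exclusion`` (e.g. an
    optic-disc mask) zeroes its pixels in the result.
    """
    h, w = img.shape
    if exclusion is not None and exclusion.shape != (h, w):
        raise InputError(f"exclusion mask shape {exclusion.shape} != image shape {(h, w)}")

    pad = int(np.ceil(cfg.r1)) + 1
    padded = np.full((h + 2 * pad, w + 2 * pad), np.nan)
    padded[pad : pad + h, pad : pad + w] = img.intensities
    rows = np.arange(h)[:, None] + pad
    cols = np.arange(w)[None, :] + pad

    entrance = np.empty((cfg.n_semi, h, w), dtype=bool)
    for i, dirs in enumerate(_all_directions(cfg)):
        counts = np.zeros((h, w), dtype=np.int16)
        for d in dirs:
            _, drows, dcols = direction_offsets(d.phi, cfg.r0, cfg.r1, cfg.step)
            vals = padded[rows[None, :, :] + drows[:, None, None], cols[None, :, :] + dcols[:, None, None]]
            diffs = vals[1:] - vals[:-1]
            counts += np.any(diffs < -cfg.th1, axis=0)
        entrance[i] = counts > cfg.th2

    positive = _th3_rule(entrance, cfg)
    if cfg.fill_radius:
        yy, xx = np.mgrid[-int(cfg.r0) : int(cfg.r0) + 1, -int(cfg.r0) : int(cfg.r0) + 1]
        structure = (yy * yy + xx * xx) <= cfg.r0 * cfg.r0
        positive = ndimage.binary_dilation(positive, structure=structure)
    if exclusion is not None:
        positive = positive & (exclusion.labels == 0)
    logger.info("detect: %d/%d pixels positive", int(positive.sum()), h * w)
    return BinaryMask(labels=positive.astype(np.uint8), meaning="lesion")
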