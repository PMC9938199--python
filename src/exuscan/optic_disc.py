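"""Optic-disc localization: quarter-sector ring candidacy + brightest-ray selection.

The disc is found by looking for circles of a known (user-supplied)
radius in an edge map: around a candidate center, each quarter of the
circle casts several rays and checks for an edge pixel near the expected
radius.  Centers whose four quarters all pass become candidates, and the
candidate whose brightest ray has the highest mean intensity wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InputError
from .geometry import PixelCoord, round_half_up
from .image_io import BinaryMask, GrayImage

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


@dataclass
class OdConfig:
    od_radius: int = 20
    median_kernel: int = 5
    edge_threshold: float = 0.1
    n_sectors_per_quarter: int = 8
    radius_tolerance: float = 2.0
    quarter_dir_threshold: float = 0.5
    dilation: float = 2.0
    stride: int = 2

    def __post_init__(self) -> None:
        if self.od_radius < 3:
            raise ConfigError(f"od_radius must be >= 3, got {self.od_radius}")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ConfigError(f"median_kernel must be odd and >= 3, got {self.median_kernel}")
        if not 0 < self.quarter_dir_threshold <= 1:
            raise ConfigError(f"quarter_dir_threshold must be in (0, 1], got {self.quarter_dir_threshold}")
        if self.n_sectors_per_quarter < 1:
            raise ConfigError("n_sectors_per_quarter must be >= 1")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")


@dataclass
class OpticDiscResult:
    center: PixelCoord
    radius: float
    brightest_direction_mean: float
    candidate_count: int

    def to_dict(self) -> dict:
        return {
            "center": {"row": self.center.row, "col": self.center.col},
            "radius": self.radius,
            "brightest_direction_mean": self.brightest_direction_mean,
            "candidate_count": self.candidate_count,
        }


def _ray_angles(cfg: OdConfig) -> list[list[float]]:
    """Sector-midpoint ray angles, grouped by quarter."""
    n = cfg.n_sectors_per_quarter
    quarters = []
    for q in range(4):
        lo = q * math.pi / 2.0
        quarters.append([lo + (s + 0.5) * (math.pi / 2.0) / n for s in range(n)])
    return quarters


def _ray_offsets(phi: float, radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapsed integer offsets along ``phi`` for the given radii."""
    dcols = round_half_up(radii * math.cos(phi))
    drows = round_half_up(-radii * math.sin(phi))
    keep = np.ones(len(radii), dtype=bool)
    keep[1:] = (drows[1:] != drows[:-1]) | (dcols[1:] != dcols[:-1])
    return drows[keep], dcols[keep]


def preprocess_for_od(img: GrayImage, cfg: OdConfig) -> tuple[GrayImage, BinaryMask]:
    """Median-filter the image, then threshold the Sobel gradient magnitude.

    The magnitude is normalized by 4·√2 (the response of the classic 3×3
    kernels to a unit step on both axes) so ``edge_threshold`` lives on
    a [0, 1] scale.
    """
    smoothed = ndimage.median_filter(img.intensities, size=cfg.median_kernel, mode="reflect")
    gx = ndimage.sobel(smoothed, axis=1, mode="reflect")
    gy = ndimage.sobel(smoothed, axis=0, mode="reflect")
    mag = np.hypot(gx, gy) / (4.0 * _SQRT2)
    edges = BinaryMask(labels=(mag > cfg.edge_threshold).astype(np.uint8), meaning="optic_disc")
    return GrayImage(intensities=np.clip(smoothed, 0.0, 1.0), channel_tag=img.channel_tag), edges


def _band_radii(cfg: OdConfig) -> np.ndarray:
    lo = max(1.0, cfg.od_radius - cfg.radius_tolerance)
    return np.arange(lo, cfg.od_radius + cfg.radius_tolerance + 0.5)


def quarter_candidacy(edges: BinaryMask, center: PixelCoord, cfg: OdConfig) -> tuple[list[bool], bool]:
    """Per-quarter ray-hit test at one center.

    A ray hits when any edge pixel lies on it within
    [od_radius − tol, od_radius + tol]; a quarter passes when its hit
    fraction reaches ``quarter_dir_threshold``; the center is a
    candidate when all four quarters pass.
    """
    h, w = edges.shape
    if not (0 <= center.row < h and 0 <= center.col < w):
        raise InputError(f"center {center} outside image of shape {(h, w)}")
    radii = _band_radii(cfg)
    quarters_ok: list[bool] = []
    for angles in _ray_angles(cfg):
        hits = 0
        for phi in angles:
            drows, dcols = _ray_offsets(phi, radii)
            rr = center.row + drows
            cc = center.col + dcols
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            if ok.any() and edges.labels[rr[ok], cc[ok]].any():
                hits += 1
        quarters_ok.append(hits / len(angles) >= cfg.quarter_dir_threshold)
    return quarters_ok, all(quarters_ok)


def _candidate_map(edges: BinaryMask, cfg: OdConfig) -> np.ndarray:
    """Vectorized quarter candidacy for every center pixel."""
    h, w = edges.shape
    radii = _band_radii(cfg)
    pad = int(cfg.od_radius + cfg.radius_tolerance) + 1
    epad = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    epad[pad : pad + h, pad : pad + w] = edges.labels.astype(bool)
    rows = np.arange(h)[:, None] + pad
    cols = np.arange(w)[None, :] + pad

    candidate = np.ones((h, w), dtype=bool)
    for angles in _ray_angles(cfg):
        hit_count = np.zeros((h, w), dtype=np.int16)
        for phi in angles:
            drows, dcols = _ray_offsets(phi, radii)
            hit = np.zeros((h, w), dtype=bool)
            for dr, dc in zip(drows, dcols):
                hit |= epad[rows + dr, cols + dc]
            hit_count += hit
        candidate &= hit_count / len(angles) >= cfg.quarter_dir_threshold
    return candidate


def _brightest_ray_mean(img: GrayImage, center: PixelCoord, cfg: OdConfig) -> float:
    """Max over rays of the mean intensity over radii [0, od_radius]."""
    h, w = img.shape
    radii = np.arange(0.0, cfg.od_radius + 0.5)
    best = -1.0
    for angles in _ray_angles(cfg):
        for phi in angles:
            drows, dcols = _ray_offsets(phi, radii)
            rr = center.row + drows
            cc = center.col + dcols
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            if not ok.any():
                continue
            best = max(best, float(img.intensities[rr[ok], cc[ok]].mean()))
    return best


def select_optic_disc(img: GrayImage, edges: BinaryMask, cfg: OdConfig) -> OpticDiscResult | None:
    """Pick the candidate region whose brightest ray has the highest mean.

    Candidate centers form connected blobs around plausible disc
    positions.  Each blob is scored by the maximum brightest-ray mean
    over its pixels (subsampled at ``stride`` for speed); the winning
    blob's centroid is returned as the disc center.  Ties break toward
    the blob encountered first in row-major order, which makes the
    result deterministic.  Returns None when no center qualifies.
    """
    if img.shape != edges.shape:
        raise InputError(f"image shape {img.shape} != edge-map shape {edges.shape}")
    cand = _candidate_map(edges, cfg)
    if not cand.any():
        return None
    labeled, n_blobs = ndimage.label(cand)
    best_score, best_blob = -np.inf, 0
    for b in range(1, n_blobs + 1):
        pts = np.argwhere(labeled == b)[:: cfg.stride]
        score = max(_brightest_ray_mean(img, PixelCoord(int(r), int(c)), cfg) for r, c in pts)
        if score > best_score:
            best_score, best_blob = score, b
    pts = np.argwhere(labeled == best_blob)
    cr, cc = pts.mean(axis=0)
    h, w = img.shape
    center = PixelCoord(min(h - 1, max(0, int(round_half_up(cr)))), min(w - 1, max(0, int(round_half_up(cc)))))
    logger.info("optic disc at %s, score %.4f, %d candidate pixels in %d blobs", center, best_score,
                int(cand.sum()), n_blobs)
    return OpticDiscResult(
        center=center,
        radius=float(cfg.od_radius),
        brightest_direction_mean=best_score,
        candidate_count=int(cand.sum()),
    )


def od_exclusion_mask(result: OpticDiscResult, shape: tuple[int, int], cfg: OdConfig) -> BinaryMask:
    """Filled disc of radius od_radius + dilation at the detected center, clipped."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = cfg.od_radius + cfg.dilation
    mask = (yy - result.center.row) ** 2 + (xx - result.center.col) ** 2 <= r * r
    return BinaryMask(labels=mask.astype(np.uint8), meaning="optic_disc")
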