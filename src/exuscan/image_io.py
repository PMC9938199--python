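"""Image loading, working-channel extraction, normalization, and binary masks.

Coordinate convention used throughout the package: row-major rasters,
0-based indices, pixel centers at integer coordinates.  Angle 0 points
along +x (increasing column); angles increase counter-clockwise with +y
pointing up, i.e. toward decreasing row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: Channel tags accepted by :func:`extract_channel`.
SUPPORTED_CHANNELS = ("green", "red", "blue", "L", "Y", "S")

# sRGB -> XYZ (D65) matrix, applied to *linear* RGB: gamma companding is
# deliberately ignored (only relative contrast matters downstream).
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65_WHITE = _RGB2XYZ.sum(axis=1)  # XYZ of RGB=(1,1,1)


@dataclass
class RgbImage:
    """8-bit RGB raster (H, W, 3) with its source identifier."""

    pixels: np.ndarray
    path: str = "<memory>"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError(f"RgbImage requires an (H, W, 3) raster, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InputError("RgbImage must have H >= 1 and W >= 1")
        if self.pixels.dtype != np.uint8:
            raise InputError(f"RgbImage pixels must be uint8, got {self.pixels.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class GrayImage:
    """Single-channel intensity raster with values in [0, 1].

    ``channel_tag`` records which channel the intensities came from.
    """

    intensities: np.ndarray
    channel_tag: str = "green"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise InputError(f"GrayImage requires a 2-D raster, got shape {self.intensities.shape}")
        lo, hi = float(self.intensities.min(initial=0.0)), float(self.intensities.max(initial=0.0))
        if self.intensities.size and (lo < -1e-12 or hi > 1 + 1e-12):
            raise InputError(f"GrayImage intensities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class BinaryMask:
    """H×W raster of {0, 1} labels."""

    labels: np.ndarray
    meaning: str = "lesion"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise InputError(f"BinaryMask requires a 2-D raster, got shape {arr.shape}")
        self.labels = (arr != 0).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self) -> int:
        return int(self.labels.sum())


def load_rgb(path: str | Path) -> RgbImage:
    """Load an image file as an 8-bit RGB raster.

    Single-channel inputs are replicated to three channels (with a
    warning); 16-bit inputs are rescaled to the 8-bit range by dividing
    by 257 and rounding half-up.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by backend
        raise InputError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = np.floor(arr / 257.0 + 0.5).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise InputError(f"unsupported image dtype {arr.dtype} in {path}")
    if arr.ndim == 2:
        logger.warning("single-channel input %s replicated to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]  # drop alpha
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"cannot interpret {path} with shape {arr.shape} as RGB")
    return RgbImage(pixels=arr, path=str(path))


def extract_channel(img: RgbImage, channel_tag: str = "green") -> GrayImage:
    """Extract a working channel, un-normalized, scaled to [0, 1].

    ``green``/``red``/``blue`` are plain 8-bit channels divided by 255.
    ``Y`` is the luminance row of the linear-RGB→XYZ matrix, ``L`` the
    CIE lightness derived from that Y (divided by 100), and ``S`` the
    HSI saturation 1 − 3·min(R,G,B)/(R+G+B).
    """
    if channel_tag not in SUPPORTED_CHANNELS:
        raise ConfigError(f"unknown channel tag {channel_tag!r}; supported: {', '.join(SUPPORTED_CHANNELS)}")
    rgb = img.pixels.astype(np.float64) / 255.0
    if channel_tag in ("red", "green", "blue"):
        idx = ("red", "green", "blue").index(channel_tag)
        values = rgb[:, :, idx]
    elif channel_tag == "Y":
        values = rgb @ _RGB2XYZ[1]  # Y of white is exactly 1
    elif channel_tag == "L":
        y = (rgb @ _RGB2XYZ[1]) / _D65_WHITE[1]
        eps = (6.0 / 29.0) ** 3
        f = np.where(y > eps, np.cbrt(y), y / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
        values = (116.0 * f - 16.0) / 100.0
        values = np.clip(values, 0.0, 1.0)
    else:  # S of HSI
        total = rgb.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = 1.0 - 3.0 * rgb.min(axis=2) / total
        values = np.where(total > 0, values, 0.0)
        values = np.clip(values, 0.0, 1.0)
    return GrayImage(intensities=values, channel_tag=channel_tag)


def normalize(img: GrayImage) -> GrayImage:
    """Min–max normalize to [0, 1]; a constant image maps to all zeros."""
    arr = img.intensities
    lo = float(arr.min())
    hi = float(arr.max())
    if hi - lo <= 0.0:
        logger.warning("normalize: constant image (value %g); returning all zeros", lo)
        out = np.zeros_like(arr)
    else:
        out = (arr - lo) / (hi - lo)
    return GrayImage(intensities=out, channel_tag=img.channel_tag)


def read_mask(path: str | Path, companion_shape: tuple[int, int] | None = None, meaning: str = "lesion") -> BinaryMask:
    """Read a binary mask from a PNG; any nonzero pixel becomes 1."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot read mask file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[:, :, :3].max(axis=2)
    if companion_shape is not None and tuple(arr.shape) != tuple(companion_shape):
        raise InputError(f"mask {path} has shape {arr.shape}, expected {tuple(companion_shape)}")
    return BinaryMask(labels=(arr != 0).astype(np.uint8), meaning=meaning)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel PNG with 0/255 values."""
    iio.imwrite(Path(path), (mask.labels * np.uint8(255)))
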