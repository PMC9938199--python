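"""Seeded generator of fundus-like test scenes with exact ground truth.

A scene is a smooth bright-ish background, dark curvilinear vessels,
bright sharp-margin lesions (discs, ellipses, or star-convex blobs), and
one bright circular disc of known radius, plus paired lesion/disc masks.
Everything is deterministic given the seed; each component draws from
its own sub-stream so toggling one component does not shift the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ConfigError, InputError
from .geometry import PixelCoord
from .image_io import BinaryMask, RgbImage

_LESION_SHAPES = ("disc", "ellipse", "star_convex")


@dataclass
class SceneSpec:
    seed: int = 0
    size: tuple[int, int] = (256, 256)
    background_base: float = 0.45
    background_amplitude: float = 0.08
    n_lesions: int = 6
    lesion_radius_range: tuple[float, float] = (5.0, 20.0)
    lesion_contrast_range: tuple[float, float] = (0.15, 0.3)
    lesion_shape: str = "star_convex"
    lesion_feather: float = 0.0
    n_vessels: int = 3
    vessel_darkness: float = 0.18
    od_center: tuple[int, int] | None = None
    od_radius: int | None = None  # None -> round(0.08 * W)
    od_contrast: float = 0.35
    od_feather: float = 2.0
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        h, w = self.size
        rmin, rmax = self.lesion_radius_range
        if rmin < 2:
            raise ConfigError(f"lesion radii must be >= 2, got min {rmin}")
        if rmax < rmin:
            raise ConfigError("lesion_radius_range must be (min, max) with max >= min")
        if self.lesion_contrast_range[0] <= 0:
            raise ConfigError("lesion contrast must be > 0")
        if 2 * rmax + 4 > min(h, w):
            raise ConfigError(f"largest lesion (radius {rmax}) does not fit in a {h}x{w} image")
        if self.lesion_shape not in _LESION_SHAPES:
            raise ConfigError(f"lesion_shape must be one of {_LESION_SHAPES}, got {self.lesion_shape!r}")

    def resolved_od_radius(self) -> int:
        return self.od_radius if self.od_radius is not None else round(0.08 * self.size[1])


@dataclass
class SyntheticScene:
    spec: SceneSpec
    image: RgbImage
    he_mask: BinaryMask
    od_mask: BinaryMask
    od_center: PixelCoord
    od_radius: int
    lesion_records: list[dict] = field(default_factory=list)


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([seed, component])


def _background(spec: SceneSpec) -> np.ndarray:
    h, w = spec.size
    rng = _rng(spec.seed, 0)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    bg = np.zeros((h, w))
    for _ in range(3):
        wavelength = rng.uniform(0.6, 1.6) * min(h, w)
        angle = rng.uniform(0.0, 2 * math.pi)
        phase = rng.uniform(0.0, 2 * math.pi)
        amp = rng.uniform(0.5, 1.0)
        k = 2 * math.pi / wavelength
        bg += amp * np.cos(k * (xx * math.cos(angle) + yy * math.sin(angle)) + phase)
    peak = np.abs(bg).max()
    if peak > 0:
        bg *= spec.background_amplitude / peak
    return spec.background_base + bg


def _vessel_mask(spec: SceneSpec) -> np.ndarray:
    h, w = spec.size
    rng = _rng(spec.seed, 1)
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_vessels):
        side = rng.integers(0, 4)
        if side == 0:
            r, c, heading = 0.0, rng.uniform(0, w - 1), -math.pi / 2
        elif side == 1:
            r, c, heading = float(h - 1), rng.uniform(0, w - 1), math.pi / 2
        elif side == 2:
            r, c, heading = rng.uniform(0, h - 1), 0.0, 0.0
        else:
            r, c, heading = rng.uniform(0, h - 1), float(w - 1), math.pi
        heading += rng.uniform(-0.4, 0.4)
        width = int(rng.integers(2, 5))
        path = np.zeros((h, w), dtype=bool)
        for _ in range(3 * max(h, w)):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            path[ri, ci] = True
            heading += rng.normal(0.0, 0.08)
            c += math.cos(heading)
            r -= math.sin(heading)
        radius = max(1, width // 2)
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        mask |= ndimage.binary_dilation(path, structure=(yy * yy + xx * xx) <= radius * radius)
    return mask


def _lesion_radius_fn(spec: SceneSpec, rng: np.random.Generator) -> dict:
    """Draw shape parameters; the radius function stays inside the configured range."""
    rmin, rmax = spec.lesion_radius_range
    if spec.lesion_shape == "ellipse":
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, rmax)
        return {"shape": "ellipse", "a": a, "b": b, "orientation": rng.uniform(0, math.pi)}
    mean_radius = rng.uniform(rmin, rmax)
    if spec.lesion_shape == "disc":
        return {"shape": "disc", "mean_radius": mean_radius, "amplitudes": [0.0] * 4, "phases": [0.0] * 4}
    # star-convex: rho(theta) = mean * (1 + sum a_k cos(k theta + psi_k)),
    # with sum |a_k| bounded so rho never leaves [rmin, rmax]
    budget = min(0.3, (rmax - mean_radius) / mean_radius, (mean_radius - rmin) / mean_radius)
    raw = rng.uniform(-1.0, 1.0, size=4)
    total = np.abs(raw).sum()
    scale = budget * rng.uniform(0.4, 1.0) / total if total > 0 else 0.0
    return {
        "shape": "star_convex",
        "mean_radius": mean_radius,
        "amplitudes": (raw * scale).tolist(),
        "phases": rng.uniform(0, 2 * math.pi, size=4).tolist(),
    }


def _max_radius(params: dict) -> float:
    if params["shape"] == "ellipse":
        return max(params["a"], params["b"])
    return params["mean_radius"] * (1 + float(np.sum(np.abs(params["amplitudes"]))))


def _rho(params: dict, theta: np.ndarray) -> np.ndarray:
    if params["shape"] == "ellipse":
        a, b = params["a"], params["b"]
        beta = theta - params["orientation"]
        return a * b / np.sqrt((b * np.cos(beta)) ** 2 + (a * np.sin(beta)) ** 2)
    rho = np.full_like(theta, float(params["mean_radius"]))
    for k, (amp, psi) in enumerate(zip(params["amplitudes"], params["phases"]), start=1):
        rho += params["mean_radius"] * amp * np.cos(k * theta + psi)
    return rho


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Build a deterministic scene with exact lesion and disc masks."""
    h, w = spec.size
    background = _background(spec)

    vessels = _vessel_mask(spec)
    field_ = background - spec.vessel_darkness * vessels

    # optic disc
    od_rng = _rng(spec.seed, 2)
    od_radius = spec.resolved_od_radius()
    margin = od_radius + spec.od_feather + 3
    if spec.od_center is not None:
        od_r, od_c = spec.od_center
    else:
        if 2 * margin >= min(h, w):
            raise ConfigError(f"optic disc of radius {od_radius} does not fit in a {h}x{w} image")
        od_r = int(od_rng.uniform(margin, h - 1 - margin))
        od_c = int(od_rng.uniform(margin, w - 1 - margin))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    od_dist = np.hypot(yy - od_r, xx - od_c)
    if spec.od_feather > 0:
        profile = np.clip((od_radius + spec.od_feather / 2 - od_dist) / spec.od_feather, 0.0, 1.0)
    else:
        profile = (od_dist <= od_radius).astype(np.float64)
    field_ = field_ + spec.od_contrast * profile
    od_mask = BinaryMask(labels=(od_dist <= od_radius).astype(np.uint8), meaning="optic_disc")

    # lesions
    lesion_rng = _rng(spec.seed, 3)
    he = np.zeros((h, w), dtype=bool)
    records: list[dict] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, max radius)
    for n in range(spec.n_lesions):
        params = _lesion_radius_fn(spec, lesion_rng)
        rmax_n = _max_radius(params)
        for _ in range(300):
            cr = lesion_rng.uniform(rmax_n + 2, h - 1 - rmax_n - 2)
            cc = lesion_rng.uniform(rmax_n + 2, w - 1 - rmax_n - 2)
            if math.hypot(cr - od_r, cc - od_c) <= od_radius + spec.od_feather + rmax_n + 3:
                continue
            if any(math.hypot(cr - pr, cc - pc) <= rmax_n + prm + 2 for pr, pc, prm in placed):
                continue
            break
        else:
            raise ConfigError(f"could not place lesion {n + 1} of {spec.n_lesions} without overlap")
        contrast = lesion_rng.uniform(*spec.lesion_contrast_range)
        box = int(math.ceil(rmax_n)) + 2
        r0, r1 = max(0, int(cr) - box), min(h, int(cr) + box + 1)
        c0, c1 = max(0, int(cc) - box), min(w, int(cc) + box + 1)
        ly, lx = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dist = np.hypot(ly - cr, lx - cc)
        theta = np.arctan2(-(ly - cr), lx - cc)  # +y up convention
        rho = _rho(params, theta)
        inside = dist <= rho
        if spec.lesion_feather > 0:
            bump = contrast * np.clip((rho + spec.lesion_feather / 2 - dist) / spec.lesion_feather, 0.0, 1.0)
            field_[r0:r1, c0:c1] += bump
        else:
            # hard-edged lesions replace whatever is underneath (vessels
            # included) with background + contrast, so the margin drop is
            # never diluted by a vessel crossing the boundary
            window = field_[r0:r1, c0:c1]
            field_[r0:r1, c0:c1] = np.where(inside, background[r0:r1, c0:c1] + contrast, window)
        he[r0:r1, c0:c1] |= inside
        placed.append((cr, cc, rmax_n))
        records.append(
            {"center": [float(cr), float(cc)], "contrast": float(contrast), **params}
        )

    he_mask = BinaryMask(labels=he.astype(np.uint8), meaning="lesion")

    # noise + 8-bit RGB composition (lesions live in the green channel)
    noise_rng = _rng(spec.seed, 4)
    green = field_.copy()
    if spec.noise_sigma > 0:
        green = green + noise_rng.normal(0.0, spec.noise_sigma, size=(h, w))
    green = np.clip(green, 0.0, 1.0)
    red = np.clip(0.35 + 0.5 * green, 0.0, 1.0)
    blue = np.clip(0.05 + 0.25 * green, 0.0, 1.0)
    pixels = np.stack(
        [np.floor(red * 255 + 0.5), np.floor(green * 255 + 0.5), np.floor(blue * 255 + 0.5)], axis=-1
    ).astype(np.uint8)

    scene = SyntheticScene(
        spec=spec,
        image=RgbImage(pixels=pixels, path=f"<synthetic seed={spec.seed}>"),
        he_mask=he_mask,
        od_mask=od_mask,
        od_center=PixelCoord(od_r, od_c),
        od_radius=od_radius,
        lesion_records=records,
    )
    if spec.noise_sigma == 0 and spec.lesion_feather == 0 and spec.n_lesions > 0 and he_mask.count():
        min_drop = min_margin_drop(scene)
        floor = spec.lesion_contrast_range[0] - 2.0 / 255.0
        if min_drop < min(floor, 0.015):
            raise ConfigError(f"generator contract violated: lesion margin drop {min_drop:.4f} too small")
    return scene


def min_margin_drop(scene: SyntheticScene) -> float:
    """Smallest green-channel step from a lesion pixel to a 4-neighbor outside it."""
    green = scene.image.pixels[:, :, 1].astype(np.float64) / 255.0
    he = scene.he_mask.labels.astype(bool)
    drops: list[float] = []
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        inner = he & ~np.roll(he, (-dr, -dc), axis=(0, 1))
        # exclude pairs wrapping around the image edge
        if dr == 1:
            inner[-1, :] = False
        elif dr == -1:
            inner[0, :] = False
        elif dc == 1:
            inner[:, -1] = False
        else:
            inner[:, 0] = False
        outer = np.roll(green, (-dr, -dc), axis=(0, 1))
        if inner.any():
            drops.append(float((green - outer)[inner].min()))
    return min(drops) if drops else math.inf


def scene_to_disk(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write image.png, he_mask.png, od_mask.png, and scene.json into ``out_dir``."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc
    paths = {
        "image": out / "image.png",
        "he_mask": out / "he_mask.png",
        "od_mask": out / "od_mask.png",
        "scene": out / "scene.json",
    }
    iio.imwrite(paths["image"], scene.image.pixels)
    iio.imwrite(paths["he_mask"], scene.he_mask.labels * np.uint8(255))
    iio.imwrite(paths["od_mask"], scene.od_mask.labels * np.uint8(255))
    record = {
        "spec": asdict(scene.spec),
        "od_center": [scene.od_center.row, scene.od_center.col],
        "od_radius": scene.od_radius,
        "lesion_records": scene.lesion_records,
    }
    paths["scene"].write_text(json.dumps(record, indent=2))
    return paths


def scene_spec_from_json(path: str | Path) -> SceneSpec:
    """Rebuild a SceneSpec from a scene.json written by :func:`scene_to_disk`."""
    record = json.loads(Path(path).read_text())
    raw = record["spec"]
    raw["size"] = tuple(raw["size"])
    raw["lesion_radius_range"] = tuple(raw["lesion_radius_range"])
    raw["lesion_contrast_range"] = tuple(raw["lesion_contrast_range"])
    if raw.get("od_center") is not None:
        raw["od_center"] = tuple(raw["od_center"])
    return SceneSpec(**raw)
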