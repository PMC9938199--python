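"""Patch-based IoU evaluation of detection masks.

The image is tiled into non-overlapping square patches (ragged
right/bottom patches kept at reduced size).  A patch containing ground
truth counts as a true positive when the in-patch IoU between ground
truth and prediction exceeds the threshold; a ground-truth-free patch
counts as a false positive when the prediction puts any pixel in it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .image_io import BinaryMask


@dataclass
class EvalConfig:
    patch_size: int = 32
    iou_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.patch_size < 4:
            raise ConfigError(f"patch_size must be >= 4, got {self.patch_size}")
        if not 0 < self.iou_threshold <= 1:
            raise ConfigError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")


@dataclass
class PatchResult:
    window: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    gt_positive: bool
    pred_positive: bool
    iou: float


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    patch_size: int
    iou_threshold: float
    per_patch: list[PatchResult] = field(default_factory=list)

    def to_dict(self, include_patches: bool = False) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "patch_size": self.patch_size,
            "iou_threshold": self.iou_threshold,
        }
        if include_patches:
            d["per_patch"] = [
                {
                    "window": list(p.window),
                    "gt_positive": p.gt_positive,
                    "pred_positive": p.pred_positive,
                    "iou": p.iou,
                }
                for p in self.per_patch
            ]
        return d

    def to_json(self, include_patches: bool = False) -> str:
        return json.dumps(self.to_dict(include_patches), indent=2)

    def to_tsv_line(self) -> str:
        def fmt(x: float | None) -> str:
            return "NA" if x is None else f"{x:.6f}"

        return "\t".join(
            str(v) for v in (self.tp, self.fp, self.tn, self.fn, fmt(self.sensitivity), fmt(self.specificity))
        )

    TSV_HEADER = "tp\tfp\ttn\tfn\tsensitivity\tspecificity"


def patchify(shape: tuple[int, int], patch_size: int) -> list[tuple[int, int, int, int]]:
    """Non-overlapping tiling from the origin; each window is (r0, r1, c0, c1)."""
    if patch_size < 4:
        raise ConfigError(f"patch_size must be >= 4, got {patch_size}")
    h, w = shape
    return [
        (r, min(r + patch_size, h), c, min(c + patch_size, w))
        for r in range(0, h, patch_size)
        for c in range(0, w, patch_size)
    ]


def patch_iou(gt_patch: np.ndarray, pred_patch: np.ndarray) -> float:
    """|gt ∧ pred| / |gt ∨ pred|; 1.0 when both windows are empty."""
    gt = np.asarray(gt_patch, dtype=bool)
    pred = np.asarray(pred_patch, dtype=bool)
    union = int((gt | pred).sum())
    if union == 0:
        return 1.0
    return int((gt & pred).sum()) / union


def evaluate(gt: BinaryMask, pred: BinaryMask, cfg: EvalConfig | None = None) -> EvalReport:
    """Score a prediction mask against ground truth, patch by patch."""
    cfg = cfg or EvalConfig()
    if gt.shape != pred.shape:
        raise InputError(f"ground-truth shape {gt.shape} != prediction shape {pred.shape}")
    tp = fp = tn = fn = 0
    per_patch: list[PatchResult] = []
    for r0, r1, c0, c1 in patchify(gt.shape, cfg.patch_size):
        g = gt.labels[r0:r1, c0:c1]
        p = pred.labels[r0:r1, c0:c1]
        gt_pos = bool(g.any())
        pred_pos = bool(p.any())
        iou = patch_iou(g, p)
        if gt_pos:
            if iou > cfg.iou_threshold:
                tp += 1
            else:
                fn += 1
        else:
            if pred_pos:
                fp += 1
            else:
                tn += 1
        per_patch.append(PatchResult(window=(r0, r1, c0, c1), gt_positive=gt_pos, pred_positive=pred_pos, iou=iou))
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return EvalReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sensitivity,
        specificity=specificity,
        patch_size=cfg.patch_size,
        iou_threshold=cfg.iou_threshold,
        per_patch=per_patch,
    )
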