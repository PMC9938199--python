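"""Independent reference implementations used as test oracles.

Everything here is written as straight-line loops, deliberately sharing
no code with the package (only the contractual definitions: half-up
rounding, midpoint direction angles, duplicate collapse, border
truncation).
"""

from __future__ import annotations

import math

import numpy as np


def reference_offsets(phi: float, r0: float, r1: float, step: float) -> list[tuple[int, int]]:
    """(drow, dcol) per radius, consecutive duplicates collapsed."""
    n_steps = int(math.floor((r1 - r0) / step + 1e-9)) + 1
    offs: list[tuple[int, int]] = []
    prev = None
    for k in range(n_steps):
        r = r0 + k * step
        dc = math.floor(r * math.cos(phi) + 0.5)
        dr = math.floor(-r * math.sin(phi) + 0.5)
        if (dr, dc) != prev:
            offs.append((dr, dc))
            prev = (dr, dc)
    return offs


def reference_direction_angles(n_semi: int, n_dirs: int) -> list[list[float]]:
    """Per-sector midpoint direction angles."""
    sector_width = 2.0 * math.pi / n_semi
    out = []
    for i in range(n_semi):
        lo = i * sector_width
        out.append([lo + (j + 0.5) * sector_width / n_dirs for j in range(n_dirs)])
    return out


def longest_circular_run_bruteforce(flags: list[bool]) -> int:
    """Max circular run of True, by trying every start position."""
    n = len(flags)
    if all(flags):
        return n
    best = 0
    for s in range(n):
        k = 0
        while k < n and flags[(s + k) % n]:
            k += 1
        best = max(best, k)
    return best


def naive_classify(
    values: list[list[float]],
    row: int,
    col: int,
    all_offsets: list[list[list[tuple[int, int]]]],
    th1: float,
    th2: int,
    th3: int,
    require_consecutive: bool,
    comparator: str,
) -> bool:
    """Literal per-direction, per-radius scan at one pixel."""
    h = len(values)
    w = len(values[0])
    flags: list[bool] = []
    for sector in all_offsets:
        count = 0
        for offs in sector:
            prev = None
            for dr, dc in offs:
                rr = row + dr
                cc = col + dc
                if rr < 0 or rr >= h or cc < 0 or cc >= w:
                    break
                v = values[rr][cc]
                if prev is not None and v - prev < -th1:
                    count += 1
                    break
                prev = v
        flags.append(count > th2)
    if require_consecutive:
        score = longest_circular_run_bruteforce(flags)
    else:
        score = sum(flags)
    return score >= th3 if comparator == "at_least" else score > th3


def naive_detect(
    intensities: np.ndarray,
    th1: float = 0.015,
    th2: int = 2,
    th3: int = 3,
    r0: float = 4.0,
    r1: float = 25.0,
    n_semi: int = 8,
    n_dirs: int = 5,
    step: float = 1.0,
    require_consecutive: bool = True,
    comparator: str = "at_least",
) -> np.ndarray:
    """Triple-loop reference detector (per pixel, per direction, per radius)."""
    all_offsets = [
        [reference_offsets(phi, r0, r1, step) for phi in sector]
        for sector in reference_direction_angles(n_semi, n_dirs)
    ]
    values = intensities.tolist()
    h, w = intensities.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if naive_classify(values, r, c, all_offsets, th1, th2, th3, require_consecutive, comparator):
                out[r, c] = 1
    return out
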