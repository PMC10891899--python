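"""Binary-mask morphological refinement.

Predicted vein masks are cleaned with erosion/dilation recipes built from
three structuring-element shapes:

* ``disk(r)`` — lattice points with dx^2 + dy^2 <= r^2;
* ``line(L, angle)`` — L collinear pixels through the anchor (180 deg and
  0 deg are both horizontal);
* ``square(s)`` — s x s block anchored at offset ceil(s/2) - 1.

Per-method presets: after PCA, erode with disk(4) then dilate with a
horizontal line(5); after Folded PCA, erode with disk(4) then dilate with
square(2); after WaLuMI band selection, erode coarse-to-fine with disk(4)
and disk(2), then dilate with disk(2).  One iteration per step by default.

Pixels outside the image count as 0 for both operations, so erosion is
anti-extensive and dilation extensive away from border truncation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "MorphRecipe",
    "make_se",
    "erode",
    "dilate",
    "refine",
    "PRESETS",
]


@dataclass(frozen=True)
class StructuringElement:
    shape: str
    params: tuple
    footprint: np.ndarray  # odd-sized boolean array, anchor at the center

    def __post_init__(self) -> None:
        fp = self.footprint
        if fp.ndim != 2 or fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
            raise ValueError("footprint must be odd-sized in both axes")
        if not fp.any():
            raise ValueError("footprint must be non-empty")
        if not fp[fp.shape[0] // 2, fp.shape[1] // 2]:
            raise ValueError("footprint must contain its anchor")

    def reflected(self) -> "StructuringElement":
        return StructuringElement(self.shape, self.params, self.footprint[::-1, ::-1])


def _center_embed(fp: np.ndarray, anchor: tuple[int, int]) -> np.ndarray:
    """Re-embed a footprint in an odd-sized array with the anchor at center."""
    ar, ac = anchor
    mr = max(ar, fp.shape[0] - 1 - ar)
    mc = max(ac, fp.shape[1] - 1 - ac)
    out = np.zeros((2 * mr + 1, 2 * mc + 1), dtype=bool)
    out[mr - ar : mr - ar + fp.shape[0], mc - ac : mc - ac + fp.shape[1]] = fp
    return out


def make_se(shape: str, *params) -> StructuringElement:
    """Build a structuring element: disk(r), line(length, angle_deg), square(s)."""
    if shape == "disk":
        (r,) = params
        r = int(r)
        if r < 0:
            raise ValueError("disk radius must be >= 0")
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        fp = dy * dy + dx * dx <= r * r
        return StructuringElement("disk", (r,), fp)
    if shape == "line":
        length, angle = params
        length = int(length)
        if length < 1:
            raise ValueError("line length must be >= 1")
        theta = np.deg2rad(float(angle))
        # symmetric integer offsets along the angle; 0 and 180 deg coincide
        ts = np.arange(length) - (length - 1) / 2.0
        cols = np.round(ts * np.cos(theta)).astype(int)
        rows = np.round(-ts * np.sin(theta)).astype(int)
        mr, mc = np.abs(rows).max(), np.abs(cols).max()
        fp = np.zeros((2 * mr + 1, 2 * mc + 1), dtype=bool)
        fp[rows + mr, cols + mc] = True
        fp[mr, mc] = True
        return StructuringElement("line", (length, float(angle)), fp)
    if shape == "square":
        (s,) = params
        s = int(s)
        if s < 1:
            raise ValueError("square side must be >= 1")
        anchor = -(-s // 2) - 1  # ceil(s/2) - 1
        fp = _center_embed(np.ones((s, s), dtype=bool), (anchor, anchor))
        return StructuringElement("square", (s,), fp)
    raise ValueError(f"unknown structuring element shape {shape!r}")


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def erode(mask: np.ndarray, se: StructuringElement, iterations: int = 1) -> np.ndarray:
    """Binary erosion; outside-image pixels are 0 (anti-extensive)."""
    out = ndimage.binary_erosion(
        _check_mask(mask), structure=se.footprint, iterations=iterations, border_value=0
    )
    return out.astype(np.uint8)


def dilate(mask: np.ndarray, se: StructuringElement, iterations: int = 1) -> np.ndarray:
    """Binary dilation; outside-image pixels are 0 (extensive in-frame)."""
    out = ndimage.binary_dilation(
        _check_mask(mask), structure=se.footprint, iterations=iterations, border_value=0
    )
    return out.astype(np.uint8)


@dataclass(frozen=True)
class MorphRecipe:
    """Ordered (operation, structuring element, iterations) steps."""

    steps: tuple[tuple[str, StructuringElement, int], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("recipe must have at least one step")
        for op, _se, it in self.steps:
            if op not in ("erode", "dilate"):
                raise ValueError(f"unknown operation {op!r}")
            if it < 1:
                raise ValueError("iterations must be >= 1")

    def apply(self, mask: np.ndarray) -> np.ndarray:
        out = np.asarray(mask)
        for op, se, it in self.steps:
            out = erode(out, se, it) if op == "erode" else dilate(out, se, it)
        return out


def _preset(name: str) -> MorphRecipe:
    if name == "pca":
        steps = (("erode", make_se("disk", 4), 1), ("dilate", make_se("line", 5, 180), 1))
    elif name == "fpca":
        steps = (("erode", make_se("disk", 4), 1), ("dilate", make_se("square", 2), 1))
    elif name == "walumi":
        steps = (
            ("erode", make_se("disk", 4), 1),
            ("erode", make_se("disk", 2), 1),
            ("dilate", make_se("disk", 2), 1),
        )
    else:
        raise ValueError(f"unknown morphology preset {name!r}")
    return MorphRecipe(steps)


PRESETS = ("pca", "fpca", "walumi")


def refine(mask: np.ndarray, recipe: str | MorphRecipe) -> np.ndarray:
    """Apply a preset name or an explicit recipe to a predicted mask."""
    if isinstance(recipe, str):
        recipe = _preset(recipe)
    return recipe.apply(mask)
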