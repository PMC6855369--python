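"""Raw data to network-ready tensors.

Central cropping, per-image min-max normalization, diamond-dilated label
maps, and 90-degree rotational augmentation for the rotation-invariant
confocal modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import validate_cones

__all__ = [
    "Sample",
    "crop_central",
    "normalize_image",
    "make_label_map",
    "augment_rotations",
    "diamond_area",
]


@dataclass
class Sample:
    """A normalized image, its binary cone label map, and truth points."""

    image: np.ndarray  # 2-D float, [0, 1]
    labels: np.ndarray  # 2-D bool, same shape
    cones: np.ndarray  # (n, 2) float, (x, y)
    modality: str = "confocal"  # "confocal" | "split_detector"

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError("image and label map shapes differ")
        validate_cones(self.cones, shape=self.image.shape)


def crop_central(
    image: np.ndarray, cones: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the central ``size`` x ``size`` window; shift and filter cones.

    The window offset along each axis is ``floor((dim - size) / 2)``, so an
    odd remainder leaves the extra row/column at the bottom/right.  Cones
    whose shifted position falls outside the window are dropped.
    """
    h, w = image.shape
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    out = image[r0 : r0 + size, c0 : c0 + size]
    cones = np.asarray(cones, dtype=np.float64).reshape(-1, 2)
    shifted = cones - np.array([c0, r0], dtype=np.float64)
    inside = (
        (shifted[:, 0] >= 0)
        & (shifted[:, 0] <= size - 1)
        & (shifted[:, 1] >= 0)
        & (shifted[:, 1] <= size - 1)
    )
    return out, shifted[inside]


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1] per image.

    A constant image maps to all zeros (the division would be undefined);
    this degenerate case is reported as a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    lo = image.min()
    hi = image.max()
    if hi == lo:
        warnings.warn("constant image: normalizing to all zeros", stacklevel=2)
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def _round_half_away(v: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def diamond_area(radius: int) -> int:
    """Pixels in a Manhattan ball of the given radius: 2r^2 + 2r + 1."""
    return 2 * radius * radius + 2 * radius + 1


def make_label_map(cones: np.ndarray, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Stamp a diamond of the given Manhattan radius around each cone.

    Cones are rounded to the nearest pixel before stamping; diamonds are
    clipped at the borders, and overlapping diamonds merge into their
    union.  Radius 0 marks the single center pixel.
    """
    if radius not in (0, 1, 2, 3):
        raise ValueError(f"label radius must be in 0..3, got {radius}")
    h, w = shape
    cones = validate_cones(cones, shape=shape, where="label cones")
    mask = np.zeros(shape, dtype=bool)
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if abs(dy) + abs(dx) <= radius
    ]
    cols = _round_half_away(cones[:, 0]).astype(int)
    rows = _round_half_away(cones[:, 1]).astype(int)
    for dy, dx in offsets:
        rr = rows + dy
        cc = cols + dx
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[ok], cc[ok]] = True
    return mask


def rotate_points_ccw(cones: np.ndarray, size: int, quarter_turns: int) -> np.ndarray:
    """Rotate (x, y) pixel-index points about a size x size frame.

    One 90-degree counter-clockwise turn maps (x, y) -> (y, N-1-x).
    """
    xy = np.asarray(cones, dtype=np.float64).reshape(-1, 2).copy()
    for _ in range(quarter_turns % 4):
        xy = np.column_stack([xy[:, 1], size - 1 - xy[:, 0]])
    return xy


def augment_rotations(sample: Sample) -> list[Sample]:
    """Return the four 90-degree rotations of a confocal sample.

    The confocal modality is rotation invariant, so each training sample
    contributes its 0/90/180/270-degree counter-clockwise rotations with
    image, label map and cone coordinates transformed consistently.  Split
    detector images are anisotropic (bright/dark lobes from the difference
    of two offset channels) and must not be augmented this way.
    """
    if sample.modality != "confocal":
        raise ValueError(
            "rotational augmentation applies only to the rotation-invariant "
            "confocal modality"
        )
    h, w = sample.image.shape
    if h != w:
        raise ValueError("rotational augmentation requires square images")
    out = []
    for k in range(4):
        out.append(
            Sample(
                image=np.rot90(sample.image, k).copy(),
                labels=np.rot90(sample.labels, k).copy(),
                cones=rotate_points_ccw(sample.cones, h, k),
                modality=sample.modality,
            )
        )
    return out
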