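"""Image and cone-coordinate file I/O.

Fixes the coordinate convention used throughout the package:

* points are ``(x, y)`` pairs with ``x`` the column and ``y`` the row,
* coordinates are 0-based with the origin at the top-left pixel center,
* sub-pixel positions are continuous floats.

Coordinate files are plain CSV with header ``x,y``, one point per line.
Datasets annotated in 1-based environments are reconciled once, at read
time, via ``one_based=True``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "read_cone_coords",
    "write_cone_coords",
    "validate_cones",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as a float 2-D array.

    Intensities are cast to float preserving stored values (a pixel stored
    as 200 in an 8-bit file reads as 200.0); no rescaling or normalization
    is applied here.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    FormatError
        For unreadable files or genuine color content (non-identical
        channels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise FormatError(f"could not decode image {path}: {exc}") from exc
    if arr.ndim == 3:
        # allow replicated-grayscale RGB(A); reject true color
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise FormatError(f"{path} has non-grayscale color content")
        arr = rgb[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return arr.astype(np.float64)


def read_cone_coords(path: str | Path, one_based: bool = False) -> np.ndarray:
    """Read a cone-coordinate CSV into an ``(n, 2)`` float array of (x, y).

    Parameters
    ----------
    path
        CSV file with header ``x,y``.
    one_based
        If True, coordinates in the file use a 1-based origin and 1 is
        subtracted from each value on read.
    """
    path = Path(path)
    points: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected 'x,y' header") from None
        if [c.strip().lower() for c in header[:2]] != ["x", "y"]:
            raise FormatError(f"{path}: expected header 'x,y', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x, y = float(row[0]), float(row[1])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            points.append((x, y))
    xy = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if one_based:
        xy = xy - 1.0
    validate_cones(xy, where=str(path))
    return xy


def write_cone_coords(cones: np.ndarray, path: str | Path) -> None:
    """Write an ``(n, 2)`` (x, y) array as CSV; round-trips to 1e-6."""
    cones = np.asarray(cones, dtype=np.float64).reshape(-1, 2)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in cones:
            writer.writerow([f"{x:.6f}", f"{y:.6f}"])


def validate_cones(
    cones: np.ndarray,
    shape: tuple[int, int] | None = None,
    where: str = "cone set",
) -> np.ndarray:
    """Check finiteness, uniqueness and (optionally) frame containment."""
    cones = np.asarray(cones, dtype=np.float64).reshape(-1, 2)
    if not np.isfinite(cones).all():
        raise ValueError(f"{where}: non-finite coordinates")
    if len(cones) > 1:
        uniq = np.unique(cones, axis=0)
        if len(uniq) != len(cones):
            raise ValueError(f"{where}: duplicate points are an input error")
    if shape is not None:
        h, w = shape
        x, y = cones[:, 0], cones[:, 1]
        if len(cones) and ((x < 0).any() or (y < 0).any() or (x > w - 1).any() or (y > h - 1).any()):
            raise ValueError(f"{where}: point outside [0, {w - 1}] x [0, {h - 1}] frame")
    return cones
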