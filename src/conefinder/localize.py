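"""Reduce a cone-probability map to cone coordinates.

The localization chain is the classical morphological spot detector:

1. Gaussian smoothing with standard deviation ``sigma``.
2. Extended-maxima transform with height tolerance ``h`` — the regional
   maxima of the H-maxima transform, i.e. of the morphological
   reconstruction by dilation of ``(map - h)`` under ``map``
   (8-connectivity throughout).
3. Region filtering against the *original* (pre-smoothing) probability
   map with minimal threshold ``t``.
4. Unweighted centroids of the surviving regions.

``sweep_detection_params`` selects ``(sigma, h, t)`` by exhaustively
scoring every grid combination by mean Dice over training images.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction

from .evaluate import ZonePartition, compute_metrics, match_cones

__all__ = [
    "DetectionParams",
    "SweepGrid",
    "gaussian_smooth",
    "extended_maxima",
    "filter_regions",
    "region_centroids",
    "localize_cones",
    "sweep_detection_params",
]

_FOOTPRINT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    """The (sigma, h, t) triple governing map-to-points reduction."""

    sigma: float  # Gaussian smoothing SD, px
    h: float  # extended-maxima height tolerance, probability units
    t: float  # minimal original-map probability threshold

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if not 0 <= self.t <= 1:
            raise ValueError("t must be in [0, 1]")


def _default_sigmas() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0, 21) * 0.1, 10))


def _default_hs() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0, 11) * 0.1, 10))


def _default_ts() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0, 7) * 0.05, 10)) + (0.4, 0.5)


@dataclass(frozen=True)
class SweepGrid:
    """Exhaustive search grid over detection parameters.

    Defaults: sigma 0 to 2 in steps of 0.1 (21 values), h 0 to 1 in steps
    of 0.1 (11 values), t 0 to 0.3 in steps of 0.05 followed by 0.4 and
    0.5 (9 values) — 2079 combinations in total.
    """

    sigmas: tuple[float, ...] = field(default_factory=_default_sigmas)
    hs: tuple[float, ...] = field(default_factory=_default_hs)
    ts: tuple[float, ...] = field(default_factory=_default_ts)

    def __post_init__(self) -> None:
        for name, vals in (("sigmas", self.sigmas), ("hs", self.hs), ("ts", self.ts)):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name} must be ascending")

    def __len__(self) -> int:
        return len(self.sigmas) * len(self.hs) * len(self.ts)

    def combinations(self):
        """Yield (sigma, h, t) in lexicographic order."""
        return itertools.product(self.sigmas, self.hs, self.ts)


def gaussian_smooth(prob_map: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-filter the map; ``sigma = 0`` skips smoothing.

    The kernel is truncated at radius ``ceil(4 * sigma)`` with reflective
    boundaries, so the filter preserves total mass away from borders.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(prob_map, dtype=np.float64)
    radius = int(np.ceil(4 * sigma))
    return ndimage.gaussian_filter(
        np.asarray(prob_map, dtype=np.float64), sigma=sigma, mode="reflect", radius=radius
    )


def extended_maxima(arr: np.ndarray, h: float) -> tuple[np.ndarray, int]:
    """Label the extended maxima of a 2-D map.

    Computes the H-maxima transform (reconstruction by dilation of
    ``arr - h`` under ``arr``, 8-connected) and returns its regional
    maxima as 8-connected components: ``(labels, n_regions)`` with label 0
    background and region ids contiguous from 1 in scan order.

    A constant map is a single whole-frame plateau with no higher
    neighbor, hence one region covering the frame.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("map must be finite")
    if h < 0:
        raise ValueError("h must be >= 0")
    if h == 0:
        rec = arr
    else:
        rec = reconstruction(arr - h, arr, method="dilation", footprint=_FOOTPRINT8)
    if rec.max() == rec.min():
        mask = np.ones_like(rec, dtype=bool)
    else:
        mask = local_maxima(rec, connectivity=2, allow_borders=True)
    labels, n = ndimage.label(mask, structure=_FOOTPRINT8)
    return labels, int(n)


def filter_regions(
    labels: np.ndarray,
    n_regions: int,
    original: np.ndarray,
    t: float,
    statistic: str = "max",
) -> tuple[np.ndarray, int]:
    """Keep regions whose original-map statistic reaches the threshold.

    A region survives iff the ``max`` (default; ``mean`` optional) of the
    original, pre-smoothing probability map over its pixels is >= ``t``.
    Survivors are relabeled contiguously preserving scan order.
    """
    original = np.asarray(original, dtype=np.float64)
    if labels.shape != original.shape:
        raise ValueError("label and map shapes differ")
    if not 0 <= t <= 1:
        raise ValueError("t must be in [0, 1]")
    if n_regions == 0:
        return labels.copy(), 0
    idx = np.arange(1, n_regions + 1)
    if statistic == "max":
        stats = ndimage.labeled_comprehension(original, labels, idx, np.max, float, -np.inf)
    elif statistic == "mean":
        stats = ndimage.labeled_comprehension(original, labels, idx, np.mean, float, -np.inf)
    else:
        raise ValueError(f"unknown region statistic {statistic!r}")
    keep = stats >= t
    remap = np.zeros(n_regions + 1, dtype=labels.dtype)
    remap[idx[keep]] = np.arange(1, keep.sum() + 1)
    return remap[labels], int(keep.sum())


def region_centroids(labels: np.ndarray, n_regions: int) -> np.ndarray:
    """Unweighted per-region pixel centroids as (x, y), ordered by id."""
    if n_regions == 0:
        return np.empty((0, 2), dtype=np.float64)
    centers = ndimage.center_of_mass(
        np.ones_like(labels), labels, np.arange(1, n_regions + 1)
    )
    yx = np.asarray(centers, dtype=np.float64)
    return yx[:, ::-1].copy()


def localize_cones(
    prob_map: np.ndarray, params: DetectionParams, statistic: str = "max"
) -> np.ndarray:
    """Full smoothing -> extended maxima -> filter -> centroid chain."""
    smoothed = gaussian_smooth(prob_map, params.sigma)
    labels, n = extended_maxima(smoothed, params.h)
    labels, n = filter_regions(labels, n, prob_map, params.t, statistic=statistic)
    return region_centroids(labels, n)


def sweep_detection_params(
    maps: list[np.ndarray],
    truths: list[np.ndarray],
    grid: SweepGrid,
    free_zone_pad: int = 2,
    max_dist: float = 4.0,
    statistic: str = "max",
) -> DetectionParams:
    """Exhaustively select (sigma, h, t) maximizing mean Dice.

    Every grid combination is scored by the mean per-image Dice over the
    training maps under the free-zone matching protocol; images with an
    undefined Dice (no truths and no predictions in the testing area) are
    excluded from that mean.  Ties break toward the lexicographically
    smallest (sigma, h, t).
    """
    if len(maps) == 0 or len(maps) != len(truths):
        raise ValueError("need equally many (non-zero) maps and truth sets")
    best: DetectionParams | None = None
    best_score = -np.inf
    for sigma, h, t in grid.combinations():
        params = DetectionParams(sigma, h, t)
        dices = []
        for prob_map, truth in zip(maps, truths):
            preds = localize_cones(prob_map, params, statistic=statistic)
            zones = ZonePartition(shape=prob_map.shape, pad=free_zone_pad)
            result = match_cones(preds, truth, zones, max_dist=max_dist)
            dice = compute_metrics(result).dice
            if not np.isnan(dice):
                dices.append(dice)
        score = float(np.mean(dices)) if dices else -np.inf
        if score > best_score:
            best_score = score
            best = params
    assert best is not None
    return best
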