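"""Score predicted cones against ground truth with a border free zone.

Cropped frames cut cones in half at the borders, so a band of ``pad``
pixels (default 2) inside each border is a "free zone" and the rest of
the frame the "testing area":

* predictions inside the free zone are disregarded entirely;
* a testing-area prediction may still match a truth in the free zone and
  count as a true positive;
* truths in the free zone with no matching prediction are excluded, not
  false negatives.

From the resulting counts: TPR = Tp/(Tp+Fn), FDR = Fp/(Fp+Tp) and
Dice = 2Tp/(2Tp+Fp+Fn).  Undefined ratios (zero denominators) are
reported as NaN, flagged and excluded from aggregation — never silently
zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZonePartition",
    "MatchResult",
    "MetricSet",
    "match_cones",
    "compute_metrics",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ZonePartition:
    """Free zone (border band of width ``pad``) vs. testing area.

    A sub-pixel point belongs to the free zone iff its floor pixel lies in
    the band.  ``pad = 0`` makes the whole frame testing area.
    """

    shape: tuple[int, int]  # (height, width)
    pad: int = 2

    def __post_init__(self) -> None:
        if self.pad < 0:
            raise ValueError("pad must be >= 0")

    def in_free_zone(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: True where a point falls in the border band."""
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        h, w = self.shape
        col = np.floor(pts[:, 0])
        row = np.floor(pts[:, 1])
        return (
            (col < self.pad)
            | (col >= w - self.pad)
            | (row < self.pad)
            | (row >= h - self.pad)
        )


@dataclass
class MatchResult:
    """One-to-one matching bookkeeping under the free-zone protocol."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]]  # (prediction index, truth index)
    disregarded_predictions: np.ndarray  # free-zone predictions, (k, 2)
    excluded_truths: np.ndarray  # unmatched free-zone truths, (k, 2)


def match_cones(
    preds: np.ndarray,
    truths: np.ndarray,
    zones: ZonePartition,
    max_dist: float = 4.0,
) -> MatchResult:
    """Greedily match predictions to truths by ascending distance.

    Free-zone predictions are disregarded first.  Remaining predictions
    are matched one-to-one to truths anywhere in the frame among pairs
    with Euclidean distance <= ``max_dist``, nearest pairs first, ties
    broken by (prediction index, truth index).  Unmatched testing-area
    predictions are false positives; unmatched testing-area truths are
    false negatives; unmatched free-zone truths are excluded.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    preds = np.asarray(preds, dtype=np.float64).reshape(-1, 2)
    truths = np.asarray(truths, dtype=np.float64).reshape(-1, 2)

    pred_free = zones.in_free_zone(preds)
    active = preds[~pred_free]
    truth_free = zones.in_free_zone(truths)

    pairs: list[tuple[float, int, int]] = []
    if len(active) and len(truths):
        d = np.linalg.norm(active[:, None, :] - truths[None, :, :], axis=2)
        pi, ti = np.nonzero(d <= max_dist)
        pairs = sorted(zip(d[pi, ti], pi, ti))

    used_pred: set[int] = set()
    used_truth: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, pi, ti in pairs:
        if pi in used_pred or ti in used_truth:
            continue
        used_pred.add(pi)
        used_truth.add(ti)
        matched.append((int(pi), int(ti)))

    tp = len(matched)
    fp = len(active) - tp
    unmatched_truth = np.setdiff1d(np.arange(len(truths)), list(used_truth))
    fn = int((~truth_free[unmatched_truth]).sum())
    excluded = truths[unmatched_truth[truth_free[unmatched_truth]]]
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        matched_pairs=matched,
        disregarded_predictions=preds[pred_free],
        excluded_truths=excluded,
    )


@dataclass(frozen=True)
class MetricSet:
    """True positive rate, false discovery rate and Dice overlap."""

    tpr: float
    fdr: float
    dice: float

    def as_dict(self) -> dict[str, float]:
        return {"tpr": self.tpr, "fdr": self.fdr, "dice": self.dice}


def compute_metrics(m: MatchResult) -> MetricSet:
    """TPR, FDR and Dice from match counts; NaN where undefined."""
    if min(m.tp, m.fp, m.fn) < 0:
        raise ValueError("counts must be non-negative")
    tpr = m.tp / (m.tp + m.fn) if m.tp + m.fn > 0 else math.nan
    fdr = m.fp / (m.fp + m.tp) if m.fp + m.tp > 0 else math.nan
    denom = 2 * m.tp + m.fp + m.fn
    dice = 2 * m.tp / denom if denom > 0 else math.nan
    return MetricSet(tpr=tpr, fdr=fdr, dice=dice)


@dataclass
class RunSummary:
    """Mean and sample SD per metric over all images of all runs."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    n_excluded: dict[str, int] = field(default_factory=dict)


def aggregate_runs(per_run_metrics: list[list[MetricSet]]) -> RunSummary:
    """Pool per-image metrics across repeat runs.

    Repeat trainings from scratch differ only by their random seed; the
    pooled mean and sample standard deviation (ddof=1; 0 for a single
    value) summarize both performance and run-to-run consistency.
    Undefined (NaN) values are excluded and counted.
    """
    if not per_run_metrics or not any(per_run_metrics):
        raise ValueError("need at least one run with at least one image")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n: dict[str, int] = {}
    n_excl: dict[str, int] = {}
    for key in ("tpr", "fdr", "dice"):
        vals = np.array(
            [getattr(ms, key) for run in per_run_metrics for ms in run], dtype=float
        )
        ok = vals[~np.isnan(vals)]
        n_excl[key] = int(np.isnan(vals).sum())
        n[key] = len(ok)
        if len(ok) == 0:
            mean[key] = math.nan
            sd[key] = math.nan
        else:
            mean[key] = float(ok.mean())
            sd[key] = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
    return RunSummary(mean=mean, sd=sd, n=n, n_excluded=n_excl)


def overlay_detections(
    image: np.ndarray,
    result: MatchResult,
    preds: np.ndarray,
    truths: np.ndarray,
    zones: ZonePartition,
    path=None,
):
    """Diagnostic overlay: yellow TP, red FP, blue FN, magenta excluded
    truths, green disregarded predictions, cyan free-zone border."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preds = np.asarray(preds, dtype=np.float64).reshape(-1, 2)
    truths = np.asarray(truths, dtype=np.float64).reshape(-1, 2)
    h, w = zones.shape
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image, cmap="gray", interpolation="nearest")
    matched_p = {p for p, _ in result.matched_pairs}
    matched_t = {t for _, t in result.matched_pairs}
    free_p = zones.in_free_zone(preds)
    free_t = zones.in_free_zone(truths)
    tp_xy = preds[[i for i in matched_p]] if matched_p else np.empty((0, 2))
    fp_xy = np.array(
        [p for i, p in enumerate(preds) if not free_p[i] and i not in matched_p]
    ).reshape(-1, 2)
    fn_xy = np.array(
        [t for i, t in enumerate(truths) if not free_t[i] and i not in matched_t]
    ).reshape(-1, 2)
    for xy, color in [
        (tp_xy, "yellow"),
        (fp_xy, "red"),
        (fn_xy, "blue"),
        (result.excluded_truths, "magenta"),
        (result.disregarded_predictions, "green"),
    ]:
        if len(xy):
            ax.plot(xy[:, 0], xy[:, 1], "o", mfc="none", mec=color, ms=6)
    pad = zones.pad
    ax.add_patch(
        plt.Rectangle(
            (pad - 0.5, pad - 0.5), w - 2 * pad, h - 2 * pad,
            fill=False, edgecolor="cyan",
        )
    )
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
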