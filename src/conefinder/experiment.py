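"""End-to-end experiment orchestration.

The protocol has a strict order: train the network on the training
images, run the *training* images back through the trained network and
sweep the detection parameters (sigma, h, t) on those probability maps,
then — with both frozen — infer, localize and score the held-out test
images.  The sweep never sees test data.  Repeat runs retrain from
scratch with different seeds and are summarized as mean (SD) per metric.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .evaluate import MetricSet, RunSummary, ZonePartition, aggregate_runs, compute_metrics, match_cones
from .localize import DetectionParams, localize_cones, sweep_detection_params
from .nn.train import TrainConfig, TrainedModel, predict_prob_map, train_model
from .preprocess import Sample, augment_rotations, make_label_map, normalize_image
from .synthetic import MosaicParams, generate_dataset

__all__ = ["RunResult", "ExperimentReport", "run_experiment", "synthetic_samples"]


@dataclass
class RunResult:
    """One from-scratch training: its model, swept params and test scores."""

    seed: int
    model: TrainedModel
    params: DetectionParams
    per_image: list[MetricSet]


@dataclass
class ExperimentReport:
    runs: list[RunResult]
    summary: RunSummary
    manifest: dict = field(default_factory=dict)


def synthetic_samples(
    n: int, mosaic: MosaicParams, label_radius: int, seed: int
) -> list[Sample]:
    """Render mosaics and package them as normalized, labeled samples."""
    raw = generate_dataset(n, mosaic, seed=seed)
    out = []
    for s in raw:
        img = normalize_image(s.image)
        labels = make_label_map(s.cones, img.shape, label_radius)
        out.append(Sample(image=img, labels=labels, cones=s.cones, modality=mosaic.modality))
    return out


def _evaluate_model(
    model: TrainedModel,
    params: DetectionParams,
    test: list[Sample],
    cfg: RunConfig,
) -> list[MetricSet]:
    metrics = []
    for s in test:
        prob = predict_prob_map(model, s.image)
        preds = localize_cones(prob, params)
        zones = ZonePartition(shape=s.image.shape, pad=cfg.free_zone_pad)
        metrics.append(compute_metrics(match_cones(preds, s.cones, zones, cfg.match_distance)))
    return metrics


def run_experiment(
    cfg: RunConfig,
    train_samples: list[Sample],
    test_samples: list[Sample],
    repeats: int = 4,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Train/sweep/test ``repeats`` times and pool the per-image metrics.

    Repeat runs differ only in the training seed (weight initialization,
    shuffling, dropout); data, architecture and sweep grid are shared.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not train_samples or not test_samples:
        raise ValueError("need non-empty train and test sets")

    if cfg.augment_rotations and cfg.modality == "confocal":
        augmented: list[Sample] = []
        for s in train_samples:
            augmented.extend(augment_rotations(s))
    else:
        augmented = list(train_samples)

    run_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(repeats)
    ]
    runs: list[RunResult] = []
    for seed in run_seeds:
        t0 = time.time()
        tcfg = TrainConfig(
            epochs=cfg.train.epochs,
            batch_size=cfg.train.batch_size,
            learning_rate=cfg.train.learning_rate,
            momentum=cfg.train.momentum,
            seed=seed,
            class_weights=cfg.train.class_weights,
        )
        model = train_model(cfg.network, augmented, tcfg)
        # sweep on the training images' probability maps only
        train_maps = [predict_prob_map(model, s.image) for s in train_samples]
        train_truths = [s.cones for s in train_samples]
        params = sweep_detection_params(
            train_maps,
            train_truths,
            cfg.sweep,
            free_zone_pad=cfg.free_zone_pad,
            max_dist=cfg.match_distance,
        )
        per_image = _evaluate_model(model, params, test_samples, cfg)
        runs.append(RunResult(seed=seed, model=model, params=params, per_image=per_image))
        _ = time.time() - t0
    summary = aggregate_runs([r.per_image for r in runs])
    manifest = {
        "modality": cfg.modality,
        "n_train": len(train_samples),
        "n_train_after_augmentation": len(augmented),
        "n_test": len(test_samples),
        "repeats": repeats,
        "run_seeds": run_seeds,
        "epochs": cfg.train.epochs,
        "label_radius": cfg.label_radius,
        "chosen_params": [
            {"sigma": r.params.sigma, "h": r.params.h, "t": r.params.t} for r in runs
        ],
    }
    report = ExperimentReport(runs=runs, summary=summary, manifest=manifest)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: ExperimentReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "per_image.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run", "image", "tpr", "fdr", "dice"])
        for i, run in enumerate(report.runs):
            for j, m in enumerate(run.per_image):
                w.writerow([i, j, f"{m.tpr:.6f}", f"{m.fdr:.6f}", f"{m.dice:.6f}"])
    with open(out / "summary.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "mean", "sd", "n", "n_excluded"])
        for key in ("tpr", "fdr", "dice"):
            w.writerow(
                [
                    key,
                    f"{report.summary.mean[key]:.6f}",
                    f"{report.summary.sd[key]:.6f}",
                    report.summary.n[key],
                    report.summary.n_excluded[key],
                ]
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
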