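"""Training and inference for the cone-probability network.

Training minimizes unweighted per-pixel two-class cross-entropy between
the softmax output and the (optionally diamond-dilated) binary label map
with SGD + momentum, for a fixed number of epochs — no early stopping,
no validation split.  Everything random (weight init, shuffling, dropout)
derives from one seed, so a run is bit-reproducible within one
environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import Sample
from .unet import NetworkConfig, UNet, build_unet, softmax_channels

__all__ = ["TrainConfig", "TrainedModel", "train_model", "predict_prob_map",
           "save_model", "load_model"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults: 50 epochs, SGD with momentum 0.9 at learning rate 1e-2,
    batch size 8, no class weighting.
    """

    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-2
    momentum: float = 0.9
    seed: int = 0
    class_weights: tuple[float, float] | None = None  # (background, cone)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A network plus its architecture and per-epoch mean training loss."""

    architecture: NetworkConfig
    net: UNet
    training_log: list[float] = field(default_factory=list)


def _cross_entropy_grad(
    logits: np.ndarray,
    targets: np.ndarray,
    class_weights: tuple[float, float] | None,
) -> tuple[float, np.ndarray]:
    """Mean per-pixel CE loss and gradient wrt logits."""
    probs = softmax_channels(logits)
    n, _, h, w = logits.shape
    npx = n * h * w
    t = targets.astype(int)
    p_true = np.take_along_axis(probs, t[:, None], axis=1)[:, 0]
    eps = 1e-12
    if class_weights is None:
        loss = float(-np.log(p_true + eps).mean())
        onehot = np.stack([1 - t, t], axis=1)
        grad = (probs - onehot) / npx
    else:
        wmap = np.where(t == 1, class_weights[1], class_weights[0])
        loss = float(-(wmap * np.log(p_true + eps)).sum() / wmap.sum())
        onehot = np.stack([1 - t, t], axis=1)
        grad = wmap[:, None] * (probs - onehot) / wmap.sum()
    return loss, grad


def train_model(
    cfg: NetworkConfig, samples: list[Sample], tcfg: TrainConfig
) -> TrainedModel:
    """Train from scratch on the given samples.

    Weights are initialized with small random values from ``tcfg.seed``;
    samples are reshuffled every epoch with the same generator.  Returns
    the model with one mean-loss entry per epoch.
    """
    if not samples:
        raise ValueError("empty training set")
    size = cfg.in_size
    for s in samples:
        if s.image.shape != (size, size):
            raise ValueError(
                f"sample shape {s.image.shape} does not match network input {size}"
            )
    x = np.stack([s.image for s in samples])[:, None, :, :].astype(np.float64)
    y = np.stack([s.labels for s in samples]).astype(np.int8)

    master = np.random.SeedSequence(tcfg.seed)
    init_ss, shuffle_ss, dropout_ss = master.spawn(3)
    net = UNet(cfg, np.random.default_rng(init_ss))
    net.dropout.rng = np.random.default_rng(dropout_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)

    velocity = [np.zeros_like(p) for p in net.params]
    log: list[float] = []
    n = len(samples)
    for _epoch in range(tcfg.epochs):
        order = shuffle_rng.permutation(n)
        losses: list[tuple[float, int]] = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            logits = net.forward(x[idx], train=True)
            loss, grad = _cross_entropy_grad(logits, y[idx], tcfg.class_weights)
            net.backward(grad)
            params, grads = net.params, net.grads
            for v, p, g in zip(velocity, params, grads):
                v *= tcfg.momentum
                v -= tcfg.learning_rate * g
                p += v
            losses.append((loss, len(idx)))
        total = sum(w for _, w in losses)
        log.append(sum(l * w for l, w in losses) / total)
    return TrainedModel(architecture=cfg, net=net, training_log=log)


def predict_prob_map(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Cone-class probability map for one normalized image.

    Inference is deterministic: dropout is inactive and batch-norm uses
    its frozen running statistics.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.max() > 1.0 + 1e-9 or image.min() < -1e-9:
        raise ValueError("input must be normalized to [0, 1] (see normalize_image)")
    probs = model.net.predict_probs(image[None, None])
    return probs[0, 1]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize weights, running stats and architecture to one archive."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.net.params)}
    bns = [l for l in model.net._all_layers() if hasattr(l, "running_mean")]
    for i, bn in enumerate(bns):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    meta = dict(
        depth=model.architecture.depth,
        base_filters=model.architecture.base_filters,
        kernel=model.architecture.kernel,
        dropout_rate=model.architecture.dropout_rate,
        in_size=model.architecture.in_size,
        training_log=model.training_log,
    )
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        log = meta.pop("training_log")
        cfg = NetworkConfig(**meta)
        net = build_unet(cfg, seed=0)
        for i, p in enumerate(net.params):
            p[...] = data[f"param_{i}"]
        bns = [l for l in net._all_layers() if hasattr(l, "running_mean")]
        for i, bn in enumerate(bns):
            bn.running_mean = data[f"bn_mean_{i}"]
            bn.running_var = data[f"bn_var_{i}"]
    return TrainedModel(architecture=cfg, net=net, training_log=list(log))
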