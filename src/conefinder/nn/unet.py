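"""Modified U-Net for per-pixel cone probability maps.

Compared with the original U-Net, each level has a single
conv-ReLU-batchnorm block (not two convolutions), convolutions are
zero-padded so the output map has exactly the input's spatial size, and
a single dropout layer sits at the bottleneck.  The decoder mirrors the
encoder with 2x2 stride-2 transposed convolutions; each upsampled map is
concatenated with the same-level encoder feature map (skip connection).
A final 1x1 convolution maps to two channels (background, cone) and a
softmax yields per-pixel class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, Conv2d, ConvTranspose2x2, Dropout, MaxPool2x2, ReLU

__all__ = ["NetworkConfig", "UNet", "build_unet", "softmax_channels"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs.

    ``depth`` pooling stages halve the spatial size each, so ``in_size``
    must be divisible by ``2**depth``.  ``base_filters`` channels at the
    first level double at every deeper level.  The default preset
    (depth 4, 64 base filters, 3x3 kernels) follows U-Net heritage; the
    ``tiny`` preset (depth 3, 8 base filters) trains in minutes on a CPU
    and is used by the test suite.
    """

    depth: int = 4
    base_filters: int = 64
    kernel: int = 3
    dropout_rate: float = 0.5
    in_size: int = 144

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.in_size % (2**self.depth) != 0:
            raise ValueError(
                f"in_size {self.in_size} not divisible by 2^depth = {2**self.depth}"
            )
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")

    @classmethod
    def tiny(cls, in_size: int = 96) -> "NetworkConfig":
        return cls(depth=3, base_filters=8, kernel=3, in_size=in_size)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over axis 1 (channels)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _ConvBlock:
    """conv -> ReLU -> batch norm, the single block per level."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, c_out, kernel, rng)
        self.relu = ReLU()
        self.bn = BatchNorm2d(c_out)

    def forward(self, x, train):
        return self.bn.forward(self.relu.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.relu.backward(self.bn.backward(g)))

    def layers(self):
        return [self.conv, self.relu, self.bn]


class UNet:
    """The network: ``forward`` yields 2-channel logits, NCHW float64."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.enc_blocks: list[_ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        c_in = 1
        for level in range(cfg.depth):
            c_out = cfg.base_filters * (2**level)
            self.enc_blocks.append(_ConvBlock(c_in, c_out, cfg.kernel, rng))
            self.pools.append(MaxPool2x2())
            c_in = c_out
        c_bottom = cfg.base_filters * (2**cfg.depth)
        self.bottleneck = _ConvBlock(c_in, c_bottom, cfg.kernel, rng)
        self.dropout = Dropout(cfg.dropout_rate)
        self.up_convs: list[ConvTranspose2x2] = []
        self.dec_blocks: list[_ConvBlock] = []
        c_in = c_bottom
        for level in reversed(range(cfg.depth)):
            c_out = cfg.base_filters * (2**level)
            self.up_convs.append(ConvTranspose2x2(c_in, c_out, rng))
            self.dec_blocks.append(_ConvBlock(2 * c_out, c_out, cfg.kernel, rng))
            c_in = c_out
        self.head = Conv2d(c_in, 2, 1, rng)

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self):
        out = []
        for b in self.enc_blocks:
            out.extend(b.layers())
        out.extend(self.pools)
        out.extend(self.bottleneck.layers())
        out.append(self.dropout)
        out.extend(self.up_convs)
        for b in self.dec_blocks:
            out.extend(b.layers())
        out.append(self.head)
        return out

    @property
    def params(self):
        return [p for layer in self._all_layers() for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self._all_layers() for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected NCHW input with one channel")
        h = x
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        h = self.dropout.forward(h, train)
        for up, block, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = block.forward(h, train)
        if train:
            self._skip_channels = [s.shape[1] for s in skips]
        return self.head.forward(h, train)

    def backward(self, gout: np.ndarray) -> None:
        g = self.head.backward(gout)
        gskips = []
        for up, block, c_skip in zip(
            reversed(self.up_convs), reversed(self.dec_blocks), self._skip_channels
        ):
            g = block.backward(g)
            gskip, g = g[:, :c_skip], g[:, c_skip:]
            gskips.append(gskip)
            g = up.backward(g)
        g = self.dropout.backward(g)
        g = self.bottleneck.backward(g)
        # gskips were collected shallowest-first; encoder unwinds deepest-first
        for pool, block, gskip in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(gskips)
        ):
            g = pool.backward(g)
            g = block.backward(g + gskip)

    # -- prediction -------------------------------------------------------
    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities with dropout off and frozen batch norm."""
        return softmax_channels(self.forward(x, train=False))


def build_unet(cfg: NetworkConfig, seed: int = 0) -> UNet:
    """Construct a network with small random initial weights."""
    rng = np.random.default_rng(seed)
    return UNet(cfg, rng)
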