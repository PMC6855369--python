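"""Synthetic photoreceptor-mosaic generator.

Healthy cone mosaics pack quasi-hexagonally; the generator places cone
centers on a triangular lattice with Gaussian positional jitter and
optional site dropout, then renders them in one of two appearances:

* ``confocal`` — bright, roughly isotropic Gaussian spots on a dark
  background (the rotation-invariant confocal AOSLO channel);
* ``split_detector`` — horizontally antisymmetric bright/dark lobe pairs
  on a mid-gray background (the split-detector channel derives from the
  difference of two horizontally offset detectors, so cones are not
  rotation invariant).

Additive Gaussian noise and intensity clipping complete the rendering.
Everything is deterministic per seed, so the generator can stand in for
annotated datasets in end-to-end training and evaluation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .io import write_cone_coords

__all__ = ["MosaicParams", "SyntheticSample", "generate_mosaic", "generate_dataset"]


@dataclass(frozen=True)
class MosaicParams:
    """Geometry and photometry of a simulated mosaic.

    Defaults mimic the visual scale of 144-px AOSLO crops: mean cone
    spacing 9 px, spot width (Gaussian SD) 2 px, positional jitter 0.8 px
    and additive noise SD 0.05 on a [0, 1] intensity scale.
    """

    size: int = 144  # frame side, px
    spacing: float = 9.0  # mean nearest-neighbor cone distance, px
    jitter: float = 0.8  # positional noise SD, px
    blob_sigma: float = 2.0  # cone spot width (Gaussian SD), px
    amplitude: float = 0.8  # peak spot intensity above/around background
    noise_sd: float = 0.05  # additive Gaussian noise SD
    background: float | None = None  # default 0.1 confocal, 0.5 split detector
    modality: str = "confocal"  # "confocal" | "split_detector"
    dropout_fraction: float = 0.0  # fraction of lattice sites left empty

    def __post_init__(self) -> None:
        if self.modality not in ("confocal", "split_detector"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.spacing <= 2 * self.jitter:
            raise ValueError("spacing must exceed 2 * jitter")
        if self.size < 4 * self.spacing:
            raise ValueError("size must be at least 4 * spacing")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")

    @property
    def effective_background(self) -> float:
        if self.background is not None:
            return self.background
        return 0.5 if self.modality == "split_detector" else 0.1


@dataclass
class SyntheticSample:
    image: np.ndarray  # 2-D float in [0, 1]
    cones: np.ndarray  # (n, 2) float, (x, y)
    params: MosaicParams
    seed: int


def _lattice_sites(size: int, spacing: float) -> np.ndarray:
    """Triangular-lattice (x, y) sites covering the frame interior.

    Rows are spacing * sqrt(3)/2 apart with alternate rows offset by half
    a spacing — hexagonal packing.  A half-spacing margin keeps noiseless
    spot maxima strictly inside the frame.
    """
    dy = spacing * np.sqrt(3) / 2
    margin = spacing / 2
    ys = np.arange(margin, size - margin + 1e-9, dy)
    sites = []
    for i, y in enumerate(ys):
        x0 = margin + (spacing / 2 if i % 2 else 0.0)
        xs = np.arange(x0, size - margin + 1e-9, spacing)
        sites.extend((x, y) for x in xs)
    return np.asarray(sites, dtype=np.float64).reshape(-1, 2)


def _render(centers: np.ndarray, params: MosaicParams) -> np.ndarray:
    yy, xx = np.mgrid[0 : params.size, 0 : params.size].astype(np.float64)
    img = np.full((params.size, params.size), params.effective_background)
    s2 = 2 * params.blob_sigma**2
    for x, y in centers:
        # evaluate each spot only on a local window; tails beyond 5 sigma
        # are below float display precision
        r = int(np.ceil(5 * params.blob_sigma + params.blob_sigma))
        r0, r1 = max(0, int(y) - r), min(params.size, int(y) + r + 1)
        c0, c1 = max(0, int(x) - r), min(params.size, int(x) + r + 1)
        wy = yy[r0:r1, c0:c1]
        wx = xx[r0:r1, c0:c1]
        if params.modality == "confocal":
            img[r0:r1, c0:c1] += params.amplitude * np.exp(
                -((wx - x) ** 2 + (wy - y) ** 2) / s2
            )
        else:
            off = params.blob_sigma
            lobe = np.exp(-((wx - (x - off)) ** 2 + (wy - y) ** 2) / s2) - np.exp(
                -((wx - (x + off)) ** 2 + (wy - y) ** 2) / s2
            )
            img[r0:r1, c0:c1] += params.amplitude * lobe
    return img


def generate_mosaic(params: MosaicParams, seed: int) -> SyntheticSample:
    """Generate one mosaic image with its ground-truth cone centers."""
    rng = np.random.default_rng(seed)
    sites = _lattice_sites(params.size, params.spacing)
    if params.dropout_fraction > 0:
        keep = rng.random(len(sites)) >= params.dropout_fraction
        sites = sites[keep]
    if params.jitter > 0:
        sites = sites + rng.normal(0.0, params.jitter, size=sites.shape)
    sites = np.clip(sites, 0.0, params.size - 1.0)
    img = _render(sites, params)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SyntheticSample(image=img, cones=sites, params=params, seed=seed)


def generate_dataset(
    n: int,
    params: MosaicParams,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[SyntheticSample]:
    """Generate ``n`` mosaics with per-sample seeds derived from ``seed``.

    If ``out_dir`` is given, writes ``sample_###.png`` (8-bit grayscale,
    intensity scaled by 255) and matching ``sample_###.csv`` truth files
    in the layout the training and evaluation entry points consume.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for i, ss in enumerate(child_seeds):
        sub = int(ss.generate_state(1)[0] % (2**31))
        samples.append(generate_mosaic(params, seed=sub))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(samples):
            stem = f"sample_{i:03d}"
            iio.imwrite(
                out / f"{stem}.png",
                np.round(s.image * 255).astype(np.uint8),
            )
            write_cone_coords(s.cones, out / f"{stem}.csv")
    return samples
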