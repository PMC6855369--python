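# conefinder

Automatic detection of cone photoreceptors in adaptive optics scanning
laser ophthalmoscope (AOSLO) images.

Counting and mapping cones is the basis of photoreceptor metrics such as
density, spacing and packing regularity, but manual annotation of a
single image means marking hundreds of cells. `conefinder` implements a
two-step detector for researchers working with confocal or
split-detector AOSLO imagery:

1. **Probability map.** A fully convolutional network (a modified U-Net:
   one conv–ReLU–batchnorm block per level, zero-padded convolutions for
   input/output size parity, dropout 0.5 at the bottleneck, skip
   concatenations, two-channel softmax head) maps a min–max-normalized
   grayscale image to a per-pixel cone probability map of the same size.
2. **Localization.** The map is reduced to coordinates by Gaussian
   smoothing (σ), the extended-maxima transform (height tolerance H),
   filtering of each maximal region against the original map
   (threshold T), and region centroids. (σ, H, T) are chosen by an
   exhaustive sweep on the *training* images' probability maps.

Detections are scored against ground truth with a 2-px border **free
zone**: border predictions are disregarded, border truths are excluded
rather than counted as misses, and a testing-area prediction may match a
free-zone truth. Reported metrics are

    TPR  = Tp / (Tp + Fn)
    FDR  = Fp / (Fp + Tp)
    Dice = 2·Tp / (2·Tp + Fp + Fn)

A synthetic mosaic simulator (quasi-hexagonal cone lattice with
positional jitter; bright Gaussian spots for confocal, bright/dark lobe
pairs for split detector; additive noise) provides fully annotated data,
so the entire train → sweep → evaluate loop runs without any external
dataset. The network is implemented directly on numpy with hand-written
backpropagation; the small presets train in minutes on one CPU.

## Worked example

```python
import numpy as np
from conefinder import (MosaicParams, NetworkConfig, TrainConfig, SweepGrid,
                        DetectionParams, ZonePartition, train_model,
                        predict_prob_map, localize_cones, match_cones,
                        compute_metrics, sweep_detection_params)
from conefinder.experiment import synthetic_samples

mosaic = MosaicParams(size=96, modality="confocal")
train = synthetic_samples(100, mosaic, label_radius=3, seed=101)
test = synthetic_samples(20, mosaic, label_radius=3, seed=102)

model = train_model(NetworkConfig.tiny(96), train, TrainConfig(epochs=10, seed=7))
maps = [predict_prob_map(model, s.image) for s in train]
best = sweep_detection_params(maps, [s.cones for s in train],
                              SweepGrid(sigmas=(0.5, 1.0), hs=(0.2, 0.4), ts=(0.1, 0.2)))
print(best)

dices = []
for s in test:
    preds = localize_cones(predict_prob_map(model, s.image), best)
    zones = ZonePartition(shape=s.image.shape, pad=2)
    dices.append(compute_metrics(match_cones(preds, s.cones, zones, 4.0)).dice)
print(f"mean test Dice: {np.mean(dices):.3f}")
```

Output:

```
DetectionParams(sigma=0.5, h=0.2, t=0.1)
mean test Dice: 0.974
```

The chosen `DetectionParams` is the sweep's argmax of mean training
Dice; the final line is the mean Dice over 20 held-out synthetic images
— the fraction of cones (harmonically combining precision and recall)
the trained detector localizes correctly within 4 px under the
free-zone protocol.

More narrative scripts live in `examples/` (one per capability), and a
thin CLI wraps the same functions:

```sh
conefinder generate --n 20 --modality confocal --out data/
conefinder train --data data/ --out model.npz --epochs 10
conefinder localize --model model.npz --image data/sample_000.png \
    --sigma 1 --h 0.3 --t 0.25 --out cones.csv
```

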