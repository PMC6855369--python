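"""Score detections under the free-zone protocol.

Shows the border rules explicitly — a disregarded border prediction, an
excluded border truth, and a testing-area prediction matched to a
free-zone truth — then the derived TPR/FDR/Dice.
"""

import numpy as np

from conefinder import ZonePartition, compute_metrics, match_cones

zones = ZonePartition(shape=(20, 20), pad=2)

preds = np.array([
    [10.0, 10.0],   # testing area, exactly on a truth      -> TP
    [15.0, 15.0],   # testing area, no truth within 4 px    -> FP
    [3.0, 10.0],    # testing area, matches free-zone truth -> TP
    [0.5, 5.0],     # free zone                             -> disregarded
])
truths = np.array([
    [10.0, 10.0],   # matched
    [1.0, 10.0],    # free zone, matched by the 3rd prediction
    [5.0, 17.0],    # testing area, no prediction           -> FN
    [18.5, 1.0],    # free zone, unmatched                  -> excluded
])

result = match_cones(preds, truths, zones, max_dist=4.0)
print(f"tp={result.tp} fp={result.fp} fn={result.fn}")
print(f"disregarded predictions: {len(result.disregarded_predictions)}, "
      f"excluded truths: {len(result.excluded_truths)}")

m = compute_metrics(result)
print(f"TPR={m.tpr:.3f} FDR={m.fdr:.3f} Dice={m.dice:.3f}")

# Expected: tp=2 fp=1 fn=1, one disregarded prediction, one excluded
# truth; TPR=0.667, FDR=0.333, Dice=0.667.
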