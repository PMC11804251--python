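"""Score a set of predicted centroids against ground truth.

Builds a toy scenario with a few localization errors, a miss and a false
positive, then walks through optimal assignment, TP/FP/FN classification and
the summary metrics.
"""

import numpy as np

from tomopick import CentroidSet, ParticleSet, match, normalized_rmse, prf

gt = ParticleSet(
    np.array([[10.0, 10.0, 10.0], [30.0, 30.0, 30.0], [50.0, 20.0, 40.0]]),
    diameter=100.0,  # Angstrom
    voxel_size=10.0,  # -> 10 px diameter, TP threshold 5 px
)
pred = CentroidSet(
    np.array([[11.0, 9.0, 10.0],    # 1.4 px off: true positive
              [30.0, 33.0, 30.0],   # 3 px off: true positive
              [80.0, 80.0, 80.0]]),  # nowhere near: false positive
    np.array([0.9, 0.7, 0.4]),
)

result = match(gt, pred)
print(f"TP={result.tp} FP={result.fp} FN={result.fn} "
      f"(distance threshold {result.dist_threshold} px)")
precision, recall, f1 = prf(result)
print(f"precision {precision:.3f}, recall {recall:.3f}, F1 {f1:.3f}")
print(f"normalized RMSE over TPs: {normalized_rmse(result, gt.diameter_px):.4f}")
# Assignment is globally optimal (minimum total distance), so a prediction is
# never matched to a far ground-truth point when a nearer unclaimed one exists.
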