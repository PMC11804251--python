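"""Centroid extraction from confidence maps.

Predicted heatmaps are turned into coordinates by a neighbourhood peak
search: a voxel is a candidate when it attains the maximum of its centered
cubic neighbourhood of side ``2*floor(min_distance/2) + 1``; candidates are
then processed in decreasing confidence, greedily suppressing any candidate
within ``min_distance`` (Chebyshev) of an already accepted peak, and finally
filtered by a confidence threshold (0.3 is a sensible starting point, but the
right value is data-dependent and worth choosing after inspecting the maps).
Extraction can be gated by a binary mask for targeted picking, and detected
coordinates can be mapped back to the original pre-resize pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import Volume

__all__ = ["CentroidSet", "find_peaks", "apply_mask", "to_original_frame"]


@dataclass
class CentroidSet:
    """Predicted centroids with per-point confidence.

    ``points`` is an ``(n, 3)`` array of (x, y, z) voxel coordinates sorted by
    descending score; ``frame`` records whether they refer to the rescaled
    detection grid or the original tomogram grid.
    """

    points: np.ndarray
    scores: np.ndarray
    min_distance: float = 1.0
    threshold: float = 0.0
    frame: str = "rescaled"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        if len(self.points) != len(self.scores):
            raise ValueError("points and scores length mismatch")
        if self.frame not in ("rescaled", "original"):
            raise ValueError(f"frame must be 'rescaled' or 'original', got {self.frame!r}")

    def __len__(self) -> int:
        return len(self.points)


def find_peaks(
    confidence: Volume | np.ndarray,
    min_distance: float = 10,
    threshold: float = 0.3,
) -> CentroidSet:
    """Detect local confidence maxima separated by at least ``min_distance``.

    ``min_distance`` defaults to the particle diameter in rescaled pixels
    (10 under the default preprocessing target).  Candidates are voxels that
    are >= every value in their cubic neighbourhood (clipped at the volume
    border); equal-valued plateau candidates are broken toward the
    lexicographically smallest (z, y, x) index, making the result
    deterministic.  Accepted peaks are returned sorted by descending
    confidence with their scores.
    """
    if min_distance < 1:
        raise ValueError(f"min_distance must be >= 1, got {min_distance}")
    data = confidence.data if isinstance(confidence, Volume) else np.asarray(confidence)
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("confidence map contains non-finite values")
    side = 2 * int(min_distance // 2) + 1
    local_max = ndimage.maximum_filter(data, size=side, mode="constant", cval=-np.inf)
    cand = np.argwhere(data >= local_max)  # (z, y, x) rows, lexicographically ordered
    values = data[tuple(cand.T)]
    # stable sort by descending value; argwhere order breaks ties toward the
    # lexicographically smallest (z, y, x)
    order = np.argsort(-values, kind="stable")
    cand = cand[order]
    values = values[order]
    # greedy suppression in decreasing confidence; the Chebyshev-distance
    # check against accepted peaks is vectorized per candidate
    acc = np.empty((len(cand), 3), dtype=np.int64)
    n_acc = 0
    accepted_scores: list[float] = []
    for zyx, val in zip(cand, values):
        if val < threshold:
            break  # sorted descending: nothing below threshold can follow
        if n_acc == 0 or np.min(np.max(np.abs(acc[:n_acc] - zyx), axis=1)) >= min_distance:
            acc[n_acc] = zyx
            n_acc += 1
            accepted_scores.append(float(val))
    if n_acc:
        pts = acc[:n_acc, ::-1].astype(np.float64)  # (z,y,x) -> (x,y,z)
    else:
        pts = np.zeros((0, 3))
    return CentroidSet(
        pts,
        np.array(accepted_scores),
        min_distance=min_distance,
        threshold=threshold,
        frame="rescaled",
    )


def apply_mask(centroids: CentroidSet, mask: Volume | np.ndarray) -> CentroidSet:
    """Keep only centroids whose nearest voxel lies inside ``mask > 0``.

    The mask must be congruent with the frame the centroids were detected in;
    scores are unchanged.
    """
    data = mask.data if isinstance(mask, Volume) else np.asarray(mask)
    if len(centroids) == 0:
        return replace(centroids)
    idx = np.rint(centroids.points[:, ::-1]).astype(int)  # (x,y,z) -> (z,y,x)
    if np.any(idx < 0) or np.any(idx >= np.array(data.shape)):
        raise ValueError("centroid indices fall outside the mask volume: shape mismatch?")
    keep = data[tuple(idx.T)] > 0
    return replace(centroids, points=centroids.points[keep], scores=centroids.scores[keep])


def to_original_frame(centroids: CentroidSet, scale: float) -> CentroidSet:
    """Map rescaled-frame coordinates back to the original pixel grid.

    ``scale`` is the factor that produced the rescaled grid (original * scale
    = rescaled), so coordinates are divided by it.  Scores are unchanged.
    """
    if centroids.frame != "rescaled":
        raise ValueError("centroids are already in the original frame")
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return replace(
        centroids,
        points=centroids.points / scale,
        min_distance=centroids.min_distance / scale,
        frame="original",
    )
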