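"""Full-volume prediction by tiled inference with overlap stitching.

A trained backbone only sees fixed-size cubes, so whole tomograms are tiled
with the same clamped-origin chunk grid used during training, each cube is
predicted independently, and overlapping predictions are fused by unweighted
per-voxel averaging (a cosine-window weighting is available for seam
suppression).  The fused map is clamped to [0, 1] so downstream confidence
thresholds keep their meaning regardless of the backbone's output range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneContract
from .io import Volume
from .preprocess import DEFAULT_CHUNK_SIZE, DEFAULT_STRIDE, chunk_volume

__all__ = ["ConfidenceMap", "predict_volume"]


@dataclass
class ConfidenceMap:
    """Per-voxel centroid confidence with provenance of how it was produced."""

    volume: Volume
    provenance: dict = field(default_factory=dict)

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def _cosine_window(size: int) -> np.ndarray:
    w1 = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(size) + 0.5) / size)
    win = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    return win.astype(np.float64)


def predict_volume(
    backbone: BackboneContract,
    volume: Volume,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    stride: int = DEFAULT_STRIDE,
    cosine_window: bool = False,
    provenance: dict | None = None,
) -> ConfidenceMap:
    """Predict a confidence map for a (rescaled, normalized) tomogram.

    The volume is tiled exactly as in training (clamped final window per
    axis, zero-padding only for volumes smaller than one chunk), every chunk
    is passed through the backbone, and overlaps are combined by averaging
    with per-voxel coverage counts (weights sum to 1 everywhere).  Output is
    clamped to [0, 1].
    """
    if chunk_size % backbone.stride_requirement:
        raise ValueError(
            f"chunk_size {chunk_size} incompatible with backbone stride "
            f"requirement {backbone.stride_requirement}"
        )
    chunks = chunk_volume(volume, chunk_size=chunk_size, stride=stride)
    padded_shape = tuple(s + p for s, p in zip(chunks.source_shape, chunks.padding))
    acc = np.zeros(padded_shape, dtype=np.float64)
    cov = np.zeros(padded_shape, dtype=np.float64)
    window = _cosine_window(chunk_size) if cosine_window else np.ones((chunk_size,) * 3)
    for (oz, oy, ox), cube in chunks:
        pred = np.asarray(backbone.forward(cube), dtype=np.float64)
        if pred.shape != cube.shape:
            raise ValueError(
                f"backbone returned shape {pred.shape} for chunk of shape {cube.shape}"
            )
        sl = (slice(oz, oz + chunk_size), slice(oy, oy + chunk_size), slice(ox, ox + chunk_size))
        acc[sl] += pred * window
        cov[sl] += window
    assert np.all(cov > 0), "stitching left uncovered voxels"
    fused = acc / cov
    nz, ny, nx = chunks.source_shape
    fused = fused[:nz, :ny, :nx]
    fused = np.clip(fused, 0.0, 1.0).astype(np.float32)
    prov = {
        "chunk_size": chunk_size,
        "stride": stride,
        "cosine_window": cosine_window,
        "backbone": type(backbone).__name__,
    }
    prov.update(provenance or {})
    return ConfidenceMap(Volume(fused, voxel_size=volume.voxel_size, origin=volume.origin), prov)
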