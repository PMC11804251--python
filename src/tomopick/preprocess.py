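"""Tomogram preprocessing: rescaling, robust normalization, chunking, balancing.

Tomograms are resampled so the target particle spans a fixed number of pixels
(10 by default), intensity-normalized with a robust median/IQR statistic, and
cut into overlapping cubes (64^3, stride 32 by default) for training.  Because
almost all voxels of a tomogram are background, cubes containing no positive
label voxel vastly outnumber the rest; training keeps every positive cube and
an equal number of randomly sampled negative cubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Volume

__all__ = [
    "ChunkSet",
    "compute_scale",
    "resize_volume",
    "robust_normalize",
    "chunk_volume",
    "balance_chunks",
]

DEFAULT_TARGET_PARTICLE_PX = 10
DEFAULT_CHUNK_SIZE = 64
DEFAULT_STRIDE = 32


@dataclass
class ChunkSet:
    """Overlapping cubic chunks cut from one volume.

    ``origins[i]`` is the (z, y, x) offset of ``cubes[i]`` within the (possibly
    padded) source volume; ``padding`` records per-axis zero padding applied to
    volumes smaller than one chunk so chunks can be mapped back.
    """

    origins: list[tuple[int, int, int]]
    cubes: list[np.ndarray]
    chunk_size: int
    stride: int
    source_shape: tuple[int, int, int]
    padding: tuple[int, int, int] = (0, 0, 0)

    def __len__(self) -> int:
        return len(self.cubes)

    def __iter__(self):
        return iter(zip(self.origins, self.cubes))


def compute_scale(
    voxel_size: float,
    diameter: float,
    target_particle_px: float = DEFAULT_TARGET_PARTICLE_PX,
) -> float:
    """Scale factor that brings the particle to ``target_particle_px`` voxels.

    ``scale = target_particle_px / (diameter / voxel_size)``; the rescaled
    volume has voxel size ``voxel_size / scale``.  ``diameter`` refers to the
    particle diameter (longest axis) in Angstrom.
    """
    if voxel_size <= 0 or diameter <= 0 or target_particle_px <= 0:
        raise ValueError("voxel_size, diameter and target_particle_px must all be > 0")
    return target_particle_px / (diameter / voxel_size)


def resize_volume(volume: Volume, scale: float) -> Volume:
    """Trilinear resampling by ``scale`` (Gaussian anti-alias filter when < 1).

    Output dims are ``round(dim * scale)``; the voxel size is divided by the
    scale so physical extent is preserved.  Constant volumes stay constant.
    """
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if scale == 1.0:
        return volume.copy()
    out_shape = tuple(int(round(s * scale)) for s in volume.shape)
    if min(out_shape) < 1:
        raise ValueError(f"scale {scale} collapses shape {volume.shape} to {out_shape}")
    data = volume.data
    if scale < 1.0:
        # variance-matching anti-alias sigma: blur so one output voxel carries
        # the variance of the (1/scale)-voxel neighbourhood it replaces
        sigma = np.sqrt((1.0 / scale) ** 2 - 1.0) / 2.0
        data = ndimage.gaussian_filter(data.astype(np.float64), sigma=sigma, mode="nearest")
    zoomed = ndimage.zoom(data.astype(np.float64), zoom=scale, order=1, mode="nearest")
    assert zoomed.shape == out_shape
    return Volume(zoomed.astype(np.float32), voxel_size=volume.voxel_size / scale, origin=volume.origin)


def robust_normalize(volume: Volume) -> Volume:
    """Normalize to ``(x - median) / IQR`` with IQR the 75th - 25th percentile.

    After normalization the median is ~0 and the IQR ~1, making intensity
    statistics comparable across tomograms regardless of reconstruction
    software or filtering.  Constant (zero-IQR) volumes are rejected.
    """
    data = volume.data.astype(np.float64)
    median = np.median(data)
    q25, q75 = np.percentile(data, [25, 75])
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError(
            "interquartile range is zero (constant or near-constant volume); "
            "check the input tomogram — normalization needs intensity spread"
        )
    out = (data - median) / iqr
    return Volume(out.astype(np.float32), voxel_size=volume.voxel_size, origin=volume.origin)


def _axis_origins(dim: int, chunk_size: int, stride: int) -> list[int]:
    origins = list(range(0, dim - chunk_size + 1, stride))
    if origins[-1] + chunk_size < dim:
        origins.append(dim - chunk_size)  # clamped final window for full coverage
    return origins


def chunk_volume(
    volume: Volume | np.ndarray,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> ChunkSet:
    """Split a volume into overlapping ``chunk_size``^3 cubes.

    Per axis the origins are 0, stride, 2*stride, ... plus a final clamped
    origin at ``dim - chunk_size`` whenever the last strided window stops
    short of the boundary, so every voxel is covered by at least one chunk.
    Volumes smaller than one chunk are zero-padded up to ``chunk_size`` (the
    padding is recorded on the returned set).
    """
    if chunk_size < 1 or stride < 1:
        raise ValueError("chunk_size and stride must be >= 1")
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float32)
    source_shape = data.shape
    pad = tuple(max(0, chunk_size - s) for s in data.shape)
    if any(pad):
        data = np.pad(data, [(0, p) for p in pad], mode="constant")
    origins_per_axis = [_axis_origins(d, chunk_size, stride) for d in data.shape]
    origins: list[tuple[int, int, int]] = []
    cubes: list[np.ndarray] = []
    for oz in origins_per_axis[0]:
        for oy in origins_per_axis[1]:
            for ox in origins_per_axis[2]:
                origins.append((oz, oy, ox))
                cubes.append(
                    data[oz : oz + chunk_size, oy : oy + chunk_size, ox : ox + chunk_size].copy()
                )
    return ChunkSet(origins, cubes, chunk_size, stride, source_shape, pad)


def balance_chunks(
    image_chunks: ChunkSet, label_chunks: ChunkSet, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair image/label cubes and balance positives against negatives.

    A cube is positive when its label contains any voxel > 0.  All positive
    cubes are kept; ``min(#positives, #negatives)`` negative cubes are sampled
    uniformly without replacement with the given seed.  Returns a list of
    ``(image_cube, label_cube)`` pairs, positives first.
    """
    if image_chunks.origins != label_chunks.origins:
        raise ValueError("image and label chunk grids are not congruent")
    pos_idx = [i for i, cube in enumerate(label_chunks.cubes) if np.any(cube > 0)]
    neg_idx = [i for i in range(len(label_chunks)) if i not in set(pos_idx)]
    if not pos_idx:
        raise ValueError("no positive chunks: every label cube is empty, nothing to train on")
    rng = np.random.default_rng(seed)
    n_neg = min(len(pos_idx), len(neg_idx))
    chosen_neg = sorted(rng.choice(len(neg_idx), size=n_neg, replace=False).tolist()) if n_neg else []
    selected = pos_idx + [neg_idx[j] for j in chosen_neg]
    return [(image_chunks.cubes[i], label_chunks.cubes[i]) for i in selected]
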