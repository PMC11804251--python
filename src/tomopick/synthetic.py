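"""Synthetic phantom tomograms with exactly known centroids.

Phantoms are fields of uniform solid spheres on a flat background with
additive Gaussian noise, optionally blurred anisotropically along Z to mimic
the missing-wedge elongation of real tomograms.  Spheres are dark on a light
background by default, matching the density convention of cryo-ET
reconstructions.  The particles are deliberately simple shapes rather than
projected molecular densities: the pipeline under test is shape-agnostic
centroid detection, and spheres make the ground truth exact.

SNR here is defined as (density contrast)^2 / noise variance — "SNR" is used
loosely in the field, so the definition is fixed and documented.  Real
cryo-ET data sits at SNR well below 0.1; the defaults are more benign so that
desk-scale models can be exercised end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ParticleSet, Volume

__all__ = ["PhantomParams", "simulate_tomogram"]

_PLACEMENT_RETRY_BUDGET = 10_000


@dataclass(frozen=True)
class PhantomParams:
    """Conditions of one phantom tomogram.

    shape : volume dims in voxels, (z, y, x).
    n_particles : spheres to place.
    radius_px : sphere radius in voxels.
    density_contrast : particle-minus-background amplitude; negative means
        dark particles (the cryo-ET convention).
    snr : contrast^2 / noise-variance target for the additive Gaussian noise.
    min_separation : minimum center-to-center distance (default 2*radius_px,
        i.e. non-overlapping spheres).
    wedge_blur : optional (sigma_z, sigma_y, sigma_x) Gaussian blur with
        sigma_z >= sigma_xy, emulating missing-wedge elongation.
    voxel_size : Angstrom per pixel of the phantom grid.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    n_particles: int = 15
    radius_px: float = 5.0
    density_contrast: float = -1.0
    snr: float = 0.5
    min_separation: float | None = None
    wedge_blur: tuple[float, float, float] | None = None
    voxel_size: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.radius_px < 1:
            raise ValueError(f"radius_px must be >= 1, got {self.radius_px}")
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")
        if self.min_separation is not None and self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if min(self.shape) < 1:
            raise ValueError(f"degenerate shape {self.shape}")

    @property
    def separation(self) -> float:
        return 2.0 * self.radius_px if self.min_separation is None else self.min_separation

    @property
    def diameter(self) -> float:
        """Particle diameter in Angstrom."""
        return 2.0 * self.radius_px * self.voxel_size


def _place_centers(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer-grid centers with pairwise separation and full
    containment of the radius-R sphere inside the volume."""
    margin = int(np.ceil(params.radius_px))
    los = [margin] * 3
    his = [s - 1 - margin for s in params.shape]
    if any(hi < lo for lo, hi in zip(los, his)):
        raise ValueError(
            f"shape {params.shape} cannot contain a sphere of radius {params.radius_px}"
        )
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < params.n_particles:
        if attempts >= _PLACEMENT_RETRY_BUDGET:
            raise RuntimeError(
                f"could not place {params.n_particles} spheres of radius {params.radius_px} "
                f"with separation {params.separation} in shape {params.shape} after "
                f"{_PLACEMENT_RETRY_BUDGET} attempts; reduce n_particles or min_separation"
            )
        attempts += 1
        cand = np.array([rng.integers(lo, hi + 1) for lo, hi in zip(los, his)], dtype=np.float64)
        if all(np.linalg.norm(cand - c) >= params.separation for c in centers):
            centers.append(cand)
    if centers:
        return np.stack(centers)  # (n, 3) in (z, y, x)
    return np.zeros((0, 3))


def simulate_tomogram(params: PhantomParams) -> tuple[Volume, ParticleSet]:
    """Generate one phantom tomogram and its exact ground-truth centroids.

    Deterministic for a fixed seed.  The returned :class:`ParticleSet` holds
    the placed centers (x, y, z, voxel units) with diameter ``2 * radius_px *
    voxel_size`` Angstrom, so the standard preprocessing arrives back at the
    native grid when the target particle size equals ``2 * radius_px``.
    """
    rng = np.random.default_rng(params.seed)
    centers_zyx = _place_centers(params, rng)
    clean = np.zeros(params.shape, dtype=np.float64)
    if len(centers_zyx):
        zz, yy, xx = np.indices(params.shape, sparse=True)
        for cz, cy, cx in centers_zyx:
            r2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            clean[r2 <= params.radius_px**2] = params.density_contrast
    if params.wedge_blur is not None:
        sz, sy, sx = params.wedge_blur
        if sz < max(sy, sx):
            raise ValueError("wedge_blur must elongate along z (sigma_z >= sigma_xy)")
        clean = ndimage.gaussian_filter(clean, sigma=(sz, sy, sx), mode="nearest")
    noise_std = abs(params.density_contrast) / np.sqrt(params.snr)
    noisy = clean + rng.normal(0.0, noise_std, size=params.shape)
    volume = Volume(noisy.astype(np.float32), voxel_size=params.voxel_size)
    coords_xyz = centers_zyx[:, ::-1] if len(centers_zyx) else np.zeros((0, 3))
    particles = ParticleSet(
        coords_xyz,
        diameter=params.diameter,
        voxel_size=params.voxel_size,
        tomo_id=f"phantom_seed{params.seed}",
    )
    return volume, particles
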