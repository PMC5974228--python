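"""Automatic seed placement at region centers of mass.

A seed is a small fixed-size voxel set (default 5 voxels) chosen inside
a region, restricted to the region's central z-slice — the constraint
exists because acquisition voxels are typically highly anisotropic in
the slice direction, so mixing slices would mix poorly matched tissue.
Distances are measured in millimetres (voxel-size scaled), making the
placement robust to anisotropic grids; ties are broken by lexicographic
voxel coordinate so placement is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import BoldSeries, LabelAtlas

__all__ = ["SeedSet", "place_seed", "place_all_seeds", "seed_timecourse"]

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Seed voxels of one region: all in-region, all on one z-slice."""

    region_id: int
    voxels: np.ndarray  # (n, 3) integer voxel coordinates
    centroid: np.ndarray  # (3,) center of mass in voxel units
    plane_z: int
    truncated: bool = False  # region had fewer in-plane voxels than requested

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]


def place_seed(atlas: LabelAtlas, region_id: int, seed_size: int = 5) -> SeedSet:
    """Place a seed of up to ``seed_size`` voxels in one region.

    The anchor is the in-region voxel nearest (Euclidean, in mm) to the
    region's center of mass, restricted to the region's central plane:
    the z-slice closest to the center-of-mass z coordinate that contains
    at least one region voxel (ties toward the lower slice).  The
    remaining voxels are the next-nearest in-region voxels on that
    plane.  Regions with fewer in-plane voxels than ``seed_size`` yield
    all of them, flagged ``truncated``.
    """
    if seed_size < 1:
        raise ValueError("seed_size must be positive")
    coords = atlas.region_voxels(region_id)  # raises KeyError if absent
    scale = np.asarray(atlas.voxel_size, dtype=float)
    centroid = coords.mean(axis=0)
    z_values = np.unique(coords[:, 2])
    # central plane: occupied z-slice nearest the center of mass (mm),
    # ties broken toward the lower slice index
    z_dist = np.abs((z_values - centroid[2]) * scale[2])
    plane_z = int(z_values[np.argmin(z_dist)])
    in_plane = coords[coords[:, 2] == plane_z]
    dist = np.linalg.norm((in_plane - centroid) * scale, axis=1)
    order = np.lexsort((in_plane[:, 2], in_plane[:, 1], in_plane[:, 0], dist))
    n_take = min(seed_size, in_plane.shape[0])
    truncated = n_take < seed_size
    if truncated:
        logger.warning(
            "region %d has only %d voxels on its central plane (requested %d)",
            region_id,
            n_take,
            seed_size,
        )
    return SeedSet(
        region_id=int(region_id),
        voxels=in_plane[order[:n_take]],
        centroid=centroid,
        plane_z=plane_z,
        truncated=truncated,
    )


def place_all_seeds(atlas: LabelAtlas, seed_size: int = 5) -> dict[int, SeedSet]:
    """Place one seed per atlas region; deterministic."""
    return {int(r): place_seed(atlas, int(r), seed_size) for r in atlas.region_ids}


def seed_timecourse(series: BoldSeries, seed: SeedSet) -> np.ndarray:
    """Unweighted mean time-course over the seed voxels."""
    vox = seed.voxels
    shape = series.data.shape[:3]
    if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
        raise ValueError(f"seed of region {seed.region_id} has voxels outside the volume")
    if not series.brain_mask[vox[:, 0], vox[:, 1], vox[:, 2]].all():
        raise ValueError(f"seed of region {seed.region_id} has voxels outside the brain mask")
    return series.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
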