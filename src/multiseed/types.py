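"""Core in-memory containers shared across the pipeline.

The pipeline operates on three kinds of objects: a :class:`LabelAtlas`
(integer parcellation volume), a :class:`BoldSeries` (4D voxel
time-series with acquisition metadata), and a :class:`ConnectivityMatrix`
(region-by-region correlation or Fisher-z matrix in which a zero entry
means "not significant").  Module-specific result types (seed sets,
graphs, pNBS results, ...) live next to the code that produces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelAtlas", "BoldSeries", "ConnectivityMatrix"]


@dataclass
class LabelAtlas:
    """3D integer parcellation: 0 = background, 1..R = region ids.

    Parameters
    ----------
    labels
        3D integer array of region labels.
    voxel_size
        Physical voxel extents ``(dx, dy, dz)`` in millimetres.
    region_names
        Optional mapping of region id to a human-readable name.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    region_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-typed")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("region ids must be contiguous starting at 1")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region_voxels(self, region_id: int) -> np.ndarray:
        """Voxel coordinates of one region as an (n, 3) integer array."""
        coords = np.argwhere(self.labels == region_id)
        if coords.size == 0:
            raise KeyError(f"region {region_id} not present in atlas")
        return coords

    def foreground_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class BoldSeries:
    """4D BOLD volume (x, y, z, t) with repetition time and brain mask."""

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 3:
            raise ValueError("need at least 3 time points")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain mask shape must match spatial grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def copy_with(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(
            data=data,
            tr=self.tr,
            voxel_size=self.voxel_size,
            brain_mask=self.brain_mask.copy(),
        )


@dataclass
class ConnectivityMatrix:
    """Region-by-region connectivity; zeros mean "not significant".

    ``directed`` is True for the pseudo-directed multi-seed matrix and
    False for the symmetric seed/region cross-correlation matrices.
    ``fdr_threshold_r`` records the realized correlation magnitude at the
    FDR significance boundary (the mean across seed maps for the directed
    method, where each seed's whole-brain map has its own boundary).
    """

    values: np.ndarray
    directed: bool
    scale: str = "pearson_r"  # or "fisher_z"
    fdr_q: float | None = None
    fdr_threshold_r: float | None = None
    region_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    invalid_regions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError("scale must be 'pearson_r' or 'fisher_z'")
        if self.region_ids is None:
            self.region_ids = np.arange(1, self.values.shape[0] + 1)
        else:
            self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.size != self.values.shape[0]:
            raise ValueError("region_ids length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def check(self) -> None:
        """Assert structural invariants (zero diagonal, symmetry, range)."""
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if not self.directed and not np.allclose(self.values, self.values.T):
            raise ValueError("undirected matrix must be symmetric")
        if self.scale == "pearson_r" and np.any(np.abs(self.values) >= 1.0):
            raise ValueError("pearson_r entries must lie in (-1, 1)")
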