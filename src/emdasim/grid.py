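"""Regular voxel grids and labelled volumes.

All grid metadata is carried in millimetres (the native unit of medical
segmentations); physical quantities elsewhere in the package are SI.
World coordinates are right-handed with +z superior and +y anterior;
voxel membership is decided by voxel *centers*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "ConductivityVolume",
    "TISSUE_NAMES",
]

#: Tissue / structure classes a LabelVolume legend may use.
TISSUE_NAMES = frozenset(
    {
        "bladder_wall",
        "bladder_lumen",
        "prostate",
        "fat",
        "muscle",
        "intestines",
        "bone",
        "internal_air",
        "balloon",
        "electrode_helix",
        "electrode_patch",
        "skin",
        "background",
    }
)


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel edge lengths in millimetres.
    origin
        World coordinate (mm) of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    # ------------------------------------------------------------------ #
    def world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices; ``index`` shape (..., 3)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def index(self, world: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world coordinates (mm)."""
        world = np.asarray(world, dtype=float)
        frac = (world - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.rint(frac).astype(int)

    def axis_coords(self, axis: int) -> np.ndarray:
        """1-D world coordinates (mm) of voxel centers along ``axis``."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (mm), one per axis."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class LabelVolume:
    """Integer tissue labels on a :class:`VoxelGrid` with a label legend."""

    grid: VoxelGrid
    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels present but absent from legend: {sorted(missing)}")
        bad = set(self.legend.values()) - TISSUE_NAMES
        if bad:
            raise ValueError(f"unknown tissue names in legend: {sorted(bad)}")

    def label_of(self, tissue: str) -> int | None:
        """Integer label for a tissue name, or None if not in the legend."""
        for lab, name in self.legend.items():
            if name == tissue:
                return lab
        return None

    def mask(self, tissue: str) -> np.ndarray:
        """Boolean mask of voxels carrying ``tissue`` (all-False if absent)."""
        lab = self.label_of(tissue)
        if lab is None:
            return np.zeros(self.grid.shape, dtype=bool)
        return self.labels == lab


@dataclass
class ConductivityVolume:
    """Per-voxel scalar conductivity with an excluded-insulator mask.

    ``sigma`` is in S/m.  Excluded voxels (perfect insulators: catheter
    balloon, internal air, exterior) carry no unknowns in the solve and
    their sigma values are ignored.
    """

    grid: VoxelGrid
    sigma: np.ndarray
    excluded: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.sigma.shape != self.grid.shape or self.excluded.shape != self.grid.shape:
            raise ValueError("sigma/excluded shape must match grid shape")
        active = ~self.excluded
        if np.any(self.sigma[active] <= 0):
            raise ValueError("sigma must be > 0 on all non-excluded voxels")
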