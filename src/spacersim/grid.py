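"""Voxel-grid containers shared by every stage of the pipeline.

Arrays are indexed ``(x, y, z)`` and live on a regular axis-aligned grid:
``world_mm = origin + index * spacing``.  All masks and dose grids belonging
to one case share a single :class:`VoxelGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import numpy as np

#: structures every generated case must carry
REQUIRED_STRUCTURES = (
    "GTV",
    "GTV_multabc",
    "PTV",
    "HOP",
    "D1",
    "D2",
    "D3",
    "D4",
    "duodenum",
    "stomach",
    "bowel",
)

DUODENAL_SECTIONS = ("D1", "D2", "D3", "D4")


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel size in mm along each axis; strictly positive.
    origin : tuple of float
        World coordinate (mm) of voxel index (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 on all axes, got {self.spacing}")

    # -- geometry helpers -------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def world_coordinates(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (broadcastable via ``np.meshgrid``)."""
        return tuple(
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i] for i in range(3)
        )

    def dense_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        ax = self.world_coordinates()
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        return np.stack([xs, ys, zs], axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def check_mask(self, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.shape:
            raise GridMismatchError(
                f"mask shape {mask.shape} does not conform to grid {self.shape}"
            )
        return mask.astype(bool)

    def same_as(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def mask_centroid_mm(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """World-coordinate centroid of a nonempty binary mask."""
    idx = np.argwhere(grid.check_mask(mask))
    if idx.size == 0:
        raise ValueError("centroid of an empty mask is undefined")
    return grid.index_to_world(idx.mean(axis=0))[0]


def mask_volume_cc(mask: np.ndarray, grid: VoxelGrid) -> float:
    return float(np.count_nonzero(grid.check_mask(mask))) * grid.voxel_volume_cc


@dataclass
class StructureSet:
    """Named binary masks on one grid: the anatomical state of a case.

    Required names are listed in :data:`REQUIRED_STRUCTURES`; ``spacer`` and
    ``duodenum_lumen`` are optional.  D1–D4 are pairwise disjoint full-tube
    sections whose union is ``duodenum``; the wall used for finite-element
    meshing is ``duodenum & ~duodenum_lumen``.
    """

    grid: VoxelGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterator[str]:
        return iter(self.masks)

    def add(self, name: str, mask: np.ndarray) -> None:
        self.masks[name] = self.grid.check_mask(mask)

    def volume_cc(self, name: str) -> float:
        return mask_volume_cc(self.masks[name], self.grid)

    def centroid_mm(self, name: str) -> np.ndarray:
        return mask_centroid_mm(self.masks[name], self.grid)

    def copy(self) -> "StructureSet":
        return StructureSet(
            grid=self.grid,
            masks={k: v.copy() for k, v in self.masks.items()},
            meta=dict(self.meta),
        )

    def duodenum_wall(self) -> np.ndarray:
        """Wall mask (tube minus lumen), used for hollow-organ meshing."""
        wall = self.masks["duodenum"] & ~self.masks.get(
            "duodenum_lumen", np.zeros(self.grid.shape, bool)
        )
        return wall

    def validate(self, require_all: bool = True) -> None:
        """Raise if the structure-set invariants are violated."""
        for name, mask in self.masks.items():
            if mask.shape != self.grid.shape:
                raise GridMismatchError(f"{name}: shape {mask.shape} != grid {self.grid.shape}")
        if require_all:
            missing = [n for n in REQUIRED_STRUCTURES if n not in self.masks]
            if missing:
                raise ValueError(f"missing required structures: {missing}")
        sections = [self.masks[s] for s in DUODENAL_SECTIONS if s in self.masks]
        if len(sections) == 4:
            total = np.zeros(self.grid.shape, dtype=np.int16)
            for s in sections:
                total += s.astype(np.int16)
            if total.max() > 1:
                raise ValueError("duodenal sections D1..D4 are not pairwise disjoint")
            if "duodenum" in self.masks and not np.array_equal(
                total.astype(bool), self.masks["duodenum"]
            ):
                raise ValueError("duodenum mask does not equal the union of D1..D4")
        for inner, outer in (("GTV", "GTV_multabc"), ("GTV_multabc", "PTV")):
            if inner in self.masks and outer in self.masks:
                if np.any(self.masks[inner] & ~self.masks[outer]):
                    raise ValueError(f"{inner} is not contained in {outer}")


@dataclass
class DoseGrid:
    """Absorbed-dose distribution in Gy on a voxel grid.

    ``prescription`` is the total prescribed dose and ``fractions`` the
    number of fractions (default SBRT regimen: 33 Gy in 5 fractions).
    """

    grid: VoxelGrid
    dose: np.ndarray
    prescription: float = 33.0
    fractions: int = 5
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.shape != self.grid.shape:
            raise GridMismatchError(
                f"dose shape {self.dose.shape} != grid {self.grid.shape}"
            )
        if np.any(self.dose < 0) or not np.all(np.isfinite(self.dose)):
            raise ValueError("dose must be finite and non-negative everywhere")
        if self.fractions < 1:
            raise ValueError("fractions must be a positive integer")

    @property
    def dose_per_fraction(self) -> float:
        return self.prescription / self.fractions

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(
            grid=self.grid,
            dose=self.dose * float(factor),
            prescription=self.prescription,
            fractions=self.fractions,
            meta=dict(self.meta),
        )
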