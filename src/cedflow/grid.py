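"""Regular voxel grids and the scalar/vector fields that live on them.

Everything in the simulator — pore fraction, pressure, conductivity,
concentrations — is stored cell-centered on a single :class:`VoxelGrid`.
World coordinates are millimetres; the voxel-to-world map is an affine
(diagonal scaling + translation unless a full affine is supplied, e.g.
read from a NIfTI header).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["VoxelGrid", "ScalarField", "VectorField"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D cell-centered grid.

    Parameters
    ----------
    shape
        Number of voxels per axis, each >= 3.
    spacing
        Voxel edge length per axis in mm, strictly positive.
    origin
        World coordinate (mm) of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(n < 3 for n in shape):
            raise ValueError(f"grid shape must be a triple >= (3,3,3), got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        if self.affine is None:
            aff = np.eye(4)
            aff[:3, :3] = np.diag(spacing)
            aff[:3, 3] = origin
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)

    # -- geometry -----------------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to world mm via the affine."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        return (self.affine @ hom.T).T[:, :3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (…, 3) world-mm points to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        hom = np.c_[pts, np.ones(len(pts))]
        return (inv @ hom.T).T[:, :3]

    def contains_index(self, ijk: Sequence[int]) -> bool:
        return all(0 <= int(i) < n for i, n in zip(ijk, self.shape))

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate meshgrid (mm) of all voxel centers."""
        idx = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        flat = np.stack([a.ravel() for a in idx], axis=1)
        world = self.index_to_world(flat)
        return tuple(world[:, k].reshape(self.shape) for k in range(3))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


def _check_field(grid: VoxelGrid, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(
            f"field shape {values.shape} does not match grid shape {grid.shape}"
        )
    return values


@dataclass
class ScalarField:
    """One real value per voxel with a declared unit string."""

    grid: VoxelGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = _check_field(self.grid, self.values)

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.units)


@dataclass
class VectorField:
    """One 3-vector per voxel, stored as a (3, nx, ny, nz) array."""

    grid: VoxelGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (3,) + self.grid.shape:
            raise ValueError(
                f"vector field shape {values.shape} != (3,)+{self.grid.shape}"
            )
        self.values = values

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.values**2).sum(axis=0))
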