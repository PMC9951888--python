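"""Voxel grid container: a 3D scalar or binary volume with mm geometry.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)`` triples indexing ``values``.
* ``origin`` is the world-mm coordinate of the *center* of voxel
  ``(0, 0, 0)``; voxel ``(i, j, k)`` has its center at
  ``origin + (i, j, k) * spacing``.
* All world coordinates are millimetres; axes follow the file affine
  (RAS assumed for orientation hints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """3D volume with spacing and origin; carrier of CT and mask data."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(
                f"VoxelGrid values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValidationError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world-mm voxel centers."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel coordinates."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    # -- content ------------------------------------------------------------

    def is_binary(self) -> bool:
        vals = np.unique(self.values)
        return bool(np.isin(vals, (0, 1)).all())

    def require_binary(self) -> None:
        if not self.is_binary():
            raise ValidationError("expected a binary mask (values in {0, 1})")

    def foreground_indices(self) -> np.ndarray:
        """(n, 3) array of 0-based indices of nonzero voxels."""
        return np.argwhere(self.values)

    def foreground_world(self) -> np.ndarray:
        """(n, 3) world-mm centers of nonzero voxels."""
        return self.voxel_to_world(self.foreground_indices())

    def count_foreground(self) -> int:
        return int(np.count_nonzero(self.values))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return VoxelGrid(values=values, spacing=self.spacing, origin=self.origin)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(values=self.values.copy(), spacing=self.spacing,
                         origin=self.origin)
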