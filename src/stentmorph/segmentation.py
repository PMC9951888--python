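"""Classical stent segmentation from HU volumes and mask-overlap scoring.

The in-repo segmentation path is a fixed HU threshold band (default
1200-2200 HU, inclusive at both ends) followed by connectivity-based
region selection; stent metal sits well above the 300-700 HU
contrast-filled lumen. Externally produced binary masks (e.g. from a
learned model) can enter the pipeline directly — nothing downstream
depends on how the mask was made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .grid import VoxelGrid

__all__ = [
    "SegmentationReport",
    "resample_isotropic",
    "threshold_segment",
    "select_stent_region",
    "dice_score",
    "connectivity_structure",
]

log = logging.getLogger(__name__)

DEFAULT_LO_HU = 1200.0
DEFAULT_HI_HU = 2200.0


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3D neighbourhood structure; 26 (diagonal-inclusive) by default, since
    thin oblique stent wires fragment under 6-connectivity."""
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValidationError(f"connectivity must be 6, 18 or 26, got {connectivity}")


@dataclass(frozen=True)
class SegmentationReport:
    """Overlap between two binary masks on the same grid."""

    dice: float
    n_a: int
    n_b: int
    n_intersection: int

    @property
    def dice_loss(self) -> float:
        return 1.0 - self.dice


def resample_isotropic(volume: VoxelGrid, target: float = 1.0) -> VoxelGrid:
    """Resample to isotropic spacing: trilinear for HU volumes, nearest
    neighbour for binary masks. The center of voxel (0,0,0) is kept fixed,
    so world extent is preserved to within one voxel."""
    if target <= 0:
        raise ValidationError(f"target spacing must be > 0, got {target}")
    if volume.values.size == 0:
        raise ValidationError("cannot resample an empty volume")
    spacing = np.asarray(volume.spacing)
    if np.allclose(spacing, target):
        return volume.copy()

    binary = volume.is_binary()
    order = 0 if binary else 1
    dims_out = np.maximum(
        np.round((np.asarray(volume.dims) - 1) * spacing / target).astype(int) + 1,
        1)
    # output voxel i sits at input index i * target / spacing (per axis)
    axes = [np.arange(n) * target / s for n, s in zip(dims_out, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    values = ndimage.map_coordinates(
        volume.values.astype(np.float64), np.array(coords), order=order,
        mode="nearest")
    if binary:
        values = values.astype(np.uint8)
    return VoxelGrid(values=values, spacing=(target,) * 3, origin=volume.origin)


def threshold_segment(volume: VoxelGrid, lo: float = DEFAULT_LO_HU,
                      hi: float = DEFAULT_HI_HU) -> VoxelGrid:
    """Binary mask of voxels with lo <= HU <= hi (both bounds inclusive)."""
    if lo > hi:
        raise ValidationError(f"threshold lo ({lo}) exceeds hi ({hi})")
    values = ((volume.values >= lo) & (volume.values <= hi)).astype(np.uint8)
    mask = volume.with_values(values)
    if not values.any():
        log.warning("threshold [%g, %g] produced an empty mask", lo, hi)
    return mask


def select_stent_region(mask: VoxelGrid, mode: str = "largest",
                        seed_mm: tuple[float, float, float] | None = None,
                        volume_fraction: float = 0.1,
                        connectivity: int = 26) -> VoxelGrid:
    """Keep the stent's connected components and drop speckle.

    mode="largest": keep every component whose voxel count is at least
    ``volume_fraction`` of the largest component's — a stent made of
    disjoint rings survives while small speckle is removed.
    mode="seed": keep only the component containing the world-mm seed.
    """
    mask.require_binary()
    if not mask.values.any():
        raise ValidationError("cannot select regions in an empty mask")
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.values, structure=structure)
    sizes = np.bincount(labels.ravel())[1:]  # skip background

    if mode == "largest":
        keep = np.flatnonzero(sizes >= volume_fraction * sizes.max()) + 1
    elif mode == "seed":
        if seed_mm is None:
            raise ValidationError("seed mode requires a seed point")
        idx = np.round(mask.world_to_voxel(np.asarray(seed_mm))).astype(int)
        if (np.any(idx < 0) or np.any(idx >= np.asarray(mask.dims))
                or labels[tuple(idx)] == 0):
            raise ValidationError(
                f"seed point {tuple(seed_mm)} lies outside every component")
        keep = np.array([labels[tuple(idx)]])
    else:
        raise ValidationError(f"unknown selection mode {mode!r}")

    values = np.isin(labels, keep).astype(np.uint8)
    log.info("region selection: %d of %d components kept (%d of %d voxels)",
             len(keep), n, int(values.sum()), int(sizes.sum()))
    return mask.with_values(values)


def dice_score(a: VoxelGrid, b: VoxelGrid) -> SegmentationReport:
    """Dice = 2|A∩B| / (|A|+|B|); empty vs empty defined as dice 1."""
    if not a.same_geometry(b):
        raise ValidationError("dice_score requires identical grid geometry")
    a.require_binary()
    b.require_binary()
    na = a.count_foreground()
    nb = b.count_foreground()
    inter = int(np.count_nonzero((a.values > 0) & (b.values > 0)))
    dice = 1.0 if (na + nb) == 0 else 2.0 * inter / (na + nb)
    return SegmentationReport(dice=dice, n_a=na, n_b=nb, n_intersection=inter)
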