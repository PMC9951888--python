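"""Support-ring separation, ring centers and the stent centerline.

The mask is split into 26-connected components (one per support ring for
a ring-built stent), small components are dropped as speckle, rings are
ordered proximal-to-distal along the principal axis of their centroids,
and an interpolating cubic spline through the ordered centroids provides
the local tangent frame used by landmark extraction.

Two distinct "ring center" notions are exposed: the voxel-mass centroid
of a component (default for centerline fitting) and the peak-based
``point_mid`` (arithmetic mean of a ring's peak points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline
from scipy import ndimage

from .errors import ValidationError
from .grid import VoxelGrid
from .segmentation import connectivity_structure

__all__ = [
    "RingComponent",
    "Centerline",
    "label_rings",
    "point_mid",
    "ring_centroid",
    "order_rings",
    "fit_centerline",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_VOLUME_VOXELS = 50


@dataclass
class RingComponent:
    """One connected support-ring region of the mask."""

    label: int
    voxel_indices: np.ndarray      # (n, 3) 0-based indices
    volume_voxels: int
    volume_mm3: float
    centroid: np.ndarray           # (3,) world mm, voxel-mass centroid
    ring_index: int | None = None  # 1..M proximal->distal once ordered


@dataclass
class Centerline:
    """Interpolating spline through ordered ring centroids.

    Parameterised by cumulative chord length; passes through every control
    point exactly. Natural end conditions for the cubic case. The tangent
    points from proximal (t=0) toward distal."""

    control_points: np.ndarray     # (m, 3) ordered ring centroids
    t_controls: np.ndarray         # (m,) chord-length parameters
    _spline: object = field(repr=False, default=None)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return np.atleast_2d(self._spline(np.atleast_1d(t)))

    def tangent(self, t: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(self._spline(np.atleast_1d(t), 1))
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValidationError("degenerate centerline tangent")
        return d / norms


def label_rings(mask: VoxelGrid,
                min_volume_voxels: int = DEFAULT_MIN_VOLUME_VOXELS,
                connectivity: int = 26) -> list[RingComponent]:
    """Connected components with volume >= min_volume_voxels, sorted by
    label; sub-threshold components are logged and dropped."""
    mask.require_binary()
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.values, structure=structure)
    if n == 0:
        raise ValidationError("mask contains no foreground components")
    components: list[RingComponent] = []
    dropped = 0
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_volume_voxels:
            dropped += 1
            log.info("dropping component %d: %d voxels < min volume %d",
                     lab, len(idx), min_volume_voxels)
            continue
        world = mask.voxel_to_world(idx)
        components.append(RingComponent(
            label=lab, voxel_indices=idx, volume_voxels=len(idx),
            volume_mm3=len(idx) * mask.voxel_volume_mm3,
            centroid=world.mean(axis=0)))
    if not components:
        raise ValidationError(
            f"all {n} components fell below min_volume_voxels={min_volume_voxels}")
    if dropped:
        log.info("dropped %d sub-threshold components", dropped)
    return components


def point_mid(points: np.ndarray) -> np.ndarray:
    """Ring midpoint: component-wise arithmetic mean of peak coordinates."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValidationError("point_mid of an empty point list")
    return pts.mean(axis=0)


def ring_centroid(component: RingComponent, grid: VoxelGrid) -> np.ndarray:
    """Voxel-mass centroid in world mm (distinct from peak-based point_mid)."""
    if component.volume_voxels == 0:
        raise ValidationError("empty ring component")
    return grid.voxel_to_world(component.voxel_indices).mean(axis=0)


def order_rings(components: list[RingComponent],
                axis_hint: np.ndarray | None = None
                ) -> list[RingComponent]:
    """Assign ring_index 1..M from proximal to distal.

    Centroids are projected on the first principal direction of the
    centroid cloud, oriented toward ``axis_hint`` (a direction vector, or a
    proximal point; defaults to +z, the superior direction in RAS). Ring 1
    has the largest projection; ties break by label order.
    """
    if not components:
        raise ValidationError("no components to order")
    ordered = sorted(components, key=lambda c: c.label)
    if len(ordered) == 1:
        ordered[0].ring_index = 1
        return ordered

    centroids = np.array([c.centroid for c in ordered])
    centered = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]

    if axis_hint is None:
        hint_dir = np.array([0.0, 0.0, 1.0])
    else:
        hint = np.asarray(axis_hint, dtype=float)
        # a point far from the centroid cloud is treated as a proximal
        # location; otherwise as a direction
        hint_dir = hint - centroids.mean(axis=0) if np.linalg.norm(hint) > 0 \
            and _looks_like_point(hint, centroids) else hint
        if np.linalg.norm(hint_dir) == 0:
            raise ValidationError("axis hint must be a nonzero vector or point")
    if np.dot(axis, hint_dir) < 0:
        axis = -axis

    proj = centroids @ axis
    # most proximal (largest projection toward the hint) gets index 1;
    # stable sort keeps label order on ties
    order = np.argsort(-proj, kind="stable")
    for rank, pos in enumerate(order, start=1):
        ordered[pos].ring_index = rank
    return sorted(ordered, key=lambda c: c.ring_index)


def _looks_like_point(hint: np.ndarray, centroids: np.ndarray) -> bool:
    """Heuristic: hints much longer than unit scale are locations, not
    directions."""
    return np.linalg.norm(hint) > 10.0


def fit_centerline(ordered_centroids: np.ndarray) -> Centerline:
    """Interpolating spline through centroids ordered proximal->distal.

    Cubic with natural end conditions for >= 3 points, linear for 2;
    chord-length parameterisation avoids ringing with uneven ring spacing.
    """
    pts = np.asarray(ordered_centroids, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValidationError("centerline needs at least 2 ring centroids")
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chords == 0):
        raise ValidationError("duplicate consecutive centroids")
    t = np.concatenate([[0.0], np.cumsum(chords)])
    if len(pts) == 2:
        spline = make_interp_spline(t, pts, k=1)
    else:
        spline = CubicSpline(t, pts, bc_type="natural")
    return Centerline(control_points=pts, t_controls=t, _spline=spline)
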