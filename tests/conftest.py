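"""Shared fixtures: small phantoms (generated at test time, no stored data)
and hand-built observation point sets."""

from __future__ import annotations

import numpy as np
import pytest

from stentmorph import phantom
from stentmorph.landmarks import ObservationPointSet, PeakPoint


@pytest.fixture(scope="session")
def small_spec() -> phantom.PhantomSpec:
    """3-ring, 5-apex phantom: fast to voxelize, same geometry family as
    the default 7-ring device."""
    return phantom.PhantomSpec(n_rings=3, apices_per_ring=5)


@pytest.fixture(scope="session")
def small_stent(small_spec):
    geometry, ground_truth = phantom.generate_stent(small_spec)
    return geometry, ground_truth


@pytest.fixture(scope="session")
def small_mask(small_spec, small_stent):
    geometry, _ = small_stent
    return phantom.voxelize(geometry, small_spec)


@pytest.fixture(scope="session")
def default_spec() -> phantom.PhantomSpec:
    return phantom.default_spec()


@pytest.fixture(scope="session")
def default_stent(default_spec):
    return phantom.generate_stent(default_spec)


@pytest.fixture(scope="session")
def default_mask(default_spec, default_stent):
    geometry, _ = default_stent
    return phantom.voxelize(geometry, default_spec)


def build_point_set(timepoint: str, rings: dict[int, np.ndarray],
                    case_id: str = "case", registered: bool = True,
                    origin: np.ndarray | None = None) -> ObservationPointSet:
    """Hand-built observation point set; positions given per ring index."""
    peaks = []
    for ring_index, positions in sorted(rings.items()):
        for k, pos in enumerate(np.asarray(positions, dtype=float)):
            peaks.append(PeakPoint(
                position=np.asarray(pos, dtype=float), ring_index=ring_index,
                angular_coord=0.0, axial_coord=0.0, orientation="proximal",
                source="manual", peak_index=k))
    return ObservationPointSet(
        case_id=case_id, timepoint=timepoint,
        origin_landmark=np.asarray(origin, float) if origin is not None
        else np.zeros(3),
        peaks=peaks, registered=registered)


def regular_polygon(n: int, radius: float, center=(0.0, 0.0, 0.0),
                    phase_deg: float = 0.0) -> np.ndarray:
    """Planar regular n-gon in the z = center[2] plane."""
    theta = np.deg2rad(phase_deg) + 2 * np.pi * np.arange(n) / n
    center = np.asarray(center, dtype=float)
    pts = np.zeros((n, 3))
    pts[:, 0] = center[0] + radius * np.cos(theta)
    pts[:, 1] = center[1] + radius * np.sin(theta)
    pts[:, 2] = center[2]
    return pts
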