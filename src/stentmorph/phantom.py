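"""Parametric zig-zag stent phantoms with analytic apex ground truth.

A stent is modelled as M circumferential support rings. Ring ``r`` is the
closed curve

    C_r(theta) = O_r + R * (cos(theta) U + sin(theta) V)
                     + A * z(N_p * (theta - twist)) * T

where ``(U, V, T)`` is the ring's orthonormal frame (``T`` points toward
the proximal end), ``R`` the ring radius, ``A`` the apex amplitude and
``z`` a unit-amplitude periodic profile (triangle wave by default, so the
2*N_p apices are sharp, unambiguous extrema). Apices at ``z = +1`` face
the proximal end ("proximal" orientation), apices at ``z = -1`` the
distal end.

Every deformation acts on the parametric description, so the apex ground
truth stays analytic (never voxel-derived) and transform histories replay
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .grid import VoxelGrid

__all__ = [
    "PhantomSpec",
    "DeformationRecord",
    "RingGeometry",
    "StentGeometry",
    "GroundTruth",
    "generate_stent",
    "apply_deformation",
    "build_followup",
    "voxelize",
    "voxelize_vessel",
    "synthesize_ct",
    "default_spec",
]

PROXIMAL = "proximal"
DISTAL = "distal"


# ---------------------------------------------------------------------------
# specs and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic multi-ring stent in a CT-like volume.

    Lengths in mm, intensities in HU. ``apex_amplitude`` is half the
    peak-to-peak axial excursion of the zig-zag.
    """

    n_rings: int = 7
    apices_per_ring: int = 5
    ring_radius: float = 15.0
    apex_amplitude: float = 7.5
    ring_spacing: float = 22.0
    wire_radius: float = 0.8
    centerline_kind: str = "straight"  # "straight" | "arc"
    arc_radius: float = 100.0
    grid_spacing: float = 1.0
    stent_hu: float = 1700.0
    vessel_hu: float = 500.0
    background_hu: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    profile: str = "triangle"  # "triangle" | "sinusoid"

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValidationError("n_rings must be >= 1")
        if self.apices_per_ring < 3:
            raise ValidationError("apices_per_ring must be >= 3 (degenerate ring)")
        for name in ("ring_radius", "apex_amplitude", "ring_spacing",
                     "wire_radius", "grid_spacing", "arc_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 1200 <= self.stent_hu <= 2200:
            raise ValidationError("stent_hu must lie in [1200, 2200]")
        if not 300 <= self.vessel_hu <= 700:
            raise ValidationError("vessel_hu must lie in [300, 700]")
        if self.centerline_kind not in ("straight", "arc"):
            raise ValidationError("centerline_kind must be 'straight' or 'arc'")
        if self.profile not in ("triangle", "sinusoid"):
            raise ValidationError("profile must be 'triangle' or 'sinusoid'")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DeformationRecord:
    """One kinematic follow-up deformation, replayable in recorded order.

    kind:
      translate     parameters = (dx, dy, dz) mm
      radial_scale  parameters = (factor,), about each ring's own center
      twist         parameters = (angle_deg,), about each ring's local axis
      bend          parameters = (angle_deg,), rings rotate about ring 1's
                    in-plane axis with linearly increasing fraction
    applies_to: 1-based ring indices, or None for the whole stent.
    """

    kind: str
    parameters: tuple[float, ...]
    applies_to: tuple[int, ...] | None = None
    timepoint_label: str = "T2"

    def __post_init__(self) -> None:
        kinds = ("translate", "radial_scale", "twist", "bend")
        if self.kind not in kinds:
            raise ValidationError(f"unknown deformation kind {self.kind!r}")
        params = tuple(float(p) for p in self.parameters)
        object.__setattr__(self, "parameters", params)
        if self.kind == "translate" and len(params) != 3:
            raise ValidationError("translate needs 3 parameters (dx, dy, dz)")
        if self.kind in ("radial_scale", "twist", "bend") and len(params) != 1:
            raise ValidationError(f"{self.kind} needs exactly 1 parameter")
        if self.kind == "radial_scale" and params[0] <= 0:
            raise ValidationError("radial_scale factor must be > 0")
        if self.kind in ("twist", "bend") and not np.isfinite(params[0]):
            raise ValidationError(f"{self.kind} angle must be finite")
        if self.applies_to is not None:
            object.__setattr__(self, "applies_to",
                               tuple(int(i) for i in self.applies_to))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "parameters": list(self.parameters),
            "applies_to": list(self.applies_to) if self.applies_to else None,
            "timepoint_label": self.timepoint_label,
        }


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _triangle_wave(u: np.ndarray) -> np.ndarray:
    """Unit triangle wave: period 2*pi, +1 at u=0, -1 at u=pi, linear."""
    wrapped = np.mod(np.asarray(u, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return 1.0 - (2.0 / np.pi) * np.abs(wrapped)


def _profile_fn(name: str):
    if name == "triangle":
        return _triangle_wave
    return np.cos


@dataclass
class RingGeometry:
    """One ring's analytic description: center, frame, wave parameters."""

    center: np.ndarray          # (3,) mm
    u: np.ndarray               # unit, in-plane
    v: np.ndarray               # unit, in-plane
    t: np.ndarray               # unit, points proximal
    radius: float
    amplitude: float
    n_apices: int
    twist_rad: float = 0.0
    profile: str = "triangle"

    def curve(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        z = _profile_fn(self.profile)(self.n_apices * (theta - self.twist_rad))
        pts = (self.center
               + self.radius * (np.cos(theta)[:, None] * self.u
                                + np.sin(theta)[:, None] * self.v)
               + self.amplitude * z[:, None] * self.t)
        return pts

    def apex_angles(self, orientation: str) -> np.ndarray:
        k = np.arange(self.n_apices)
        if orientation == PROXIMAL:
            return self.twist_rad + 2 * np.pi * k / self.n_apices
        return self.twist_rad + (2 * k + 1) * np.pi / self.n_apices

    def apices(self, orientation: str) -> np.ndarray:
        """(n_apices, 3) analytic apex coordinates for one orientation."""
        theta = self.apex_angles(orientation)
        sign = 1.0 if orientation == PROXIMAL else -1.0
        return (self.center
                + self.radius * (np.cos(theta)[:, None] * self.u
                                 + np.sin(theta)[:, None] * self.v)
                + sign * self.amplitude * self.t)

    def copy(self) -> "RingGeometry":
        return RingGeometry(self.center.copy(), self.u.copy(), self.v.copy(),
                            self.t.copy(), self.radius, self.amplitude,
                            self.n_apices, self.twist_rad, self.profile)


@dataclass
class StentGeometry:
    """Ordered rings (index 1 = most proximal) plus transform history."""

    rings: list[RingGeometry]
    applied_transforms: list[DeformationRecord] = field(default_factory=list)

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def ground_truth(self, timepoint: str = "T1") -> "GroundTruth":
        rows = []
        for r, ring in enumerate(self.rings, start=1):
            for orientation in (PROXIMAL, DISTAL):
                for a, p in enumerate(ring.apices(orientation)):
                    rows.append((r, a, orientation, np.asarray(p)))
        centers = [ring.center.copy() for ring in self.rings]
        return GroundTruth(apex_points=rows, ring_centers=centers,
                           applied_transforms=list(self.applied_transforms),
                           timepoint=timepoint)

    def copy(self) -> "StentGeometry":
        return StentGeometry([r.copy() for r in self.rings],
                             list(self.applied_transforms))


@dataclass
class GroundTruth:
    """Analytic apex/center coordinates and the transforms that made them."""

    apex_points: list[tuple[int, int, str, np.ndarray]]
    ring_centers: list[np.ndarray]
    applied_transforms: list[DeformationRecord]
    timepoint: str = "T1"

    def apex_array(self, orientation: str | None = PROXIMAL,
                   ring_index: int | None = None) -> np.ndarray:
        """(n, 3) apex coordinates filtered by orientation and/or ring."""
        pts = [p for (r, _a, o, p) in self.apex_points
               if (orientation is None or o == orientation)
               and (ring_index is None or r == ring_index)]
        return np.array(pts).reshape(-1, 3)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ring_index": r, "apex_index": a, "orientation": o,
             "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
             "timepoint": self.timepoint}
            for (r, a, o, p) in self.apex_points
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "timepoint": self.timepoint,
            "ring_centers": [list(map(float, c)) for c in self.ring_centers],
            "applied_transforms": [t.to_dict() for t in self.applied_transforms],
            "apex_points": [
                {"ring_index": r, "apex_index": a, "orientation": o,
                 "position_mm": [float(x) for x in p]}
                for (r, a, o, p) in self.apex_points
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _centerline_frames(spec: PhantomSpec) -> list[tuple[np.ndarray, ...]]:
    """Per-ring (center, u, v, t); ring 1 most proximal, descending +z."""
    frames = []
    if spec.centerline_kind == "straight":
        for r in range(spec.n_rings):
            center = np.array([0.0, 0.0, -r * spec.ring_spacing])
            frames.append((center, np.array([1.0, 0.0, 0.0]),
                           np.array([0.0, 1.0, 0.0]),
                           np.array([0.0, 0.0, 1.0])))
    else:  # circular arc in the x-z plane, curvature center at +x
        rc = spec.arc_radius
        for r in range(spec.n_rings):
            phi = r * spec.ring_spacing / rc
            center = np.array([rc * (1 - np.cos(phi)), 0.0, -rc * np.sin(phi)])
            u = np.array([np.cos(phi), 0.0, np.sin(phi)])
            v = np.array([0.0, 1.0, 0.0])
            t = np.array([-np.sin(phi), 0.0, np.cos(phi)])  # proximal-pointing
            frames.append((center, u, v, t))
    return frames


def generate_stent(spec: PhantomSpec) -> tuple[StentGeometry, GroundTruth]:
    """Build the analytic ring curves and their apex ground truth."""
    rings = [
        RingGeometry(center=c, u=u, v=v, t=t, radius=spec.ring_radius,
                     amplitude=spec.apex_amplitude,
                     n_apices=spec.apices_per_ring, profile=spec.profile)
        for (c, u, v, t) in _centerline_frames(spec)
    ]
    geometry = StentGeometry(rings)
    return geometry, geometry.ground_truth()


def default_spec(**overrides) -> PhantomSpec:
    """Thoracic-stent-sized default phantom (7 rings x 5 apices, 1 mm grid)."""
    return PhantomSpec(**overrides)


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _selected(geometry: StentGeometry,
              record: DeformationRecord) -> list[int]:
    if record.applies_to is None:
        return list(range(1, geometry.n_rings + 1))
    bad = [i for i in record.applies_to
           if not 1 <= i <= geometry.n_rings]
    if bad:
        raise ValidationError(f"applies_to ring indices out of range: {bad}")
    return sorted(record.applies_to)


def apply_deformation(geometry: StentGeometry,
                      record: DeformationRecord) -> StentGeometry:
    """Return a deformed copy; ground truth transforms exactly with it."""
    out = geometry.copy()
    selected = _selected(out, record)
    if record.kind == "translate":
        delta = np.asarray(record.parameters)
        for i in selected:
            out.rings[i - 1].center = out.rings[i - 1].center + delta
    elif record.kind == "radial_scale":
        s = record.parameters[0]
        for i in selected:
            out.rings[i - 1].radius *= s
    elif record.kind == "twist":
        angle = np.deg2rad(record.parameters[0])
        for i in selected:
            out.rings[i - 1].twist_rad += angle
    elif record.kind == "bend":
        # Rings rotate about ring 1's in-plane v axis through ring 1's
        # center, with a fraction growing linearly toward the distal end.
        angle = np.deg2rad(record.parameters[0])
        pivot = out.rings[0].center.copy()
        axis = out.rings[0].v.copy()
        m = out.n_rings
        for i in selected:
            frac = 1.0 if m == 1 else (i - 1) / (m - 1)
            rot = _rotation_matrix(axis, angle * frac)
            ring = out.rings[i - 1]
            ring.center = pivot + rot @ (ring.center - pivot)
            ring.u = rot @ ring.u
            ring.v = rot @ ring.v
            ring.t = rot @ ring.t
    out.applied_transforms.append(record)
    return out


def build_followup(spec: PhantomSpec,
                   records: list[DeformationRecord],
                   baseline_label: str = "T1") -> dict[str, StentGeometry]:
    """Per-timepoint geometries: the baseline plus one deformed geometry per
    timepoint label found in ``records`` (records of a label applied to the
    baseline in list order)."""
    baseline, _ = generate_stent(spec)
    out = {baseline_label: baseline}
    labels = []
    for rec in records:
        if rec.timepoint_label == baseline_label:
            raise ValidationError("cannot deform the baseline timepoint")
        if rec.timepoint_label not in labels:
            labels.append(rec.timepoint_label)
    for label in labels:
        geo = baseline
        for rec in records:
            if rec.timepoint_label == label:
                geo = apply_deformation(geo, rec)
        out[label] = geo
    return out


# ---------------------------------------------------------------------------
# voxelization and CT synthesis
# ---------------------------------------------------------------------------

def _sample_curves(geometry: StentGeometry, step_mm: float) -> np.ndarray:
    """Dense samples of all ring curves, step bounded by step_mm."""
    samples = []
    for ring in geometry.rings:
        # Upper bound of curve speed |dC/dtheta|: R + A * N * max|z'|.
        zslope = 2.0 / np.pi if ring.profile == "triangle" else 1.0
        speed = ring.radius + ring.amplitude * ring.n_apices * zslope
        n = max(64, int(np.ceil(2 * np.pi * speed / step_mm)))
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        samples.append(ring.curve(theta))
    return np.vstack(samples)


def voxelize(geometry: StentGeometry, spec: PhantomSpec,
             margin_voxels: int = 2) -> VoxelGrid:
    """Binary mask: foreground iff a voxel center lies within wire_radius
    of the sampled ring curves. The grid origin is snapped to a multiple of
    the spacing so voxel centers sit on a stable world lattice."""
    h = spec.grid_spacing
    samples = _sample_curves(geometry, step_mm=h / 4.0)
    pad = spec.wire_radius + margin_voxels * h
    lo = np.floor((samples.min(axis=0) - pad) / h) * h
    hi = np.ceil((samples.max(axis=0) + pad) / h) * h
    dims = np.maximum(np.round((hi - lo) / h).astype(int) + 1, 1)

    tree = cKDTree(samples)
    idx = np.indices(dims).reshape(3, -1).T
    centers = lo + idx * h
    dist, _ = tree.query(centers, distance_upper_bound=spec.wire_radius)
    values = (dist <= spec.wire_radius).astype(np.uint8).reshape(tuple(dims))
    if not values.any():
        raise ValidationError(
            "voxelization produced an empty mask: wire_radius "
            f"{spec.wire_radius} mm is too thin for grid spacing {h} mm")
    return VoxelGrid(values=values, spacing=(h, h, h), origin=tuple(lo))


def voxelize_vessel(geometry: StentGeometry, spec: PhantomSpec,
                    like: VoxelGrid, lumen_radius: float | None = None
                    ) -> VoxelGrid:
    """Tube around the ring-center polyline on the same grid as ``like``;
    stands in for the contrast-filled lumen."""
    if lumen_radius is None:
        lumen_radius = spec.ring_radius + 2.0
    centers = np.array([ring.center for ring in geometry.rings])
    if len(centers) == 1:
        samples = centers
    else:
        # densify the polyline between consecutive ring centers
        segs = []
        for a, b in zip(centers[:-1], centers[1:]):
            n = max(2, int(np.ceil(np.linalg.norm(b - a) / (spec.grid_spacing / 2))))
            frac = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
            segs.append(a + frac * (b - a))
        segs.append(centers[-1:])
        samples = np.vstack(segs)
    tree = cKDTree(samples)
    idx = np.indices(like.dims).reshape(3, -1).T
    pts = like.voxel_to_world(idx)
    dist, _ = tree.query(pts, distance_upper_bound=lumen_radius)
    values = (dist <= lumen_radius).astype(np.uint8).reshape(like.dims)
    return like.with_values(values)


def synthesize_ct(stent_mask: VoxelGrid, vessel_mask: VoxelGrid | None,
                  spec: PhantomSpec) -> VoxelGrid:
    """HU volume: background/vessel/stent intensities plus seeded Gaussian
    noise. Overlapping stent and vessel voxels resolve to stent (metal
    occludes contrast)."""
    stent_mask.require_binary()
    values = np.full(stent_mask.dims, spec.background_hu, dtype=np.float64)
    if vessel_mask is not None:
        if not stent_mask.same_geometry(vessel_mask):
            raise ValidationError("stent and vessel masks must share grid geometry")
        vessel_mask.require_binary()
        values[vessel_mask.values > 0] = spec.vessel_hu
    values[stent_mask.values > 0] = spec.stent_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return stent_mask.with_values(values)
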