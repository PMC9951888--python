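"""Automatic peak observation-point extraction and extraction scoring.

Per ring, every mask voxel gets a local cylindrical coordinate relative to
the ring centroid and the centerline tangent: a signed axial coordinate
``s`` (positive toward the proximal end) and an angle ``theta`` in the
ring plane. The circle is divided into angular sectors; each sector's
axial extremum is a peak candidate (maximal ``s`` on the proximal side,
minimal on the distal side). Candidates whose |s| falls below a fraction
of the ring's axial amplitude are eliminated as strut points, and the
survivors are merged by a fixed-radius sphere clustering (two candidates
merge when their 2 mm spheres touch, i.e. centers within 4 mm; groups
close under transitivity) whose group means are the final peaks.

Extraction is fully deterministic: no RNG anywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import StageError, ValidationError
from .grid import VoxelGrid
from .ring_analysis import (RingComponent, fit_centerline, label_rings,
                            order_rings, point_mid,
                            DEFAULT_MIN_VOLUME_VOXELS)

__all__ = [
    "PeakPoint",
    "ObservationPointSet",
    "ExtractionAgreement",
    "extract_candidates",
    "cluster_candidates",
    "extract_peaks",
    "compare_point_sets",
    "flag_discrepant_pairs",
]

log = logging.getLogger(__name__)

PROXIMAL = "proximal"
DISTAL = "distal"

# 3-degree sectors: enough candidate voxels per apex for the cluster mean
# to average out voxel quantisation of the angular coordinate
DEFAULT_N_SECTORS = 120
# fraction of the ring's axial amplitude below which a sector extremum is
# rejected as a strut point; 0.75 keeps only the apex neighbourhood while
# a triangle-wave apex region still spans >= 2 sectors at 5 deg sectors
DEFAULT_AMP_FRACTION = 0.75
DEFAULT_CLUSTER_RADIUS_MM = 2.0
DEFAULT_MATCH_THRESHOLD_MM = 5.0
# rings with axial amplitude below this are treated as apex-free (a plain
# circular band has |s| on the order of the wire radius only)
DEFAULT_MIN_AMPLITUDE_MM = 2.0


@dataclass
class PeakPoint:
    """One peak observation point with its ring-local coordinates."""

    position: np.ndarray        # (3,) world mm
    ring_index: int
    angular_coord: float        # degrees in [0, 360)
    axial_coord: float          # mm, signed along the proximal direction
    orientation: str            # "proximal" | "distal"
    source: str = "auto"
    peak_index: int = 0

    def copy(self) -> "PeakPoint":
        return replace(self, position=np.asarray(self.position, float).copy())


@dataclass
class ObservationPointSet:
    """Registered or raw peak coordinates grouped by ring and timepoint."""

    case_id: str
    timepoint: str
    origin_landmark: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    peaks: list[PeakPoint] = field(default_factory=list)
    registered: bool = False

    def ring_indices(self) -> list[int]:
        return sorted({p.ring_index for p in self.peaks})

    def ring_peaks(self, ring_index: int,
                   orientation: str | None = None) -> list[PeakPoint]:
        out = [p for p in self.peaks if p.ring_index == ring_index
               and (orientation is None or p.orientation == orientation)]
        return sorted(out, key=lambda p: (p.orientation, p.angular_coord,
                                          p.peak_index))
    def ring_positions(self, ring_index: int,
                       orientation: str | None = None) -> np.ndarray:
        return np.array([p.position for p in
                         self.ring_peaks(ring_index, orientation)]
                        ).reshape(-1, 3)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks]).reshape(-1, 3)

    def canonical_order(self) -> None:
        """Sort peaks by (ring, orientation, angle) and renumber."""
        self.peaks.sort(key=lambda p: (p.ring_index, p.orientation,
                                       p.angular_coord))
        counters: dict[tuple[int, str], int] = {}
        for p in self.peaks:
            key = (p.ring_index, p.orientation)
            p.peak_index = counters.get(key, 0)
            counters[key] = p.peak_index + 1

    def translated(self, delta: np.ndarray) -> "ObservationPointSet":
        out = ObservationPointSet(
            case_id=self.case_id, timepoint=self.timepoint,
            origin_landmark=np.asarray(self.origin_landmark, float)
            + np.zeros(3),
            peaks=[p.copy() for p in self.peaks], registered=self.registered)
        for p in out.peaks:
            p.position = p.position + np.asarray(delta, float)
        return out


@dataclass(frozen=True)
class ExtractionAgreement:
    """Missing-extraction rate and matched-pair distances vs a reference."""

    n_reference: int
    n_missing: int
    d_mean: float
    d_max: float
    matches: list[tuple[int, int, float]]  # (reference idx, extracted idx, mm)

    @property
    def missing_rate_percent(self) -> float:
        return 100.0 * self.n_missing / self.n_reference


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def _perpendicular_frame(t_prox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane (u, v) for a given proximal direction."""
    t = t_prox / np.linalg.norm(t_prox)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, t) * t
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def extract_candidates(ring: RingComponent, grid: VoxelGrid,
                       t_prox: np.ndarray,
                       n_sectors: int = DEFAULT_N_SECTORS,
                       amp_fraction: float = DEFAULT_AMP_FRACTION,
                       min_amplitude: float = DEFAULT_MIN_AMPLITUDE_MM
                       ) -> list[PeakPoint]:
    """Per-sector axial extrema with amplitude-fraction elimination.

    Returns raw (pre-clustering) candidates of both orientations. With
    ``amp_fraction == 0`` the elimination is disabled and every nonempty
    sector contributes one candidate per orientation.
    """
    if ring.volume_voxels < max(1, n_sectors // 10):
        raise ValidationError(
            f"ring component {ring.label} too small to sector "
            f"({ring.volume_voxels} voxels)")
    pts = grid.voxel_to_world(ring.voxel_indices)
    center = ring.centroid
    u, v = _perpendicular_frame(t_prox)
    t = np.asarray(t_prox, float) / np.linalg.norm(t_prox)

    d = pts - center
    s = d @ t
    theta = np.mod(np.arctan2(d @ v, d @ u), 2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi / n_sectors)).astype(int),
                        n_sectors - 1)

    max_abs = float(np.abs(s).max())
    if amp_fraction > 0 and max_abs < min_amplitude:
        return []  # no axial excursion: a circular band has no apices
    cutoff = amp_fraction * max_abs

    candidates: list[PeakPoint] = []
    for sec in np.unique(sector):
        in_sec = np.flatnonzero(sector == sec)
        for orientation, pick in ((PROXIMAL, in_sec[np.argmax(s[in_sec])]),
                                  (DISTAL, in_sec[np.argmin(s[in_sec])])):
            signed = s[pick] if orientation == PROXIMAL else -s[pick]
            if amp_fraction > 0 and signed < cutoff:
                continue
            candidates.append(PeakPoint(
                position=pts[pick], ring_index=ring.ring_index or 0,
                angular_coord=float(np.rad2deg(theta[pick])),
                axial_coord=float(s[pick]), orientation=orientation))
    return candidates


def cluster_candidates(candidates: list[PeakPoint],
                       radius: float = DEFAULT_CLUSTER_RADIUS_MM
                       ) -> list[PeakPoint]:
    """Sphere-merge clustering: candidates whose ``radius``-spheres touch
    (centers within 2*radius) join transitively; each group collapses to
    one peak at the group's arithmetic mean."""
    if radius <= 0:
        raise ValidationError("cluster radius must be > 0")
    if not candidates:
        return []
    positions = np.array([c.position for c in candidates])
    tree = cKDTree(positions)
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(2.0 * radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        groups.setdefault(find(i), []).append(i)

    peaks = []
    for root in sorted(groups):
        members = groups[root]
        mean_pos = positions[members].mean(axis=0)
        proto = candidates[members[0]]
        peaks.append(PeakPoint(
            position=mean_pos, ring_index=proto.ring_index,
            angular_coord=float(np.mean(
                _unwrap_angles([candidates[m].angular_coord
                                for m in members]))) % 360.0,
            axial_coord=float(np.mean([candidates[m].axial_coord
                                       for m in members])),
            orientation=proto.orientation))
    return peaks


def _unwrap_angles(degrees: list[float]) -> np.ndarray:
    """Mean-safe unwrap for angles that may straddle the 0/360 seam."""
    a = np.sort(np.asarray(degrees, dtype=float))
    if len(a) > 1 and (a.max() - a.min()) > 180.0:
        a = np.where(a < 180.0, a + 360.0, a)
    return a


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------

def extract_peaks(mask: VoxelGrid, *,
                  orientation: str = PROXIMAL,
                  n_sectors: int = DEFAULT_N_SECTORS,
                  amp_fraction: float = DEFAULT_AMP_FRACTION,
                  cluster_radius: float = DEFAULT_CLUSTER_RADIUS_MM,
                  min_volume_voxels: int = DEFAULT_MIN_VOLUME_VOXELS,
                  min_amplitude: float = DEFAULT_MIN_AMPLITUDE_MM,
                  axis_hint: np.ndarray | None = None,
                  case_id: str = "case",
                  timepoint: str = "T1",
                  origin_landmark: np.ndarray | None = None
                  ) -> ObservationPointSet:
    """Full extraction pipeline: rings -> order -> centerline -> sectored
    candidates -> sphere clustering, per ring.

    ``orientation`` is "proximal" (default), "distal" or "both".
    """
    if orientation not in (PROXIMAL, DISTAL, "both"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        components = label_rings(mask, min_volume_voxels=min_volume_voxels)
    except ValidationError as exc:
        raise StageError(str(exc), stage="label_rings") from exc
    components = order_rings(components, axis_hint=axis_hint)
    centroids = np.array([c.centroid for c in components])

    if len(components) >= 2:
        centerline = fit_centerline(centroids)
        # spline parameter increases proximal -> distal, so the proximal
        # direction is the negated tangent
        tangents = centerline.tangent(centerline.t_controls)
        prox_dirs = -tangents
    else:
        hint = np.asarray(axis_hint, float) if axis_hint is not None \
            else np.array([0.0, 0.0, 1.0])
        prox_dirs = (hint / np.linalg.norm(hint)).reshape(1, 3)

    wanted = (PROXIMAL, DISTAL) if orientation == "both" else (orientation,)
    peaks: list[PeakPoint] = []
    for comp, t_prox in zip(components, prox_dirs):
        try:
            candidates = extract_candidates(
                comp, mask, t_prox, n_sectors=n_sectors,
                amp_fraction=amp_fraction, min_amplitude=min_amplitude)
        except ValidationError as exc:
            raise StageError(str(exc), stage="extract_candidates") from exc
        for want in wanted:
            ring_cands = [c for c in candidates if c.orientation == want]
            peaks.extend(cluster_candidates(ring_cands,
                                            radius=cluster_radius))

    pts = ObservationPointSet(
        case_id=case_id, timepoint=timepoint,
        origin_landmark=np.asarray(origin_landmark, float)
        if origin_landmark is not None else np.zeros(3),
        peaks=peaks)
    pts.canonical_order()
    return pts


# ---------------------------------------------------------------------------
# extraction scoring
# ---------------------------------------------------------------------------

def compare_point_sets(extracted: ObservationPointSet,
                       reference: ObservationPointSet,
                       match_threshold: float = DEFAULT_MATCH_THRESHOLD_MM
                       ) -> ExtractionAgreement:
    """Greedy one-to-one nearest-neighbour matching by ascending distance;
    reference points with no extracted point within ``match_threshold``
    count as missing. Distances are over matched pairs only."""
    ref = reference.positions()
    ext = extracted.positions()
    if len(ref) == 0:
        raise ValidationError("reference point set is empty")
    matches: list[tuple[int, int, float]] = []
    if len(ext) > 0:
        diff = ref[:, None, :] - ext[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                           dist.shape))[0]
        used_ref: set[int] = set()
        used_ext: set[int] = set()
        for i, j in order:
            if dist[i, j] > match_threshold:
                break
            if i in used_ref or j in used_ext:
                continue
            used_ref.add(int(i))
            used_ext.add(int(j))
            matches.append((int(i), int(j), float(dist[i, j])))
    n_missing = len(ref) - len(matches)
    if matches:
        dists = [m[2] for m in matches]
        d_mean, d_max = float(np.mean(dists)), float(np.max(dists))
    else:
        d_mean = d_max = float("nan")
    return ExtractionAgreement(n_reference=len(ref), n_missing=n_missing,
                               d_mean=d_mean, d_max=d_max, matches=matches)


def flag_discrepant_pairs(reader_a: ObservationPointSet,
                          reader_b: ObservationPointSet,
                          threshold: float = 1.5
                          ) -> list[tuple[int, int, float]]:
    """Adjudication helper: matched reference pairs whose readings differ
    by more than ``threshold`` mm (flagged for a third reader, offline)."""
    agreement = compare_point_sets(reader_a, reader_b,
                                   match_threshold=float("inf"))
    return [(i, j, d) for (i, j, d) in agreement.matches if d > threshold]
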