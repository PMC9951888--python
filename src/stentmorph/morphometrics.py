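"""Follow-up morphometry on registered observation-point sets.

Three parameter families are computed from the peak coordinates alone:

* end-slip vector: componentwise displacement of an end ring's midpoint
  between two periods (earlier minus later);
* characteristic diameter rho (max pairwise peak distance) and the ring
  rate R_k = (rho_k / rho_1)^2 relative to the baseline period;
* ring deflection angle: per peak, the signed projected rotation angle
  about the ring's local axis between two periods, averaged over peaks.

Plus the method-agreement statistics (difference mean/SD and squared
Pearson correlation) used to compare measurement schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .landmarks import ObservationPointSet, PeakPoint
from .ring_analysis import point_mid

__all__ = [
    "SlipVector",
    "RingDiameter",
    "RingRate",
    "DeflectionResult",
    "MethodAgreement",
    "register_to_origin",
    "end_slip",
    "characteristic_diameter",
    "ring_rate",
    "deflection_angle",
    "method_agreement",
    "relative_error",
    "measure_series",
]

log = logging.getLogger(__name__)

ARCSIN_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class SlipVector:
    delta: tuple[float, float, float]   # (dx, dy, dz) mm, earlier - later
    period_pair: tuple[str, str]
    end: str                            # "proximal" | "distal"


@dataclass(frozen=True)
class RingDiameter:
    ring_index: int
    timepoint: str
    rho: float                          # mm
    argmax_pair: tuple[int, int]        # peak indices attaining the max


@dataclass(frozen=True)
class RingRate:
    ring_index: int
    timepoint: str
    r_k: float                          # (rho_k / rho_1)^2


@dataclass(frozen=True)
class DeflectionResult:
    ring_index: int
    period_pair: tuple[str, str]
    alphas_deg: tuple[float, ...]       # per-peak angles
    beta_deg: float                     # mean of alphas
    normal_used: tuple[float, float, float]


@dataclass(frozen=True)
class MethodAgreement:
    n_pairs: int
    mean_difference: float
    sd_difference: float
    r_squared: float
    degenerate: bool = False            # zero variance in a series


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_to_origin(pts: ObservationPointSet) -> ObservationPointSet:
    """Translate all coordinates by -origin_landmark (pure translation to
    the skeletal origin; no rotation correction)."""
    if pts.registered:
        raise ValidationError(
            f"point set {pts.case_id}/{pts.timepoint} is already registered")
    origin = np.asarray(pts.origin_landmark, dtype=float)
    out = pts.translated(-origin)
    out.origin_landmark = np.zeros(3)
    out.registered = True
    return out


def _require_registered(*sets: ObservationPointSet) -> None:
    for s in sets:
        if not s.registered:
            raise ValidationError(
                f"point set {s.case_id}/{s.timepoint} is not registered "
                "to the skeletal origin")


# ---------------------------------------------------------------------------
# end-slip (earlier minus later)
# ---------------------------------------------------------------------------

def end_slip(set_i: ObservationPointSet, set_j: ObservationPointSet,
             end: str = "proximal") -> SlipVector:
    """Componentwise end-ring midpoint displacement between periods i, j."""
    _require_registered(set_i, set_j)
    if end not in ("proximal", "distal"):
        raise ValidationError(f"end must be proximal or distal, got {end!r}")
    deltas = []
    midpoints = []
    for s in (set_i, set_j):
        rings = s.ring_indices()
        if not rings:
            raise ValidationError(
                f"point set {s.case_id}/{s.timepoint} has no rings")
        ring = min(rings) if end == "proximal" else max(rings)
        pos = s.ring_positions(ring)
        if len(pos) == 0:
            raise ValidationError(f"end ring {ring} has no peaks")
        midpoints.append(point_mid(pos))
    delta = midpoints[0] - midpoints[1]
    return SlipVector(delta=tuple(float(x) for x in delta),
                      period_pair=(set_i.timepoint, set_j.timepoint), end=end)


# ---------------------------------------------------------------------------
# characteristic diameter and ring rate
# ---------------------------------------------------------------------------

def characteristic_diameter(peaks: list[PeakPoint] | np.ndarray,
                            ring_index: int | None = None,
                            timepoint: str = "") -> RingDiameter:
    """rho = max over all unordered peak pairs of the Euclidean distance."""
    if isinstance(peaks, np.ndarray):
        positions = np.asarray(peaks, dtype=float).reshape(-1, 3)
        ring = ring_index if ring_index is not None else 0
    else:
        positions = np.array([p.position for p in peaks]).reshape(-1, 3)
        ring = ring_index if ring_index is not None else (
            peaks[0].ring_index if peaks else 0)
    n = len(positions)
    if n < 2:
        raise ValidationError(
            "characteristic diameter needs at least 2 peaks")
    # explicit all-pairs scan: peak counts are tiny (N <= ~16) and the
    # strict > keeps the lowest (i, j) pair on ties
    best_d, best_pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if d > best_d:
                best_d, best_pair = d, (i, j)
    return RingDiameter(ring_index=ring, timepoint=timepoint,
                        rho=best_d, argmax_pair=best_pair)


def ring_rate(rho_k: float, rho_1: float, ring_index: int = 0,
              timepoint: str = "") -> RingRate:
    """R_k = (rho_k / rho_1)^2 relative to the baseline period."""
    if rho_1 <= 0:
        raise ValidationError("baseline characteristic diameter must be > 0")
    return RingRate(ring_index=ring_index, timepoint=timepoint,
                    r_k=float((rho_k / rho_1) ** 2))


# ---------------------------------------------------------------------------
# deflection angle
# ---------------------------------------------------------------------------

def _clamped_arcsin(x: float) -> float:
    if x > 1.0 + ARCSIN_CLAMP_TOL or x < -1.0 - ARCSIN_CLAMP_TOL:
        raise ValidationError(
            f"arcsin argument {x!r} exceeds [-1, 1] beyond tolerance")
    return float(np.arcsin(np.clip(x, -1.0, 1.0)))


def _match_by_cyclic_angle(vec_a: np.ndarray, vec_b: np.ndarray,
                           normal: np.ndarray) -> np.ndarray:
    """Order-preserving correspondence of equally sized peak rings.

    Both sets are sorted by angle about ``normal``; the cyclic shift of the
    second set minimising the total circular angular distance defines the
    pairing. Deterministic, and correct for twists smaller than half the
    inter-peak angle even across the 0/360 seam.
    Returns the permutation of vec_b rows matched to sorted vec_a rows,
    as a pair of index arrays (order_a, order_b).
    """
    u, v = _plane_frame(normal)

    def angles(vectors: np.ndarray) -> np.ndarray:
        return np.mod(np.arctan2(vectors @ v, vectors @ u), 2 * np.pi)

    ang_a = angles(vec_a)
    ang_b = angles(vec_b)
    order_a = np.argsort(ang_a, kind="stable")
    order_b = np.argsort(ang_b, kind="stable")
    n = len(order_a)
    best_shift, best_cost = 0, np.inf
    for shift in range(n):
        rolled = np.roll(order_b, -shift)
        diff = np.abs(ang_a[order_a] - ang_b[rolled])
        cost = float(np.sum(np.minimum(diff, 2 * np.pi - diff)))
        if cost < best_cost:
            best_cost, best_shift = cost, shift
    return order_a, np.roll(order_b, -best_shift)


def _plane_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, n) * n
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def deflection_angle(ring_k_t1: np.ndarray | list[PeakPoint],
                     ring_k_t2: np.ndarray | list[PeakPoint],
                     o_k: np.ndarray, o_k1: np.ndarray,
                     ring_index: int = 0,
                     period_pair: tuple[str, str] = ("T1", "T2")
                     ) -> DeflectionResult:
    """Mean signed rotation of a ring's peaks about its local axis.

    Both periods' rings are recentred so their midpoints coincide; the
    plane normal is the unit vector from O_{k+1} to O_k; for each matched
    peak pair (P_j, P_j'), alpha_j = arcsin(((OP_j x OP_j') / (|OP_j|
    |OP_j'|)) . n), and beta is the mean of the alphas (degrees).
    """
    p1 = _positions(ring_k_t1)
    p2 = _positions(ring_k_t2)
    if len(p1) != len(p2):
        raise ValidationError(
            f"deflection needs equal peak counts, got {len(p1)} vs {len(p2)}")
    if len(p1) < 1:
        raise ValidationError("deflection needs at least one peak")
    o_k = np.asarray(o_k, float)
    o_k1 = np.asarray(o_k1, float)
    axis = o_k - o_k1
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("ring centers O_k and O_{k+1} coincide")
    n_hat = axis / norm

    v1 = p1 - point_mid(p1)
    v2 = p2 - point_mid(p2)
    lens1 = np.linalg.norm(v1, axis=1)
    lens2 = np.linalg.norm(v2, axis=1)
    if np.any(lens1 == 0) or np.any(lens2 == 0):
        raise ValidationError("a peak coincides with the ring midpoint")

    order1, order2 = _match_by_cyclic_angle(v1, v2, n_hat)
    alphas = []
    for i, j in zip(order1, order2):
        cross = np.cross(v1[i] / lens1[i], v2[j] / lens2[j])
        alphas.append(np.rad2deg(_clamped_arcsin(float(np.dot(cross, n_hat)))))
    beta = float(np.mean(alphas))
    return DeflectionResult(ring_index=ring_index, period_pair=period_pair,
                            alphas_deg=tuple(alphas), beta_deg=beta,
                            normal_used=tuple(float(x) for x in n_hat))


def _positions(peaks: np.ndarray | list[PeakPoint]) -> np.ndarray:
    if isinstance(peaks, np.ndarray):
        return np.asarray(peaks, float).reshape(-1, 3)
    return np.array([p.position for p in peaks]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# method agreement
# ---------------------------------------------------------------------------

def method_agreement(values_a, values_b) -> MethodAgreement:
    """Difference mean, sample SD (n-1) and squared Pearson correlation of
    two paired measurement series. Zero variance in either series is a
    degenerate case: flagged, with r^2 = 1 only for identical series."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired series must be equal-length 1D")
    if len(a) < 2:
        raise ValidationError("need at least 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    var_a = float(a.std(ddof=1))
    var_b = float(b.std(ddof=1))
    if var_a == 0 or var_b == 0:
        r2 = 1.0 if np.array_equal(a, b) else float("nan")
        return MethodAgreement(n_pairs=len(a), mean_difference=mean_diff,
                               sd_difference=sd_diff, r_squared=r2,
                               degenerate=True)
    r = float(np.corrcoef(a, b)[0, 1])
    return MethodAgreement(n_pairs=len(a), mean_difference=mean_diff,
                           sd_difference=sd_diff, r_squared=r * r)


def relative_error(values_a, values_b) -> float:
    """Convention: mean(|a - b|) / mean(|a|)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    denom = float(np.mean(np.abs(a)))
    if denom == 0:
        raise ValidationError("relative error undefined for all-zero reference")
    return float(np.mean(np.abs(a - b)) / denom)


# ---------------------------------------------------------------------------
# series report
# ---------------------------------------------------------------------------

def _period_pairs(labels: list[str]) -> list[tuple[str, str]]:
    pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    if len(labels) > 2:
        pairs.append((labels[0], labels[-1]))
    return pairs


def _ring_midpoints(pts: ObservationPointSet) -> dict[int, np.ndarray]:
    return {r: point_mid(pts.ring_positions(r)) for r in pts.ring_indices()}


def measure_series(series: list[ObservationPointSet]) -> dict:
    """Full morphometric report over >= 2 registered timepoints.

    For every consecutive and (when more than two) first-vs-last period
    pair: slip vectors at both ends, per-ring deflection angles; per ring
    and timepoint: characteristic diameter and ring rate vs the first
    period. Rings are matched across timepoints by ring_index; indices not
    present everywhere are skipped with a warning.
    """
    if len(series) < 2:
        raise ValidationError("measure_series needs at least 2 timepoints")
    _require_registered(*series)
    labels = [s.timepoint for s in series]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate timepoint labels in series")
    by_label = dict(zip(labels, series))

    common_rings = set(series[0].ring_indices())
    for s in series[1:]:
        common_rings &= set(s.ring_indices())
    all_rings = set().union(*(s.ring_indices() for s in series))
    if common_rings != all_rings:
        log.warning("ring count mismatch across timepoints; restricting to "
                    "common indices %s", sorted(common_rings))
    rings = sorted(common_rings)
    if not rings:
        raise ValidationError("no ring indices common to all timepoints")

    report: dict = {"case_id": series[0].case_id, "timepoints": labels,
                    "rings": rings, "warnings": []}
    if common_rings != all_rings:
        report["warnings"].append("ring indices restricted to common subset")

    # characteristic diameters and ring rates per ring/timepoint
    diameters: dict = {}
    rates: dict = {}
    for ring in rings:
        rhos = {}
        for label in labels:
            rd = characteristic_diameter(by_label[label].ring_peaks(ring),
                                         ring_index=ring, timepoint=label)
            rhos[label] = rd
        diameters[str(ring)] = {
            lab: {"rho_mm": rhos[lab].rho,
                  "argmax_pair": list(rhos[lab].argmax_pair)}
            for lab in labels}
        baseline = rhos[labels[0]].rho
        rates[str(ring)] = {
            lab: ring_rate(rhos[lab].rho, baseline, ring_index=ring,
                           timepoint=lab).r_k
            for lab in labels}
    report["characteristic_diameter"] = diameters
    report["ring_rate"] = rates

    # slips and deflections per period pair
    slips: dict = {}
    deflections: dict = {}
    for (li, lj) in _period_pairs(labels):
        key = f"{li}-{lj}"
        slips[key] = {
            end: list(end_slip(by_label[li], by_label[lj], end=end).delta)
            for end in ("proximal", "distal")}
        mids = _ring_midpoints(by_label[li])
        pair_defl = {}
        for ring in rings:
            o_k = mids[ring]
            if ring + 1 in mids:
                o_k1 = mids[ring + 1]
            elif ring - 1 in mids:
                # most distal ring: reuse the negated previous direction
                o_k1 = o_k - (mids[ring - 1] - o_k)
            else:
                report["warnings"].append(
                    f"ring {ring}: no neighbour to define the plane normal; "
                    "deflection skipped")
                continue
            try:
                res = deflection_angle(
                    by_label[li].ring_peaks(ring),
                    by_label[lj].ring_peaks(ring),
                    o_k, o_k1, ring_index=ring, period_pair=(li, lj))
            except ValidationError as exc:
                report["warnings"].append(f"ring {ring} ({key}): {exc}")
                continue
            pair_defl[str(ring)] = {"beta_deg": res.beta_deg,
                                    "alphas_deg": list(res.alphas_deg),
                                    "normal": list(res.normal_used)}
        deflections[key] = pair_defl
    report["end_slip"] = slips
    report["deflection"] = deflections
    return report
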