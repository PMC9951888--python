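"""Registration, slip, diameter/rate, deflection and agreement stats.

Oracles: an independently coded all-pairs scan for the characteristic
diameter, a covariance-formula implementation for r^2, and a brute-force
projected-angle computation for the deflection angle.
"""

import numpy as np
import pytest

from stentmorph import morphometrics
from stentmorph.errors import ValidationError
from stentmorph.morphometrics import (_clamped_arcsin, characteristic_diameter,
                                      deflection_angle, end_slip,
                                      measure_series, method_agreement,
                                      register_to_origin, relative_error,
                                      ring_rate)

from conftest import build_point_set, regular_polygon


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_max_pairwise(points: np.ndarray) -> float:
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            best = max(best, float(np.linalg.norm(points[i] - points[j])))
    return best


def covariance_r_squared(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    cov = np.sum((a - a.mean()) * (b - b.mean())) / (n - 1)
    return float(cov ** 2 / (np.var(a, ddof=1) * np.var(b, ddof=1)))


def projected_angle_oracle(p1: np.ndarray, p2: np.ndarray,
                           normal: np.ndarray) -> np.ndarray:
    """Signed angles between matched peaks after projection into the plane
    perpendicular to ``normal`` (rings recentred on their own midpoints).
    Assumes index i of period 1 corresponds to index i of period 2."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    v1 = p1 - p1.mean(axis=0)
    v2 = p2 - p2.mean(axis=0)
    out = []
    for a, b in zip(v1, v2):
        a_proj = a - (a @ n) * n
        b_proj = b - (b @ n) * n
        cosang = (a_proj @ b_proj) / (np.linalg.norm(a_proj)
                                      * np.linalg.norm(b_proj))
        ang = np.arccos(np.clip(cosang, -1, 1))
        sign = np.sign(np.cross(a_proj, b_proj) @ n)
        out.append(np.degrees(sign * ang))
    return np.array(out)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class TestRegisterToOrigin:
    def test_translates_by_minus_origin(self):
        pts = build_point_set("T1", {1: [(12.0, 10, 10)]}, registered=False,
                              origin=(10.0, 10, 10))
        reg = register_to_origin(pts)
        np.testing.assert_allclose(reg.positions(), [[2.0, 0, 0]])
        assert reg.registered
        np.testing.assert_allclose(reg.origin_landmark, 0.0)

    def test_zero_origin_is_identity(self):
        pts = build_point_set("T1", {1: [(1.0, 2, 3)]}, registered=False)
        reg = register_to_origin(pts)
        np.testing.assert_allclose(reg.positions(), [[1.0, 2, 3]])

    def test_double_registration_rejected(self):
        pts = build_point_set("T1", {1: [(1.0, 2, 3)]}, registered=True)
        with pytest.raises(ValidationError):
            register_to_origin(pts)

    def test_comoving_shift_cancels(self):
        base = np.array([(0.0, 0, 0), (10, 0, 0), (0, 10, 0)])
        shift = np.array([7.0, -3.0, 2.0])
        t1 = build_point_set("T1", {1: base}, registered=False,
                             origin=(100.0, 100, 100))
        t2 = build_point_set("T2", {1: base + shift}, registered=False,
                             origin=np.array([100.0, 100, 100]) + shift)
        r1, r2 = register_to_origin(t1), register_to_origin(t2)
        np.testing.assert_allclose(r1.positions(), r2.positions(), atol=1e-12)
        slip = end_slip(r1, r2, "proximal")
        np.testing.assert_allclose(slip.delta, (0, 0, 0), atol=1e-12)


# ---------------------------------------------------------------------------
# end slip
# ---------------------------------------------------------------------------

class TestEndSlip:
    def test_identical_sets_zero(self):
        pts = build_point_set("T1", {1: regular_polygon(5, 10)})
        slip = end_slip(pts, pts)
        np.testing.assert_allclose(slip.delta, (0, 0, 0))

    def test_sign_convention_earlier_minus_later(self):
        t1 = build_point_set("T1", {1: [(1.0, 1, 1)]})
        t2 = build_point_set("T2", {1: [(1.0, 1, 4)]})
        slip = end_slip(t1, t2)
        np.testing.assert_allclose(slip.delta, (0, 0, -3.0))

    def test_antisymmetric_under_period_swap(self):
        rng = np.random.default_rng(2)
        t1 = build_point_set("T1", {1: rng.normal(size=(5, 3))})
        t2 = build_point_set("T2", {1: rng.normal(size=(5, 3))})
        fwd = end_slip(t1, t2)
        rev = end_slip(t2, t1)
        np.testing.assert_allclose(fwd.delta, -np.asarray(rev.delta),
                                   atol=1e-12)

    def test_distal_end_uses_highest_ring_index(self):
        t1 = build_point_set("T1", {1: [(0.0, 0, 0)], 3: [(0.0, 0, -50)]})
        t2 = build_point_set("T2", {1: [(0.0, 0, 0)], 3: [(0.0, 0, -53)]})
        assert end_slip(t1, t2, "proximal").delta == (0, 0, 0)
        np.testing.assert_allclose(end_slip(t1, t2, "distal").delta,
                                   (0, 0, 3.0))

    def test_unregistered_rejected(self):
        t1 = build_point_set("T1", {1: [(0.0, 0, 0)]}, registered=False)
        t2 = build_point_set("T2", {1: [(0.0, 0, 0)]})
        with pytest.raises(ValidationError):
            end_slip(t1, t2)


# ---------------------------------------------------------------------------
# characteristic diameter and ring rate
# ---------------------------------------------------------------------------

class TestCharacteristicDiameter:
    def test_unit_square(self):
        pts = np.array([(0.0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)])
        assert characteristic_diameter(pts).rho == pytest.approx(np.sqrt(2))

    def test_two_points(self):
        pts = np.array([(0.0, 0, 0), (30.0, 0, 0)])
        result = characteristic_diameter(pts)
        assert result.rho == pytest.approx(30.0)
        assert result.argmax_pair == (0, 1)

    def test_regular_pentagon_closed_form(self):
        # max pairwise distance of a circumradius-15 pentagon:
        # 2 * 15 * sin(2*pi/5), verified by the brute-force scan
        pts = regular_polygon(5, 15.0)
        expected = 2 * 15.0 * np.sin(2 * np.pi / 5)
        result = characteristic_diameter(pts)
        assert result.rho == pytest.approx(expected, abs=1e-9)
        assert result.rho == pytest.approx(brute_force_max_pairwise(pts))
        assert expected == pytest.approx(28.5317, abs=5e-5)

    def test_oracle_equivalence_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.uniform(-50, 50, size=(rng.integers(2, 12), 3))
            assert characteristic_diameter(pts).rho \
                == brute_force_max_pairwise(pts)

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValidationError):
            characteristic_diameter(np.array([[0.0, 0, 0]]))


class TestRingRate:
    def test_equal_rhos_give_one(self):
        assert ring_rate(10.0, 10.0).r_k == 1.0

    def test_doubling_gives_four(self):
        assert ring_rate(20.0, 10.0).r_k == 4.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            ring_rate(10.0, 0.0)


# ---------------------------------------------------------------------------
# deflection angle
# ---------------------------------------------------------------------------

class TestDeflectionAngle:
    def test_identical_periods_zero(self):
        pts = regular_polygon(5, 15.0)
        result = deflection_angle(pts, pts, o_k=np.zeros(3),
                                  o_k1=np.array([0.0, 0, -22]))
        np.testing.assert_allclose(result.alphas_deg, 0.0, atol=1e-12)
        assert result.beta_deg == 0.0

    def test_planar_rotation_recovered_to_1e6_deg(self):
        pts = regular_polygon(5, 15.0)
        rotated = regular_polygon(5, 15.0, phase_deg=10.0)
        # normal aligned with the ring's +z normal: O_k above O_{k+1}
        result = deflection_angle(pts, rotated, o_k=np.zeros(3),
                                  o_k1=np.array([0.0, 0, -22]))
        assert result.beta_deg == pytest.approx(10.0, abs=1e-6)
        np.testing.assert_allclose(result.alphas_deg, 10.0, atol=1e-6)
        # cross-check with the brute-force projected-angle oracle
        oracle = projected_angle_oracle(pts, rotated, np.array([0, 0, 1.0]))
        np.testing.assert_allclose(result.alphas_deg, oracle, atol=1e-6)

    def test_reversed_normal_flips_sign(self):
        pts = regular_polygon(5, 15.0)
        rotated = regular_polygon(5, 15.0, phase_deg=10.0)
        result = deflection_angle(pts, rotated, o_k=np.zeros(3),
                                  o_k1=np.array([0.0, 0, 22]))
        assert result.beta_deg == pytest.approx(-10.0, abs=1e-6)

    def test_rotation_across_angle_seam(self):
        # peaks at 350, 62, ... : a +20 deg twist wraps one peak past 0
        pts = regular_polygon(5, 15.0, phase_deg=350.0)
        rotated = regular_polygon(5, 15.0, phase_deg=10.0)
        result = deflection_angle(pts, rotated, o_k=np.zeros(3),
                                  o_k1=np.array([0.0, 0, -22]))
        assert result.beta_deg == pytest.approx(20.0, abs=1e-6)

    def test_antisymmetry_for_planar_rings(self):
        pts = regular_polygon(6, 12.0)
        rotated = regular_polygon(6, 12.0, phase_deg=14.0)
        o_k, o_k1 = np.zeros(3), np.array([0.0, 0, -22])
        fwd = deflection_angle(pts, rotated, o_k, o_k1)
        rev = deflection_angle(rotated, pts, o_k, o_k1)
        assert fwd.beta_deg == pytest.approx(-rev.beta_deg, abs=1e-9)

    def test_translation_invariance(self):
        pts = regular_polygon(5, 15.0)
        rotated = regular_polygon(5, 15.0, phase_deg=10.0)
        shift = np.array([100.0, -40.0, 7.0])
        a = deflection_angle(pts, rotated, np.zeros(3),
                             np.array([0.0, 0, -22]))
        b = deflection_angle(pts + shift, rotated + shift, shift,
                             np.array([0.0, 0, -22]) + shift)
        np.testing.assert_allclose(a.alphas_deg, b.alphas_deg, atol=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(9)
        pts = regular_polygon(5, 15.0)
        rotated = regular_polygon(5, 15.0, phase_deg=10.0)
        # random rotation applied to both periods and the axis
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        a = deflection_angle(pts, rotated, np.zeros(3),
                             np.array([0.0, 0, -22]))
        b = deflection_angle(pts @ q.T, rotated @ q.T, np.zeros(3),
                             q @ np.array([0.0, 0, -22]))
        np.testing.assert_allclose(sorted(a.alphas_deg), sorted(b.alphas_deg),
                                   atol=1e-9)

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValidationError):
            deflection_angle(regular_polygon(5, 15.0),
                             regular_polygon(6, 15.0),
                             np.zeros(3), np.array([0.0, 0, -22]))

    def test_coincident_centers_rejected(self):
        pts = regular_polygon(5, 15.0)
        with pytest.raises(ValidationError):
            deflection_angle(pts, pts, np.zeros(3), np.zeros(3))

    def test_arcsin_clamping(self):
        assert _clamped_arcsin(1.0 + 1e-12) == pytest.approx(np.pi / 2)
        assert _clamped_arcsin(-1.0 - 1e-12) == pytest.approx(-np.pi / 2)
        with pytest.raises(ValidationError):
            _clamped_arcsin(1.0 + 1e-6)


# ---------------------------------------------------------------------------
# method agreement
# ---------------------------------------------------------------------------

class TestMethodAgreement:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        result = method_agreement(a, a)
        assert result.mean_difference == 0.0
        assert result.sd_difference == 0.0
        assert result.r_squared == 1.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        result = method_agreement(a + 1.0, a)
        assert result.mean_difference == pytest.approx(1.0)
        assert result.sd_difference == pytest.approx(0.0)
        assert result.r_squared == pytest.approx(1.0)

    def test_oracle_equivalence_random_gaussians(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=100)
        b = 0.8 * a + rng.normal(scale=0.3, size=100)
        result = method_agreement(a, b)
        assert result.r_squared == pytest.approx(covariance_r_squared(a, b),
                                                 abs=1e-12)

    def test_degenerate_constant_series_flagged(self):
        result = method_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert result.degenerate
        assert np.isnan(result.r_squared)

    def test_identical_constant_series_r2_one(self):
        result = method_agreement([2.0, 2.0], [2.0, 2.0])
        assert result.degenerate
        assert result.r_squared == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            method_agreement([1.0, 2.0], [1.0])

    def test_relative_error_convention(self):
        assert relative_error([10.0, 10.0], [9.0, 11.0]) \
            == pytest.approx(0.1)
        with pytest.raises(ValidationError):
            relative_error([0.0, 0.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# series report
# ---------------------------------------------------------------------------

def _two_ring_series(shift=np.zeros(3), phase2=0.0, scale2=1.0):
    rings_t1 = {1: regular_polygon(5, 15.0, center=(0, 0, 0)),
                2: regular_polygon(5, 15.0, center=(0, 0, -22))}
    rings_t2 = {1: regular_polygon(5, 15.0 * scale2, center=(0, 0, 0),
                                   phase_deg=phase2) + shift,
                2: regular_polygon(5, 15.0 * scale2, center=(0, 0, -22),
                                   phase_deg=phase2) + shift}
    return [build_point_set("T1", rings_t1), build_point_set("T2", rings_t2)]


class TestMeasureSeries:
    def test_identical_series_all_null(self):
        series = _two_ring_series()
        report = measure_series(series)
        for end in ("proximal", "distal"):
            np.testing.assert_allclose(report["end_slip"]["T1-T2"][end], 0.0)
        for ring in ("1", "2"):
            assert report["ring_rate"][ring]["T2"] == pytest.approx(1.0)
            assert report["deflection"]["T1-T2"][ring]["beta_deg"] \
                == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_only_moves_slip(self):
        shift = np.array([3.0, -2.0, 5.0])
        report = measure_series(_two_ring_series(shift=shift))
        np.testing.assert_allclose(report["end_slip"]["T1-T2"]["proximal"],
                                   -shift, atol=1e-12)
        for ring in ("1", "2"):
            assert report["ring_rate"][ring]["T2"] == pytest.approx(1.0)
            assert report["deflection"]["T1-T2"][ring]["beta_deg"] \
                == pytest.approx(0.0, abs=1e-9)

    def test_twist_and_scale_recovered_analytically(self):
        report = measure_series(_two_ring_series(phase2=10.0, scale2=1.2))
        for ring in ("1", "2"):
            assert report["ring_rate"][ring]["T2"] == pytest.approx(1.44)
            assert report["deflection"]["T1-T2"][ring]["beta_deg"] \
                == pytest.approx(10.0, abs=1e-9)

    def test_four_timepoints_pair_enumeration(self):
        series = [build_point_set(f"T{k}",
                                  {1: regular_polygon(5, 15.0),
                                   2: regular_polygon(5, 15.0,
                                                      center=(0, 0, -22))})
                  for k in range(1, 5)]
        report = measure_series(series)
        assert sorted(report["end_slip"]) == ["T1-T2", "T1-T4", "T2-T3",
                                              "T3-T4"]
        assert sorted(report["deflection"]) == ["T1-T2", "T1-T4", "T2-T3",
                                                "T3-T4"]

    def test_ring_mismatch_restricted_with_warning(self):
        t1 = build_point_set("T1", {1: regular_polygon(5, 15.0),
                                    2: regular_polygon(5, 15.0,
                                                       center=(0, 0, -22))})
        t2 = build_point_set("T2", {1: regular_polygon(5, 15.0)})
        report = measure_series([t1, t2])
        assert report["rings"] == [1]
        assert report["warnings"]

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValidationError):
            measure_series([build_point_set("T1", {1: regular_polygon(5, 15)})])
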