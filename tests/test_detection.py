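"""Tracker acceptance, POCA reconstruction and kinematics."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from fragmon.detection import (
    DetectedTrack,
    EmissionProfile,
    ReconstructionError,
    TrackerSpec,
    detect,
    kinematics,
    longitudinal_profile,
    poca_vertex,
    rectangle_solid_angle,
    solid_angle,
)
from fragmon.emission import FragmentTrack
from fragmon.transport import PROTON


class TestSolidAngle:
    def test_reference_tracker_value(self):
        # 20 x 20 cm at 40 cm
        assert rectangle_solid_angle(20.0, 20.0, 40.0) == pytest.approx(0.23543, abs=2e-4)

    @pytest.mark.parametrize("a,b,d", [(20.0, 20.0, 40.0), (3.0, 1.5, 70.0), (10.0, 4.0, 12.0)])
    def test_against_numerical_integration(self, a, b, d):
        # Omega = integral over the rectangle of d / (d^2 + x^2 + y^2)^(3/2)
        val, _ = integrate.dblquad(
            lambda y, x: d / (d**2 + x**2 + y**2) ** 1.5,
            -a / 2, a / 2, -b / 2, b / 2,
        )
        assert rectangle_solid_angle(a, b, d) == pytest.approx(val, rel=1e-8)

    def test_far_field_limit(self):
        assert rectangle_solid_angle(1.0, 1.0, 1000.0) == pytest.approx(1e-6, rel=1e-4)

    def test_tracker_wrapper_and_validation(self):
        tr = TrackerSpec(theta=90.0, distance=40.0)
        assert solid_angle(tr) == rectangle_solid_angle(20.0, 20.0, 40.0)
        with pytest.raises(ValueError):
            TrackerSpec(theta=0.0, distance=40.0)
        with pytest.raises(ValueError):
            TrackerSpec(theta=90.0, distance=-1.0)
        with pytest.raises(ValueError):
            TrackerSpec(theta=90.0, distance=40.0, efficiency=1.5)


def _track_to(tracker, vertex, offset_uv=(0.0, 0.0)):
    """A fragment track from ``vertex`` aimed at a point on the tracker."""
    u, v = tracker.frame()
    target = tracker.center + offset_uv[0] * u + offset_uv[1] * v
    d = target - np.asarray(vertex, float)
    return FragmentTrack(PROTON, vertex, d / np.linalg.norm(d), 100.0)


class TestDetect:
    TRACKER = TrackerSpec(theta=90.0, distance=40.0)

    def test_ideal_detector_is_exact(self):
        trk = _track_to(self.TRACKER, (0, 0, -3.0), offset_uv=(2.0, -4.0))
        (det,) = detect([trk], self.TRACKER, seed=0)
        u, v = self.TRACKER.frame()
        want = self.TRACKER.center + 2.0 * u - 4.0 * v
        assert np.allclose(det.point, want, atol=1e-12)
        assert np.allclose(det.direction, trk.direction, atol=1e-12)
        assert det.weight == 1.0

    def test_misses_active_area(self):
        trk = _track_to(self.TRACKER, (0, 0, 0), offset_uv=(10.5, 0.0))
        assert detect([trk], self.TRACKER) == []

    def test_backwards_track_rejected(self):
        trk = FragmentTrack(PROTON, (0, 0, 0), (-1.0, 0.0, 0.0), 100.0)
        assert detect([trk], self.TRACKER) == []

    def test_zero_efficiency_detects_nothing(self):
        dead = TrackerSpec(theta=90.0, distance=40.0, efficiency=0.0)
        trk = _track_to(dead, (0, 0, 0))
        assert detect([trk], dead, seed=3) == []

    def test_efficiency_thinning_rate(self):
        half = TrackerSpec(theta=90.0, distance=40.0, efficiency=0.5)
        tracks = [_track_to(half, (0, 0, 0)) for _ in range(4000)]
        kept = detect(tracks, half, seed=5)
        assert len(kept) == pytest.approx(2000, abs=4 * math.sqrt(1000))

    def test_isotropic_acceptance_matches_solid_angle(self):
        """The accepted fraction of isotropic tracks from the reference point
        equals Omega / 4 pi."""
        rng = np.random.default_rng(17)
        n = 100000
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        tracks = [FragmentTrack(PROTON, (0.0, 0.0, 0.0), d, 100.0) for d in dirs]
        kept = detect(tracks, self.TRACKER)
        frac = len(kept) / n
        want = solid_angle(self.TRACKER) / (4.0 * math.pi)
        assert frac == pytest.approx(want, rel=0.08)

    def test_external_weights_and_zero_weight_drop(self):
        tracks = [_track_to(self.TRACKER, (0, 0, 0)) for _ in range(3)]
        dets = detect(tracks, self.TRACKER, weights=np.array([0.4, 0.0, 1.0]))
        assert [d.weight for d in dets] == [0.4, 1.0]

    def test_smearing_is_unbiased_and_sized(self):
        noisy = TrackerSpec(theta=90.0, distance=40.0,
                            angular_sigma=0.01, point_sigma=0.05)
        tracks = [_track_to(noisy, (0, 0, 0)) for _ in range(4000)]
        dets = detect(tracks, noisy, seed=11)
        u, _ = noisy.frame()
        du = [float(np.dot(d.point - noisy.center, u)) for d in dets]
        assert np.mean(du) == pytest.approx(0.0, abs=0.01)
        assert np.std(du) == pytest.approx(0.05, rel=0.1)
        angs = [math.acos(np.clip(np.dot(d.direction, tracks[0].direction), -1, 1))
                for d in dets]
        assert math.sqrt(np.mean(np.square(angs)) / 2.0) == pytest.approx(0.01, rel=0.1)

    def test_deterministic_under_seed(self):
        noisy = TrackerSpec(theta=90.0, distance=40.0,
                            angular_sigma=0.01, point_sigma=0.05, efficiency=0.8)
        tracks = [_track_to(noisy, (0, 0, -2.0)) for _ in range(100)]
        d1 = detect(tracks, noisy, seed=7)
        d2 = detect(tracks, noisy, seed=7)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert np.array_equal(a.point, b.point)
            assert np.array_equal(a.direction, b.direction)


class TestPoca:
    def test_perpendicular_intersecting_lines(self):
        vtx, doca = poca_vertex((10.0, 0.0, 5.0), (1.0, 0.0, 0.0),
                                (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        assert np.allclose(vtx, (0.0, 0.0, 5.0), atol=1e-12)
        assert doca == pytest.approx(0.0, abs=1e-12)

    def test_skew_lines_distance(self):
        # track line {(1, t, 5)} is 1 cm from the z axis; nearest beam point z=5
        vtx, doca = poca_vertex((1.0, -3.0, 5.0), (0.0, 1.0, 0.0),
                                (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        assert np.allclose(vtx, (0.0, 0.0, 5.0), atol=1e-12)
        assert doca == pytest.approx(1.0, abs=1e-12)

    def test_parallel_lines_raise(self):
        with pytest.raises(ReconstructionError, match="parallel"):
            poca_vertex((1.0, 0.0, 0.0), (0.0, 0.0, 1.0),
                        (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))

    def test_vertex_exact_for_ideal_chain(self):
        """Ideal detection of a track emitted from a known point on the beam
        axis returns that point exactly."""
        tracker = TrackerSpec(theta=90.0, distance=40.0)
        true_vertex = np.array([0.0, 0.0, -3.7])
        trk = FragmentTrack(PROTON, true_vertex,
                            np.array([1.0, 0.15, 0.3]) / np.linalg.norm([1.0, 0.15, 0.3]),
                            100.0)
        (det,) = detect([trk], tracker)
        vtx, doca = poca_vertex(det.point, det.direction, (0, 0, -20.0), (0, 0, 1.0))
        assert np.allclose(vtx, true_vertex, atol=1e-9)
        assert doca == pytest.approx(0.0, abs=1e-9)

    def test_against_minimisation_oracle(self):
        """Closed-form POCA against direct 2-parameter minimisation of the
        point-to-point distance for random skew line pairs."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            p1 = rng.uniform(-5, 5, 3)
            p2 = rng.uniform(-5, 5, 3)
            d1 = rng.standard_normal(3)
            d2 = rng.standard_normal(3)
            d1 /= np.linalg.norm(d1)
            d2 /= np.linalg.norm(d2)
            if np.linalg.norm(np.cross(d1, d2)) < 0.05:
                continue
            vtx, doca = poca_vertex(p2, d2, p1, d1)

            def dist2(t):
                return float(np.sum((p1 + t[0] * d1 - (p2 + t[1] * d2)) ** 2))

            res = optimize.minimize(dist2, [0.0, 0.0], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14})
            assert np.allclose(vtx, p1 + res.x[0] * d1, atol=1e-3)
            assert doca == pytest.approx(math.sqrt(res.fun), abs=1e-6)


class TestKinematics:
    def test_half_light_speed_proton(self):
        from fragmon.detection import C_LIGHT

        tof = 2.0
        beta, e_kin = kinematics(tof, 0.5 * C_LIGHT * tof, PROTON.mass)
        assert beta == pytest.approx(0.5, rel=1e-12)
        want = PROTON.mass * (1.0 / math.sqrt(0.75) - 1.0)
        assert e_kin == pytest.approx(want, rel=1e-12)
        assert e_kin == pytest.approx(145.1, abs=1.0)

    def test_superluminal_raises(self):
        from fragmon.detection import C_LIGHT

        with pytest.raises(ReconstructionError, match="beta"):
            kinematics(1.0, 1.1 * C_LIGHT, PROTON.mass)

    def test_scaling_invariance(self):
        b1, e1 = kinematics(1.3, 20.0, PROTON.mass)
        b2, e2 = kinematics(2.6, 40.0, PROTON.mass)
        assert (b1, e1) == (b2, e2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kinematics(-1.0, 10.0, PROTON.mass)
        with pytest.raises(ValueError):
            kinematics(1.0, 0.0, PROTON.mass)


class TestProfile:
    def test_weight_conservation(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, (1000, 3))
        w = rng.uniform(0.1, 2.0, 1000)
        prof = longitudinal_profile(pts, np.linspace(-3, 3, 13), weights=w)
        assert prof.total + prof.underflow + prof.overflow == pytest.approx(w.sum())

    def test_binning_and_errors(self):
        pts = np.array([[0, 0, 0.5], [0, 0, 0.5], [0, 0, 1.5], [0, 0, -10.0]])
        prof = longitudinal_profile(pts, [0.0, 1.0, 2.0], weights=[1.0, 2.0, 3.0, 5.0])
        assert prof.counts.tolist() == [3.0, 3.0]
        assert prof.errors[0] == pytest.approx(math.sqrt(1 + 4))
        assert prof.underflow == 5.0
        assert prof.overflow == 0.0

    def test_custom_axis(self):
        pts = np.array([[2.0, 0.0, 0.0]])
        prof = longitudinal_profile(pts, [1.0, 3.0], axis=(1.0, 0.0, 0.0))
        assert prof.counts[0] == 1.0

    def test_dataframe_round_trip(self):
        prof = longitudinal_profile(np.array([[0, 0, 0.2]]), [0.0, 0.5, 1.0])
        back = EmissionProfile.from_dataframe(prof.to_dataframe())
        assert np.array_equal(back.edges, prof.edges)
        assert np.array_equal(back.counts, prof.counts)

    def test_bad_edges_raise(self):
        with pytest.raises(ValueError):
            longitudinal_profile(np.zeros((1, 3)), [0.0, 0.0, 1.0])
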