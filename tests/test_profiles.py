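"""Profile models, fitting, range observables and dispersion estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragmon.detection import EmissionProfile
from fragmon.profiles import (
    DoubleLogisticParams,
    ErfcParams,
    FitError,
    beam_spot_sigma,
    eval_double_logistic,
    eval_erfc_falloff,
    fit_erfc,
    fit_profile,
    range_observables,
    resample_dispersion,
)

LN15 = math.log(1.5)
REF = DoubleLogisticParams(p0=1000.0, p1=8.0, p2=0.8, p3=2.0, p4=0.4, p5=50.0)
EDGES = np.arange(-2.0, 14.0 + 1e-9, 0.2)


def profile_from_params(p, edges=EDGES, rng=None):
    """Histogram whose bin contents follow the model at the bin centres,
    optionally Poisson-fluctuated."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    y = eval_double_logistic(centers, p)
    if rng is not None:
        y = rng.poisson(y).astype(float)
    return EmissionProfile(edges=edges, counts=y, errors=np.sqrt(np.maximum(y, 1.0)))


def brute_observables(p, n=400001):
    """Independent dense-grid evaluation of the range observables."""
    lo = p.p3 - 15.0 * p.p4 - 6.0 * p.conv_sigma
    hi = p.p1 + 15.0 * p.p2 + 6.0 * p.conv_sigma
    grid = np.linspace(lo, hi, n)
    vals = eval_double_logistic(grid, p)
    f_max = float(vals.max())
    level = p.p5 + 0.4 * (f_max - p.p5)
    above = vals >= level
    i0 = int(np.argmax(above))
    i1 = len(grid) - 1 - int(np.argmax(above[::-1]))
    # linear interpolation across the crossing bins
    x_left = np.interp(level, [vals[i0 - 1], vals[i0]], [grid[i0 - 1], grid[i0]])
    x_right = np.interp(level, [vals[i1 + 1], vals[i1]], [grid[i1 + 1], grid[i1]])
    h = grid[1] - grid[0]
    slope = (np.interp(x_right + h, grid, vals) - np.interp(x_right - h, grid, vals)) / (2 * h)
    d40 = x_right - x_left
    t40 = (x_right + (level - p.p5) / (-slope)) - x_left
    return d40, t40, x_left, x_right


class TestEvaluation:
    def test_plateau_and_background(self):
        # finite edge widths depress the plateau slightly below p0 + p5
        peak = float(np.max(eval_double_logistic(np.linspace(2.0, 8.0, 601), REF)))
        assert peak == pytest.approx(REF.p0 + REF.p5, rel=0.03)
        assert peak < REF.p0 + REF.p5
        assert eval_double_logistic(-30.0, REF) == pytest.approx(REF.p5, abs=1e-6)
        assert eval_double_logistic(40.0, REF) == pytest.approx(REF.p5, abs=1e-6)

    def test_falling_edge_midpoint(self):
        # rise saturated at x = p1: f = p0/2 + p5
        assert eval_double_logistic(REF.p1, REF) == pytest.approx(
            REF.p0 / 2.0 + REF.p5, rel=1e-4)

    def test_convolution_preserves_background_and_plateau(self):
        pc = DoubleLogisticParams(**{**REF.__dict__, "conv_sigma": 0.5,
                                     "cov": None, "chi2": None, "ndf": None})
        assert eval_double_logistic(-30.0, pc) == pytest.approx(REF.p5, abs=1e-3)
        # convolution is norm-preserving: the integrated signal is unchanged
        grid = np.linspace(-10.0, 20.0, 6001)
        area_c = np.trapezoid(eval_double_logistic(grid, pc) - REF.p5, grid)
        area = np.trapezoid(eval_double_logistic(grid, REF) - REF.p5, grid)
        assert area_c == pytest.approx(area, rel=1e-3)

    def test_convolution_widens_the_falloff(self):
        pc = DoubleLogisticParams(1000.0, 8.0, 0.8, 2.0, 0.4, 0.0, conv_sigma=1.5)
        p = DoubleLogisticParams(1000.0, 8.0, 0.8, 2.0, 0.4, 0.0)
        d40_c, *_ = brute_observables(pc)
        d40, *_ = brute_observables(p)
        assert d40_c > d40

    def test_erfc_levels(self):
        p = ErfcParams(a=10.0, b=200.0, c=1.2, d=8.0)
        assert eval_erfc_falloff(-50.0, p) == pytest.approx(10.0 + 400.0, rel=1e-6)
        assert eval_erfc_falloff(50.0, p) == pytest.approx(10.0, rel=1e-6)
        assert eval_erfc_falloff(8.0, p) == pytest.approx(10.0 + 200.0, rel=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DoubleLogisticParams(-1.0, 8.0, 0.8, 2.0, 0.4)
        with pytest.raises(ValueError):
            DoubleLogisticParams(1.0, 8.0, -0.8, 2.0, 0.4)
        with pytest.raises(ValueError):
            DoubleLogisticParams(1.0, 8.0, 0.8, 2.0, 0.4, p5=-1.0)


class TestBeamSpotSigma:
    def test_orthogonal_is_exactly_zero(self):
        assert beam_spot_sigma(0.4, 90.0) == 0.0

    def test_cotangent_values(self):
        assert beam_spot_sigma(0.4, 45.0) == pytest.approx(0.4)
        assert beam_spot_sigma(0.4, 60.0) == pytest.approx(0.4 / math.tan(math.radians(60.0)))
        assert beam_spot_sigma(0.4, 120.0) == pytest.approx(beam_spot_sigma(0.4, 60.0))

    @pytest.mark.parametrize("theta", [0.0, 180.0, -5.0])
    def test_divergent_angles_raise(self, theta):
        with pytest.raises(ValueError):
            beam_spot_sigma(0.4, theta)


class TestFitting:
    def test_noiseless_double_logistic_recovery(self):
        fit = fit_profile(profile_from_params(REF))
        for name in ("p0", "p1", "p2", "p3", "p4", "p5"):
            assert getattr(fit, name) == pytest.approx(getattr(REF, name), rel=1e-5), name
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_erfc_recovery(self):
        p = ErfcParams(a=20.0, b=300.0, c=0.9, d=8.0)
        centers = 0.5 * (EDGES[:-1] + EDGES[1:])
        y = eval_erfc_falloff(centers, p)
        prof = EmissionProfile(EDGES, y, np.sqrt(y))
        fit = fit_erfc(prof)
        for name in ("a", "b", "c", "d"):
            assert getattr(fit, name) == pytest.approx(getattr(p, name), rel=1e-5), name

    def test_erfc_rejects_profile_without_falling_edge(self):
        centers = 0.5 * (EDGES[:-1] + EDGES[1:])
        y = 10.0 + 5.0 * (centers - centers[0])  # monotone rise, no fall-off
        with pytest.raises(FitError):
            fit_erfc(EmissionProfile(EDGES, y, np.sqrt(y)))

    def test_too_few_bins_raise(self):
        prof = EmissionProfile(np.linspace(0, 1, 6), np.ones(5), np.ones(5))
        with pytest.raises(FitError):
            fit_profile(prof)
        with pytest.raises(FitError):
            fit_erfc(prof)

    def test_convolved_fit_recovers_edges(self):
        conv = 0.6
        pc = DoubleLogisticParams(1000.0, 8.0, 0.8, 2.0, 0.4, 50.0, conv_sigma=conv)
        fit = fit_profile(profile_from_params(pc), conv_sigma=conv)
        assert fit.p1 == pytest.approx(8.0, abs=0.05)
        assert fit.p3 == pytest.approx(2.0, abs=0.05)
        assert fit.p2 == pytest.approx(0.8, abs=0.05)

    def test_erfc_uncertainty_coverage(self):
        """Over Poisson replicas the fitted fall-off position d covers the
        truth within 2 sigma at roughly the Gaussian rate."""
        p = ErfcParams(a=20.0, b=300.0, c=0.9, d=8.0)
        centers = 0.5 * (EDGES[:-1] + EDGES[1:])
        mu = eval_erfc_falloff(centers, p)
        rng = np.random.default_rng(31)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.poisson(mu).astype(float)
            fit = fit_erfc(EmissionProfile(EDGES, y, np.sqrt(np.maximum(y, 1.0))))
            err_d = math.sqrt(fit.cov[3, 3])
            hits += abs(fit.d - p.d) < 2.0 * err_d
        assert 0.85 < hits / n_rep <= 1.0

    def test_delta40_pull_distribution(self):
        """The propagated Delta40 uncertainty is statistically calibrated:
        pulls over Poisson replicas have unit spread within 30%."""
        centers = 0.5 * (EDGES[:-1] + EDGES[1:])
        mu = eval_double_logistic(centers, REF)
        truth = brute_observables(REF)[0]
        rng = np.random.default_rng(37)
        pulls = []
        for _ in range(200):
            y = rng.poisson(mu).astype(float)
            prof = EmissionProfile(EDGES, y, np.sqrt(np.maximum(y, 1.0)))
            try:
                obs = range_observables(fit_profile(prof))
            except FitError:
                continue
            if np.isfinite(obs.err_delta40) and obs.err_delta40 > 0:
                pulls.append((obs.delta40 - truth) / obs.err_delta40)
        assert len(pulls) > 180
        assert 0.7 < np.std(pulls) < 1.3
        assert abs(np.mean(pulls)) < 0.3


class TestObservables:
    def test_closed_forms_in_well_separated_limit(self):
        p = DoubleLogisticParams(1000.0, 20.0, 0.8, 0.0, 0.4, 0.0)
        obs = range_observables(p)
        assert obs.x_right == pytest.approx(p.p1 + p.p2 * LN15, abs=1e-6)
        assert obs.x_left == pytest.approx(p.p3 - p.p4 * LN15, abs=1e-6)
        assert obs.delta40 == pytest.approx(obs.x_right - obs.x_left, abs=1e-9)
        assert obs.delta40_tangent == pytest.approx(obs.delta40 + (5.0 / 3.0) * p.p2,
                                                    abs=1e-6)

    def test_against_brute_scan_on_random_parameters(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            p0 = rng.uniform(50.0, 2000.0)
            p2 = rng.uniform(0.3, 1.5)
            p4 = rng.uniform(0.1, 0.8)
            p3 = rng.uniform(-5.0, 0.0)
            p1 = p3 + rng.uniform(4.0, 10.0)
            p5 = rng.uniform(0.0, 0.2) * p0
            p = DoubleLogisticParams(p0, p1, p2, p3, p4, p5)
            obs = range_observables(p)
            d40, t40, xl, xr = brute_observables(p)
            assert obs.delta40 == pytest.approx(d40, abs=1e-4)
            assert obs.delta40_tangent == pytest.approx(t40, abs=1e-4)
            assert obs.x_left == pytest.approx(xl, abs=1e-4)
            assert obs.x_right == pytest.approx(xr, abs=1e-4)

    def test_background_shift_leaves_delta40(self):
        base = DoubleLogisticParams(1000.0, 8.0, 0.8, 2.0, 0.4, 0.0)
        shifted = DoubleLogisticParams(1000.0, 8.0, 0.8, 2.0, 0.4, 200.0)
        assert range_observables(shifted).delta40 == pytest.approx(
            range_observables(base).delta40, abs=1e-6)

    @settings(max_examples=25)
    @given(
        p2=st.floats(min_value=0.3, max_value=1.5),
        p4=st.floats(min_value=0.1, max_value=0.8),
        sep=st.floats(min_value=4.0, max_value=12.0),
        bg=st.floats(min_value=0.0, max_value=0.2),
    )
    def test_tangent_width_dominates(self, p2, p4, sep, bg):
        p = DoubleLogisticParams(1000.0, sep, p2, 0.0, p4, bg * 1000.0)
        obs = range_observables(p)
        assert obs.delta40_tangent > obs.delta40
        assert obs.x_right > obs.x_left

    def test_unordered_edges_raise(self):
        with pytest.raises(ValueError, match="p1 > p3"):
            range_observables(DoubleLogisticParams(1.0, 2.0, 0.5, 8.0, 0.5, 0.0))


class TestDispersion:
    @staticmethod
    def _z_sample(n, rng):
        """Longitudinal coordinates distributed as the reference profile."""
        grid = np.linspace(-2.0, 14.0, 4001)
        pdf = eval_double_logistic(grid, REF)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        return np.interp(rng.random(n), cdf, grid)

    def test_single_sample_reports_missing_sigma(self):
        z = self._z_sample(1200, np.random.default_rng(3))
        res = resample_dispersion(z, EDGES, n_tracks=1000, n_samples=1, seed=1)
        assert res.sigma_delta40 is None
        assert res.sigma_x_left is None
        assert res.n_samples == 1
        assert np.isfinite(res.mean_delta40)

    def test_insufficient_tracks_raise(self):
        z = self._z_sample(1500, np.random.default_rng(4))
        with pytest.raises(ValueError, match="disjoint"):
            resample_dispersion(z, EDGES, n_tracks=1000, n_samples=2, seed=1)

    def test_bad_mode_raises(self):
        z = self._z_sample(1200, np.random.default_rng(5))
        with pytest.raises(ValueError, match="mode"):
            resample_dispersion(z, EDGES, n_tracks=1000, n_samples=1, mode="jackknife")

    def test_disjoint_dispersion_scales_with_statistics(self):
        """sigma(Delta40) follows ~1/sqrt(n) between 1000- and 4000-track
        samples."""
        rng = np.random.default_rng(6)
        z_small = self._z_sample(60000, rng)
        z_large = self._z_sample(240000, rng)
        r_small = resample_dispersion(z_small, EDGES, n_tracks=1000, n_samples=60, seed=2)
        r_large = resample_dispersion(z_large, EDGES, n_tracks=4000, n_samples=60, seed=3)
        ratio = r_small.sigma_delta40 / r_large.sigma_delta40
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_bootstrap_close_to_disjoint(self):
        rng = np.random.default_rng(7)
        z = self._z_sample(40000, rng)
        r_dis = resample_dispersion(z, EDGES, n_tracks=1000, n_samples=40, seed=2)
        r_boot = resample_dispersion(z, EDGES, n_tracks=1000, n_samples=40, seed=2,
                                     mode="bootstrap")
        assert r_boot.sigma_delta40 == pytest.approx(r_dis.sigma_delta40, rel=0.5)
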