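"""Fall-off models for longitudinal emission profiles and the range
observables derived from them.

Two fall-off parameterizations are provided: the complementary-error-function
form ``f(x) = a + b erfc[c (x - d)]`` whose inflection point ``d`` tracks the
primary range, and the double-logistic form

    f(x) = p0 / (1 + exp((x - p1)/p2)) / (1 + exp(-(x - p3)/p4)) + p5

whose rising (p3, p4) and falling (p1, p2) edges describe the full emission
profile over a flat background p5, optionally convolved with a Gaussian of
width sigma_beam x cot(theta) to account for the beam-spot shadow at
non-orthogonal detection angles.

From a fitted double-logistic the range observables are extracted:
Delta40, the width of the profile at 40% of its maximum (above background);
X_left/X_right, the corresponding crossing positions; and delta40, the
distance from X_left to the intercept of the tangent at X_right with the
background level.  Dispersions at fixed track statistics are estimated by
disjoint (or bootstrap) resampling of the track dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq, curve_fit, minimize_scalar
from scipy.special import erfc

from .detection import EmissionProfile, longitudinal_profile

__all__ = [
    "ErfcParams",
    "DoubleLogisticParams",
    "RangeObservables",
    "DispersionResult",
    "FitError",
    "eval_double_logistic",
    "eval_erfc_falloff",
    "beam_spot_sigma",
    "fit_erfc",
    "fit_profile",
    "range_observables",
    "resample_dispersion",
]


class FitError(RuntimeError):
    """Raised when a profile fit fails to converge or is degenerate."""


@dataclass
class ErfcParams:
    """Parameters of the erfc fall-off ``f(x) = a + b erfc[c (x - d)]``."""

    a: float    # background level
    b: float    # amplitude
    c: float    # inverse width, 1/cm
    d: float    # inflection position, cm
    cov: np.ndarray | None = None
    chi2: float | None = None
    ndf: int | None = None


@dataclass
class DoubleLogisticParams:
    """Parameters of the double-logistic profile model.

    p1/p2 are the falling-edge midpoint and width, p3/p4 the rising-edge
    midpoint and width, p0 the plateau amplitude and p5 a flat background;
    ``conv_sigma`` is an optional Gaussian convolution width (the beam-spot
    term sigma_beam x cot(theta))."""

    p0: float
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float = 0.0
    conv_sigma: float = 0.0
    cov: np.ndarray | None = None
    chi2: float | None = None
    ndf: int | None = None

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError("plateau amplitude p0 must be positive")
        if self.p2 <= 0 or self.p4 <= 0:
            raise ValueError("edge widths p2, p4 must be positive")
        if self.p5 < 0:
            raise ValueError("background p5 must be >= 0")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2, self.p3, self.p4, self.p5])


@dataclass
class RangeObservables:
    """Range observables of a fitted profile (all cm)."""

    delta40: float          # width at 40% of maximum (Delta_40)
    delta40_tangent: float  # X_left to tangent intercept (delta_40)
    x_left: float
    x_right: float
    err_delta40: float = float("nan")
    err_delta40_tangent: float = float("nan")
    err_x_left: float = float("nan")
    err_x_right: float = float("nan")


@dataclass
class DispersionResult:
    """Spread of the range observables over fixed-statistics subsamples."""

    sigma_delta40: float | None
    sigma_delta40_tangent: float | None
    sigma_x_left: float | None
    mean_delta40: float
    mean_delta40_tangent: float
    mean_x_left: float
    n_samples: int
    n_tracks_per_sample: int
    seed: int | None


def _raw_double_logistic(x: np.ndarray, p0, p1, p2, p3, p4, p5) -> np.ndarray:
    fall = 1.0 / (1.0 + np.exp(np.clip((x - p1) / p2, -700.0, 700.0)))
    rise = 1.0 / (1.0 + np.exp(np.clip(-(x - p3) / p4, -700.0, 700.0)))
    return p0 * fall * rise + p5


def eval_double_logistic(x, p: DoubleLogisticParams):
    """Evaluate the double-logistic model, numerically convolved with a
    Gaussian of width ``p.conv_sigma`` when that is positive.

    The convolution acts on the signal (plateau) part; the flat background is
    invariant under it.  The quadrature grid is ~10x finer than the
    structure scale (min edge width, conv sigma)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if p.conv_sigma <= 0:
        out = _raw_double_logistic(x, *p.vector)
    else:
        sigma = p.conv_sigma
        step = min(p.p2, p.p4, sigma) / 10.0
        lo = x.min() - 6.0 * sigma
        hi = x.max() + 6.0 * sigma
        grid = np.arange(lo, hi + step, step)
        signal = _raw_double_logistic(grid, p.p0, p.p1, p.p2, p.p3, p.p4, 0.0)
        half = int(math.ceil(5.0 * sigma / step))
        k = np.exp(-0.5 * ((np.arange(-half, half + 1) * step) / sigma) ** 2)
        k /= k.sum()
        smooth = np.convolve(signal, k, mode="same")
        out = np.interp(x, grid, smooth) + p.p5
    return float(out[0]) if scalar else out


def eval_erfc_falloff(x, p: ErfcParams):
    x = np.asarray(x, dtype=float)
    return p.a + p.b * erfc(p.c * (x - p.d))


def beam_spot_sigma(sigma_beam: float, theta: float) -> float:
    """Beam-spot shadow term |sigma_beam x cot(theta)| in cm.

    Vanishes exactly at orthogonal detection and diverges toward 0/180 deg.
    """
    if theta <= 0.0 or theta >= 180.0:
        raise ValueError("cot(theta) diverges at theta = 0 or 180 deg")
    if theta == 90.0:
        return 0.0
    return abs(sigma_beam / math.tan(math.radians(theta)))


def _fit_weights(counts: np.ndarray) -> np.ndarray:
    # Poisson-derived per-bin sigma with a unit floor for empty bins
    return np.sqrt(np.maximum(counts, 1.0))


def fit_erfc(profile: EmissionProfile, init: ErfcParams | None = None,
             restarts: int = 5, seed: int = 0) -> ErfcParams:
    """Weighted least-squares fit of the erfc fall-off to a profile."""
    x = profile.centers
    y = profile.counts
    if np.count_nonzero(y) < 8:
        raise FitError("need at least 8 non-empty bins spanning the fall-off")
    sigma = _fit_weights(y)
    if init is None:
        a0 = float(np.min(y))
        b0 = max((float(np.max(y)) - a0) / 2.0, 1e-9)
        half = a0 + b0
        above = np.nonzero(y >= half)[0]
        d0 = float(x[above[-1]]) if len(above) else float(np.median(x))
        c0 = 1.0 / (2.0 * float(np.mean(np.diff(profile.edges))))
        init = ErfcParams(a0, b0, c0, d0)
    p0 = [init.a, init.b, init.c, init.d]

    def model(xv, a, b, c, d):
        return a + b * erfc(c * (xv - d))

    rng = np.random.default_rng(seed)
    last_exc: Exception | None = None
    for attempt in range(restarts):
        trial = p0 if attempt == 0 else [
            v * (1.0 + 0.2 * rng.standard_normal()) for v in p0
        ]
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=trial, sigma=sigma, absolute_sigma=True, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        a, b, c, d = popt
        if c <= 0 or not (x[0] - 2.0 <= d <= x[-1] + 2.0) or b <= 0:
            last_exc = FitError(
                f"degenerate erfc fit (b={b:.3g}, c={c:.3g}, d={d:.3g}); "
                "profile may lack a falling edge"
            )
            continue
        resid = (model(x, *popt) - y) / sigma
        return ErfcParams(a, b, c, d, cov=pcov,
                          chi2=float(np.sum(resid**2)), ndf=len(x) - 4)
    raise FitError(f"erfc fit failed after {restarts} restarts: {last_exc}")


def _initial_double_logistic(profile: EmissionProfile) -> list[float]:
    x, y = profile.centers, profile.counts
    p0 = float(np.quantile(y, 0.90))
    n_outer = max(len(y) // 10, 2)
    p5 = float(np.median(np.concatenate([y[:n_outer], y[-n_outer:]])))
    p5 = min(max(p5, 0.0), 0.9 * p0)
    level = p5 + 0.4 * (p0 - p5)
    above = np.nonzero(y >= level)[0]
    if len(above) == 0:
        raise FitError("no bins reach 40% of the plateau estimate")
    p3 = float(x[above[0]])
    p1 = float(x[above[-1]])
    width = 3.0 * float(np.mean(np.diff(profile.edges)))
    return [max(p0 - p5, 1e-9), p1, width, p3, width, p5]


def fit_profile(profile: EmissionProfile, conv_sigma: float = 0.0,
                init: DoubleLogisticParams | None = None,
                restarts: int = 5, seed: int = 0) -> DoubleLogisticParams:
    """Weighted least-squares fit of the double-logistic model (optionally
    convolved with a fixed ``conv_sigma``) to a profile.

    Initialization from profile quantiles: plateau from the 90th percentile
    bin content, background from the outer-bin median, edge midpoints from
    the 40%-crossing estimates on the raw histogram; up to ``restarts``
    jittered retries on failure."""
    x = profile.centers
    y = profile.counts
    if np.count_nonzero(y) < 8:
        raise FitError("need at least 8 non-empty bins spanning both edges")
    sigma = _fit_weights(y)
    start = (
        [init.p0, init.p1, init.p2, init.p3, init.p4, init.p5]
        if init is not None
        else _initial_double_logistic(profile)
    )
    bin_w = float(np.mean(np.diff(profile.edges)))
    lower = [1e-12, x[0] - 5.0, bin_w / 20.0, x[0] - 5.0, bin_w / 20.0, 0.0]
    upper = [np.inf, x[-1] + 5.0, np.inf, x[-1] + 5.0, np.inf, np.inf]

    if conv_sigma > 0:
        def model(xv, p0, p1, p2, p3, p4, p5):
            return eval_double_logistic(
                xv, DoubleLogisticParams(p0, p1, p2, p3, p4, p5, conv_sigma)
            )
    else:
        def model(xv, p0, p1, p2, p3, p4, p5):
            return _raw_double_logistic(xv, p0, p1, p2, p3, p4, p5)

    rng = np.random.default_rng(seed)
    last_exc: Exception | None = None
    for attempt in range(restarts):
        trial = list(start)
        if attempt > 0:
            jitter = 1.0 + 0.2 * rng.standard_normal(6)
            trial = [v * j if abs(v) > 1e-12 else v for v, j in zip(trial, jitter)]
        trial = [min(max(t, lo + 1e-12), up) if np.isfinite(up) else max(t, lo + 1e-12)
                 for t, lo, up in zip(trial, lower, upper)]
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=trial, sigma=sigma, absolute_sigma=True,
                bounds=(lower, upper), maxfev=40000, xtol=1e-10, ftol=1e-10,
            )
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        if popt[1] <= popt[3]:
            last_exc = FitError(
                "fitted falling edge precedes the rising edge (p1 <= p3)"
            )
            continue
        resid = (model(x, *popt) - y) / sigma
        return DoubleLogisticParams(
            *popt, conv_sigma=conv_sigma, cov=pcov,
            chi2=float(np.sum(resid**2)), ndf=len(x) - 6,
        )
    raise FitError(f"double-logistic fit failed after {restarts} restarts: {last_exc}")


def _observables_point(vec: np.ndarray, conv_sigma: float) -> np.ndarray:
    """(delta40, delta40_tangent, x_left, x_right) for a parameter vector."""
    p = DoubleLogisticParams(*vec, conv_sigma=conv_sigma)
    if p.p1 <= p.p3:
        raise ValueError("physical profiles require p1 > p3")

    def f(x):
        return eval_double_logistic(x, p)

    span_lo = p.p3 - 12.0 * p.p4 - 6.0 * conv_sigma
    span_hi = p.p1 + 12.0 * p.p2 + 6.0 * conv_sigma
    grid = np.linspace(span_lo, span_hi, 4001)
    vals = f(grid)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(lambda x: -f(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    f_max = float(-res.fun)
    level = p.p5 + 0.4 * (f_max - p.p5)

    above = vals >= level
    if not above.any():
        raise ValueError("profile never reaches the 40% level")
    i_first = int(np.argmax(above))
    i_last = len(above) - 1 - int(np.argmax(above[::-1]))
    if i_first == 0 or i_last == len(grid) - 1:
        raise ValueError("40% level not bracketed inside the scan window")
    g = lambda x: f(x) - level
    x_left = brentq(g, grid[i_first - 1], grid[i_first], xtol=1e-12)
    x_right = brentq(g, grid[i_last], grid[i_last + 1], xtol=1e-12)

    h = 1e-6 * max(p.p2, 1.0)
    slope = (f(x_right + h) - f(x_right - h)) / (2.0 * h)
    if slope >= 0:
        raise ValueError("profile is not falling at X_right")
    # tangent through (x_right, level) meets the background level p5 at:
    x_intercept = x_right + (level - p.p5) / (-slope)
    d40 = x_right - x_left
    return np.array([d40, x_intercept - x_left, x_left, x_right])


def range_observables(p: DoubleLogisticParams) -> RangeObservables:
    """Extract Delta40, delta40, X_left and X_right from fitted parameters.

    The 40% level is taken above the flat background: level = p5 +
    0.4 (max f - p5), which makes Delta40 invariant under background shifts;
    X_left/X_right are the outermost crossings of that level, found by
    bracketed root-finding; delta40 extends X_right to the intercept of the
    tangent at X_right with the background level.  Uncertainties are
    propagated from the fit covariance with a numerical Jacobian.
    """
    vec = p.vector
    vals = _observables_point(vec, p.conv_sigma)
    errs = np.full(4, np.nan)
    if p.cov is not None:
        jac = np.zeros((4, 6))
        for j in range(6):
            h = 1e-5 * max(abs(vec[j]), 1e-3)
            vp, vm = vec.copy(), vec.copy()
            vp[j] += h
            vm[j] -= h
            try:
                jac[:, j] = (_observables_point(vp, p.conv_sigma)
                             - _observables_point(vm, p.conv_sigma)) / (2.0 * h)
            except ValueError:
                jac[:, j] = 0.0
        var = np.einsum("ij,jk,ik->i", jac, np.asarray(p.cov), jac)
        errs = np.sqrt(np.maximum(var, 0.0))
    return RangeObservables(
        delta40=vals[0], delta40_tangent=vals[1], x_left=vals[2], x_right=vals[3],
        err_delta40=errs[0], err_delta40_tangent=errs[1],
        err_x_left=errs[2], err_x_right=errs[3],
    )


def resample_dispersion(
    z_values,
    edges,
    n_tracks: int = 1000,
    n_samples: int | None = None,
    seed: int = 0,
    conv_sigma: float = 0.0,
    weights=None,
    mode: str = "disjoint",
) -> DispersionResult:
    """Dispersion of the range observables at fixed track statistics.

    Draws ``n_samples`` disjoint (default) or bootstrap subsets of
    ``n_tracks`` longitudinal coordinates, runs histogram -> double-logistic
    fit -> observables on each, and returns the standard deviations and means
    of Delta40, delta40 and X_left.  With a single sample the dispersions are
    reported as missing (None), never as zero.
    """
    z = np.asarray(z_values, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    if mode not in ("disjoint", "bootstrap"):
        raise ValueError("mode must be 'disjoint' or 'bootstrap'")
    max_disjoint = len(z) // n_tracks
    if n_samples is None:
        n_samples = max_disjoint if mode == "disjoint" else 50
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode == "disjoint":
        if n_samples * n_tracks > len(z):
            raise ValueError(
                f"disjoint mode needs {n_samples * n_tracks} tracks, have {len(z)}"
            )
        perm = rng.permutation(len(z))
    d40s, t40s, xls = [], [], []
    pts = np.zeros((n_tracks, 3))
    for i in range(n_samples):
        if mode == "disjoint":
            idx = perm[i * n_tracks:(i + 1) * n_tracks]
        else:
            idx = rng.integers(0, len(z), n_tracks)
        pts[:, 2] = z[idx]
        prof = longitudinal_profile(pts, edges, weights=None if w is None else w[idx])
        params = fit_profile(prof, conv_sigma=conv_sigma, seed=seed + i + 1)
        obs = range_observables(params)
        d40s.append(obs.delta40)
        t40s.append(obs.delta40_tangent)
        xls.append(obs.x_left)
    d40s, t40s, xls = map(np.asarray, (d40s, t40s, xls))
    if n_samples < 2:
        s_d = s_t = s_x = None
    else:
        s_d = float(np.std(d40s, ddof=1))
        s_t = float(np.std(t40s, ddof=1))
        s_x = float(np.std(xls, ddof=1))
    return DispersionResult(
        sigma_delta40=s_d, sigma_delta40_tangent=s_t, sigma_x_left=s_x,
        mean_delta40=float(np.mean(d40s)),
        mean_delta40_tangent=float(np.mean(t40s)),
        mean_x_left=float(np.mean(xls)),
        n_samples=n_samples, n_tracks_per_sample=n_tracks, seed=seed,
    )
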