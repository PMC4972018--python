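"""Absorption unfolding of emission profiles via thickness look-up tables.

Fragments emitted deep in a phantom traverse more material on their way to
the detector and are preferentially absorbed, which distorts the reconstructed
longitudinal emission profile.  This module builds a look-up table (LUT) of
double-logistic profile parameters as a function of the crossed
water-equivalent thickness x, generalises the profile model to f(z, x), and
corrects each detected track with the weight

    w(z, x) = f(z, x0) / f(z, x)

relative to a reference thickness x0, so that the weighted histogram recovers
the undistorted (reference-shape) emission profile.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .detection import EmissionProfile, TrackerSpec, detect, longitudinal_profile, poca_vertex
from .emission import EmissionModel, sample_tracks, survival_probability
from .geometry import Phantom
from .profiles import DoubleLogisticParams, eval_double_logistic, fit_profile
from .transport import BeamSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AbsorptionLUT",
    "build_lut",
    "params_at",
    "f_zx",
    "track_weight",
    "track_weights",
    "unfold_profile",
]

DEFAULT_THICKNESS_GRID = (2.5, 4.0, 5.5, 7.0, 8.5, 10.0)
PARAM_NAMES = ("p0", "p1", "p2", "p3", "p4", "p5")


class UnfoldingError(ValueError):
    pass


@dataclass
class AbsorptionLUT:
    """Double-logistic parameters vs crossed thickness, with per-parameter
    polynomial models over the thickness span."""

    thicknesses: np.ndarray                  # cm WET, strictly increasing
    node_params: list[DoubleLogisticParams]  # fitted per node
    poly_coeffs: dict[str, np.ndarray]       # np.polyval convention
    x0: float = 2.5                          # reference thickness, cm
    degree: int = 2
    seed: int | None = None
    w_max: float = 20.0
    floor_fraction: float = 1e-3

    def __post_init__(self) -> None:
        self.thicknesses = np.asarray(self.thicknesses, dtype=float)
        if len(self.thicknesses) < 4:
            raise UnfoldingError("LUT needs at least 4 thickness nodes")
        if np.any(np.diff(self.thicknesses) <= 0):
            raise UnfoldingError("thickness grid must be strictly increasing")
        if not (self.thicknesses[0] <= self.x0 <= self.thicknesses[-1]):
            raise UnfoldingError("reference x0 must lie inside the grid span")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.thicknesses[0]), float(self.thicknesses[-1])

    def to_json(self, path) -> None:
        doc = {
            "thicknesses_cm": self.thicknesses.tolist(),
            "x0_cm": self.x0,
            "degree": self.degree,
            "seed": self.seed,
            "w_max": self.w_max,
            "floor_fraction": self.floor_fraction,
            "node_params": [
                {k: getattr(p, k) for k in PARAM_NAMES} for p in self.node_params
            ],
            "poly_coeffs": {k: v.tolist() for k, v in self.poly_coeffs.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AbsorptionLUT":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            thicknesses=np.asarray(doc["thicknesses_cm"]),
            node_params=[DoubleLogisticParams(**d) for d in doc["node_params"]],
            poly_coeffs={k: np.asarray(v) for k, v in doc["poly_coeffs"].items()},
            x0=doc["x0_cm"],
            degree=doc["degree"],
            seed=doc.get("seed"),
            w_max=doc.get("w_max", 20.0),
            floor_fraction=doc.get("floor_fraction", 1e-3),
        )


def build_lut(
    beam: BeamSpec,
    phantom: Phantom,
    tracker: TrackerSpec,
    model: EmissionModel,
    thicknesses=DEFAULT_THICKNESS_GRID,
    n_tracks: int = 20000,
    seed: int = 0,
    edges=None,
    degree: int = 2,
    x0: float | None = None,
) -> AbsorptionLUT:
    """Build an absorption LUT by simulating the detected profile at each
    fixed exit thickness.

    For each thickness node the full chain is run -- track sampling, survival
    at that (forced) exit thickness, detector acceptance/smearing, POCA
    reconstruction, weighted histogramming -- and the resulting profile is
    fitted with the double-logistic model (counts normalised per sampled
    track).  Each parameter series p_i(x_j) is then modelled with an ordinary
    least-squares polynomial of the given degree.  Overriding the geometric
    exit path with a constant thickness emulates a family of targets of
    varying radius without rebuilding the geometry per node.
    """
    thicknesses = np.asarray(sorted(thicknesses), dtype=float)
    if len(thicknesses) < 4:
        raise UnfoldingError("need at least 4 thicknesses")
    if not (1 <= degree <= 3):
        raise UnfoldingError("polynomial degree must be 1-3")
    if edges is None:
        edges = _default_edges(beam, phantom, model)
    x0 = float(thicknesses[0]) if x0 is None else float(x0)

    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(thicknesses))
    node_params = []
    for x_j, stream in zip(thicknesses, streams):
        rng = np.random.default_rng(stream)
        tracks = sample_tracks(beam, phantom, model, n_tracks,
                               theta_aim=tracker.theta, seed=rng)
        surv = np.array(
            [survival_probability(t, phantom, model, exit_wet=float(x_j)) for t in tracks]
        )
        detected = detect(tracks, tracker, seed=rng, weights=surv)
        if len(detected) < 50:
            raise UnfoldingError(
                f"thickness {x_j} cm: only {len(detected)} detected tracks"
            )
        beam_point = np.asarray(beam.entry_point, dtype=float)
        beam_dir = np.asarray(beam.direction, dtype=float)
        pts = np.array(
            [poca_vertex(d.point, d.direction, beam_point, beam_dir)[0] for d in detected]
        )
        w = np.array([d.weight for d in detected]) / n_tracks
        profile = longitudinal_profile(pts, edges, weights=w, axis=beam_dir)
        try:
            params = fit_profile(profile, seed=seed)
        except Exception as exc:
            raise UnfoldingError(f"profile fit failed at thickness {x_j} cm: {exc}")
        node_params.append(params)

    poly = {}
    for k, name in enumerate(PARAM_NAMES):
        series = np.array([p.vector[k] for p in node_params])
        poly[name] = np.polyfit(thicknesses, series, deg=degree)
    return AbsorptionLUT(
        thicknesses=thicknesses, node_params=node_params, poly_coeffs=poly,
        x0=x0, degree=degree, seed=seed,
    )


def _default_edges(beam, phantom, model, bin_width: float = 0.2) -> np.ndarray:
    from .emission import emission_density

    density = emission_density(beam, phantom, model)
    lo = density.u_entry - 2.0
    hi = density.u_stop + 2.0
    n = int(math.ceil((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def params_at(lut: AbsorptionLUT, x: float, mode: str = "raise") -> DoubleLogisticParams:
    """Double-logistic parameters at an arbitrary thickness by polynomial
    evaluation.

    ``mode`` controls behaviour outside the grid span: ``"raise"`` (default),
    ``"clip"`` (evaluate at the nearest span edge) or ``"extrapolate"``.
    """
    lo, hi = lut.span
    if not (lo <= x <= hi):
        if mode == "raise":
            raise UnfoldingError(
                f"thickness {x} cm outside the LUT span [{lo}, {hi}] cm "
                "(pass mode='clip' or 'extrapolate' to override)"
            )
        if mode == "clip":
            x = min(max(x, lo), hi)
        elif mode != "extrapolate":
            raise ValueError("mode must be 'raise', 'clip' or 'extrapolate'")
    vals = {k: float(np.polyval(lut.poly_coeffs[k], x)) for k in PARAM_NAMES}
    vals["p5"] = max(vals["p5"], 0.0)
    return DoubleLogisticParams(**vals)


def f_zx(z, x: float, lut: AbsorptionLUT, mode: str = "raise"):
    """Generalised emission function f(z, x): the double-logistic profile
    evaluated with the LUT parameters at thickness x."""
    return eval_double_logistic(z, params_at(lut, x, mode=mode))


def _reference_floor(lut: AbsorptionLUT) -> float:
    p_ref = params_at(lut, lut.x0, mode="clip")
    grid = np.linspace(p_ref.p3 - 10 * p_ref.p4, p_ref.p1 + 10 * p_ref.p2, 801)
    return lut.floor_fraction * float(np.max(eval_double_logistic(grid, p_ref)))


def track_weight(z: float, x: float, lut: AbsorptionLUT, mode: str = "raise") -> float:
    """Per-track absorption correction w(z, x) = f(z, x0) / f(z, x).

    Capped at ``lut.w_max``; a denominator below the configured floor is
    capped (with a logged warning), never a silent infinity; exactly 1 at the
    reference thickness."""
    w, n_capped = track_weights(np.asarray([z]), np.asarray([x]), lut, mode=mode)
    return float(w[0])


def track_weights(z, x, lut: AbsorptionLUT, mode: str = "raise"):
    """Vectorised ``track_weight``; returns (weights, number capped)."""
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    floor = _reference_floor(lut)
    w = np.empty_like(z)
    n_capped = 0
    # group by unique thickness to reuse parameter evaluations
    for xv in np.unique(x):
        sel = x == xv
        if xv == lut.x0:
            w[sel] = 1.0
            continue
        num = f_zx(z[sel], lut.x0, lut, mode=mode)
        den = f_zx(z[sel], xv, lut, mode=mode)
        low = den <= floor
        ratio = num / np.where(low, floor, den)
        capped = low | (ratio > lut.w_max)
        n_capped += int(np.count_nonzero(capped))
        w[sel] = np.minimum(ratio, lut.w_max)
    if n_capped:
        logger.warning("capped %d of %d track weights", n_capped, len(z))
    return w, n_capped


def unfold_profile(z_reco, x_exit, lut: AbsorptionLUT, edges,
                   weights=None, mode: str = "raise"):
    """Absorption-corrected and uncorrected emission profiles.

    Each track with reconstructed emission coordinate ``z_reco`` and
    exit-path thickness ``x_exit`` enters the corrected histogram with the
    multiplicative weight w(z, x); tracks with missing (NaN) thickness are
    skipped and counted.

    Returns
    -------
    (corrected, uncorrected, info) : (EmissionProfile, EmissionProfile, dict)
        ``info`` holds the skipped-track and capped-weight counts.
    """
    z = np.asarray(z_reco, dtype=float)
    x = np.asarray(x_exit, dtype=float)
    base_w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(x) & np.isfinite(z)
    n_skipped = int(np.count_nonzero(~ok))
    if n_skipped:
        logger.warning("skipping %d tracks with missing exit thickness", n_skipped)
    z, x, base_w = z[ok], x[ok], base_w[ok]
    corr_w, n_capped = track_weights(z, x, lut, mode=mode)
    pts = np.zeros((len(z), 3))
    pts[:, 2] = z
    corrected = longitudinal_profile(pts, edges, weights=base_w * corr_w)
    uncorrected = longitudinal_profile(pts, edges, weights=base_w)
    info = {"n_skipped": n_skipped, "n_capped": n_capped,
            "capped_fraction": n_capped / max(len(z), 1)}
    return corrected, uncorrected, info
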