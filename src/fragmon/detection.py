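"""Detector acceptance, measurement smearing and emission-point
reconstruction.

A planar tracker of given angle, distance and active area accepts fragment
tracks, smears their measured direction and crossing point, and each accepted
track is intersected with the known beam line at the point of closest
approach (POCA) to estimate the emission point.  Time-of-flight kinematics
and weighted longitudinal histogramming complete the chain from tracks to an
emission profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

C_LIGHT = 29.9792458  # cm/ns

__all__ = [
    "TrackerSpec",
    "DetectedTrack",
    "EmissionProfile",
    "solid_angle",
    "rectangle_solid_angle",
    "detect",
    "poca_vertex",
    "kinematics",
    "longitudinal_profile",
]


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class TrackerSpec:
    """A planar tracking detector.

    ``theta`` is the angle of the detector axis from the beam (+z) in the x-z
    plane, ``distance`` the phantom-centre-to-detector distance in cm, the
    active area ``a x b`` cm; angular and transverse-point resolutions are
    Gaussian sigmas.
    """

    theta: float                  # deg
    distance: float               # cm
    a: float = 20.0               # cm
    b: float = 20.0               # cm
    angular_sigma: float = 0.0    # rad
    point_sigma: float = 0.0      # cm
    efficiency: float = 1.0
    reference: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 180.0):
            raise ValueError("theta must lie strictly between 0 and 180 deg")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("active area sides must be positive")
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must be in [0, 1]")

    @property
    def axis(self) -> np.ndarray:
        th = math.radians(self.theta)
        return np.array([math.sin(th), 0.0, math.cos(th)])

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.reference) + self.distance * self.axis

    def frame(self):
        """In-plane unit vectors (u along the a side, v along the b side)."""
        axis = self.axis
        v = np.array([0.0, 1.0, 0.0])
        u = np.cross(v, axis)
        u /= np.linalg.norm(u)
        return u, v


@dataclass
class DetectedTrack:
    """A measured track: a line (point on the detector plane, unit
    direction), optional time of flight and measured energy."""

    point: np.ndarray
    direction: np.ndarray
    tof: float | None = None      # ns
    E_meas: float | None = None   # MeV
    species: str = "proton"
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n


@dataclass
class EmissionProfile:
    """Weighted longitudinal histogram with half-open bins [lo, hi)."""

    edges: np.ndarray
    counts: np.ndarray
    errors: np.ndarray
    underflow: float = 0.0
    overflow: float = 0.0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts length must be len(edges) - 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "count": self.counts,
                "err": self.errors,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EmissionProfile":
        edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].iloc[-1]]])
        return cls(edges=edges, counts=df["count"].to_numpy(),
                   errors=df["err"].to_numpy())


def rectangle_solid_angle(a: float, b: float, d: float) -> float:
    """Exact solid angle (sr) of an a x b rectangle viewed on-axis from
    distance d (pyramid formula)."""
    if d <= 0:
        raise ValueError("distance must be positive")
    alpha, beta = a / (2.0 * d), b / (2.0 * d)
    return 4.0 * math.atan(alpha * beta / math.sqrt(1.0 + alpha**2 + beta**2))


def solid_angle(tracker: TrackerSpec) -> float:
    """Solid angle of the tracker aperture from the phantom reference point."""
    return rectangle_solid_angle(tracker.a, tracker.b, tracker.distance)


def detect(
    tracks,
    tracker: TrackerSpec,
    seed: int | np.random.Generator = 0,
    weights=None,
) -> list[DetectedTrack]:
    """Accept, thin and smear fragment tracks.

    Keeps tracks whose straight line crosses the active area, thins by the
    detection efficiency, then smears the crossing point (transverse Gaussian
    in the detector plane) and the direction (Gaussian angular deviations in
    two orthogonal planes).  Deterministic under a fixed seed.  ``weights``
    optionally rescales per-track statistical weights (e.g. survival
    probabilities carried as weights instead of sampled decisions).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = tracker.center
    axis = tracker.axis
    u, v = tracker.frame()
    out: list[DetectedTrack] = []
    for i, trk in enumerate(tracks):
        denom = float(np.dot(trk.direction, axis))
        if denom <= 1e-12:
            continue  # travelling away from or parallel to the detector plane
        t_hit = float(np.dot(center - trk.vertex, axis)) / denom
        if t_hit <= 0:
            continue
        hit = trk.vertex + t_hit * trk.direction
        rel = hit - center
        uu, vv = float(np.dot(rel, u)), float(np.dot(rel, v))
        if abs(uu) > tracker.a / 2.0 or abs(vv) > tracker.b / 2.0:
            continue
        if tracker.efficiency < 1.0 and rng.random() >= tracker.efficiency:
            continue
        if tracker.point_sigma > 0:
            uu += rng.normal(0.0, tracker.point_sigma)
            vv += rng.normal(0.0, tracker.point_sigma)
            hit = center + uu * u + vv * v
        direction = trk.direction
        if tracker.angular_sigma > 0:
            e1, e2 = _perp_frame(direction)
            direction = direction + rng.normal(0, tracker.angular_sigma) * e1 \
                + rng.normal(0, tracker.angular_sigma) * e2
            direction = direction / np.linalg.norm(direction)
        w = trk.weight * (weights[i] if weights is not None else 1.0)
        if w <= 0:
            continue
        out.append(
            DetectedTrack(point=hit, direction=direction,
                          species=trk.species.name, weight=w)
        )
    return out


def _perp_frame(d: np.ndarray):
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def poca_vertex(track_point, track_dir, beam_point, beam_dir):
    """Point of closest approach between the measured track line and the
    known beam line.

    Returns ``(vertex, doca)``: the point ON THE BEAM LINE nearest the track
    line (the emission-point estimate, since the transverse beam position is
    known from the delivery system) and the line-line distance as a quality
    metric.

    Raises
    ------
    ReconstructionError
        For (near-)parallel lines, where the POCA is undefined.
    """
    p1 = np.asarray(beam_point, dtype=float)
    d1 = np.asarray(beam_dir, dtype=float)
    p2 = np.asarray(track_point, dtype=float)
    d2 = np.asarray(track_dir, dtype=float)
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    cross = np.cross(d1, d2)
    sin2 = float(np.dot(cross, cross))
    if math.sqrt(sin2) < 1e-9:
        raise ReconstructionError("beam and track lines are parallel; POCA undefined")
    r = p2 - p1
    b = float(np.dot(d1, d2))
    t1 = (float(np.dot(r, d1)) - b * float(np.dot(r, d2))) / (1.0 - b * b)
    vertex = p1 + t1 * d1
    doca = abs(float(np.dot(r, cross))) / math.sqrt(sin2)
    return vertex, doca


def kinematics(tof: float, flight_path: float, rest_mass: float):
    """(beta, kinetic energy MeV) from a time of flight (ns) and flight path
    (cm): beta = L / (c tof), E_kin = m (gamma - 1)."""
    if tof <= 0 or flight_path <= 0:
        raise ValueError("tof and flight path must be positive")
    beta = flight_path / (C_LIGHT * tof)
    if beta >= 1.0:
        raise ReconstructionError(f"unphysical velocity beta = {beta:.6g} >= 1")
    gamma = 1.0 / math.sqrt(1.0 - beta * beta)
    return beta, rest_mass * (gamma - 1.0)


def longitudinal_profile(points, edges, weights=None, axis=(0.0, 0.0, 1.0)) -> EmissionProfile:
    """Weighted histogram of the beam-axis coordinate of emission points.

    ``points`` is (n, 3); the longitudinal coordinate is the projection on
    ``axis``.  Under/overflow is tracked separately; per-bin errors are
    sqrt(sum of squared weights).
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    z = pts @ np.asarray(axis, dtype=float)
    w = np.ones(len(z)) if weights is None else np.asarray(weights, dtype=float)
    idx = np.searchsorted(edges, z, side="right") - 1
    in_range = (idx >= 0) & (idx < len(edges) - 1) & (z < edges[-1])
    counts = np.bincount(idx[in_range], weights=w[in_range], minlength=len(edges) - 1)
    sq = np.bincount(idx[in_range], weights=w[in_range] ** 2, minlength=len(edges) - 1)
    return EmissionProfile(
        edges=edges,
        counts=counts,
        errors=np.sqrt(sq),
        underflow=float(w[z < edges[0]].sum()),
        overflow=float(w[z >= edges[-1]].sum()),
    )
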