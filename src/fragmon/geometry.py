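"""Analytic phantoms and ray tracing for exit-path thickness.

Phantoms are ordered lists of solid regions (box, cylinder, sphere); later
regions take precedence inside earlier ones, so a nested low-density insert is
expressed by listing it after its host.  The tracing is fully analytic:
per-region chord lengths, water-equivalent thickness (WET), and the exit-path
WET from an emission vertex -- the ``x`` fed to the absorption weighting.

Coordinates are right-handed, lengths in cm, the beam nominally along +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .transport import Material, WATER

_TANGENT_EPS = 1e-12

__all__ = [
    "Sphere",
    "Box",
    "Cylinder",
    "Region",
    "Phantom",
    "Ray",
    "chord_lengths",
    "water_equivalent_thickness",
    "exit_path_thickness",
]

# relative mass-stopping factors for WET (length equivalence per unit density)
DEFAULT_STOPPING_FACTORS = {"water": 1.0, "pmma": 1.16 / 1.19}


class GeometryError(ValueError):
    pass


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-12:
        raise GeometryError(f"direction must be unit length, |d| = {n}")
    return v


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def intersect(self, origin: np.ndarray, direction: np.ndarray):
        """Entry/exit parameters (t0, t1) of the infinite line, or None."""
        oc = origin - np.asarray(self.center)
        b = float(np.dot(oc, direction))
        c = float(np.dot(oc, oc)) - self.radius**2
        disc = b * b - c
        if disc <= _TANGENT_EPS:
            return None
        s = math.sqrt(disc)
        return (-b - s, -b + s)

    def contains(self, point: np.ndarray) -> bool:
        return float(np.sum((point - np.asarray(self.center)) ** 2)) <= self.radius**2


@dataclass(frozen=True)
class Box:
    """Axis-aligned box given by center and full side lengths."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def intersect(self, origin: np.ndarray, direction: np.ndarray):
        c = np.asarray(self.center)
        half = np.asarray(self.size) / 2.0
        lo, hi = c - half, c + half
        t0, t1 = -math.inf, math.inf
        for k in range(3):
            if abs(direction[k]) < 1e-300:
                if not (lo[k] <= origin[k] <= hi[k]):
                    return None
                continue
            ta = (lo[k] - origin[k]) / direction[k]
            tb = (hi[k] - origin[k]) / direction[k]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
        if t1 - t0 <= _TANGENT_EPS:
            return None
        return (t0, t1)

    def contains(self, point: np.ndarray) -> bool:
        c = np.asarray(self.center)
        half = np.asarray(self.size) / 2.0
        return bool(np.all(np.abs(point - c) <= half))


@dataclass(frozen=True)
class Cylinder:
    """Finite circular cylinder: center, unit axis, radius, full length."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    length: float

    def intersect(self, origin: np.ndarray, direction: np.ndarray):
        a = _unit(self.axis)
        c = np.asarray(self.center)
        oc = origin - c
        # split into components along / perpendicular to the axis
        d_par = float(np.dot(direction, a))
        o_par = float(np.dot(oc, a))
        d_perp = direction - d_par * a
        o_perp = oc - o_par * a
        # infinite-cylinder quadratic
        qa = float(np.dot(d_perp, d_perp))
        qb = float(np.dot(o_perp, d_perp))
        qc = float(np.dot(o_perp, o_perp)) - self.radius**2
        half = self.length / 2.0
        if qa < 1e-300:
            if qc > 0:
                return None
            t_side = (-math.inf, math.inf)
        else:
            disc = qb * qb - qa * qc
            if disc <= _TANGENT_EPS:
                return None
            s = math.sqrt(disc)
            t_side = ((-qb - s) / qa, (-qb + s) / qa)
        if abs(d_par) < 1e-300:
            if abs(o_par) > half:
                return None
            t_cap = (-math.inf, math.inf)
        else:
            ta = (-half - o_par) / d_par
            tb = (half - o_par) / d_par
            t_cap = (min(ta, tb), max(ta, tb))
        t0 = max(t_side[0], t_cap[0])
        t1 = min(t_side[1], t_cap[1])
        if t1 - t0 <= _TANGENT_EPS:
            return None
        return (t0, t1)

    def contains(self, point: np.ndarray) -> bool:
        a = _unit(self.axis)
        oc = point - np.asarray(self.center)
        par = float(np.dot(oc, a))
        perp2 = float(np.dot(oc, oc)) - par * par
        return abs(par) <= self.length / 2.0 and perp2 <= self.radius**2


@dataclass(frozen=True)
class Region:
    solid: object
    material: Material
    density_override: float | None = None

    @property
    def density(self) -> float:
        return self.density_override if self.density_override is not None else self.material.density


@dataclass(frozen=True)
class Phantom:
    """Ordered regions, outermost first; later regions win inside earlier ones."""

    regions: tuple[Region, ...]
    stopping_factors: dict = field(default_factory=lambda: dict(DEFAULT_STOPPING_FACTORS))

    def __post_init__(self) -> None:
        if not self.regions:
            raise GeometryError("phantom needs at least one region")
        for r in self.regions:
            if r.density <= 0:
                raise GeometryError("region densities must be positive")

    @property
    def outer(self):
        return self.regions[0].solid

    def contains(self, point) -> bool:
        return self.outer.contains(np.asarray(point, dtype=float))

    def region_at(self, point: np.ndarray) -> int | None:
        """Index of the owning region at a point (last containing wins)."""
        owner = None
        for i, reg in enumerate(self.regions):
            if reg.solid.contains(point):
                owner = i
        return owner

    def stopping_factor(self, region: Region) -> float:
        return self.stopping_factors.get(region.material.name, 1.0)


@dataclass(frozen=True)
class Ray:
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        _unit(self.direction)


def _segments(ray: Ray, phantom: Phantom):
    """Forward segments (t_lo, t_hi, region index) from the ray origin to the
    outer-boundary exit, with nesting resolved by list precedence."""
    origin = np.asarray(ray.origin, dtype=float)
    direction = _unit(ray.direction)
    cuts = {0.0}
    outer_exit = None
    for i, reg in enumerate(phantom.regions):
        hit = reg.solid.intersect(origin, direction)
        if hit is None:
            continue
        t0, t1 = hit
        if i == 0:
            if t1 <= 0:
                return [], origin, direction
            outer_exit = t1
        for t in (t0, t1):
            if t > 0:
                cuts.add(t)
    if outer_exit is None:
        return [], origin, direction
    ts = sorted(t for t in cuts if t <= outer_exit + 1e-12)
    if ts[-1] < outer_exit - 1e-12:
        ts.append(outer_exit)
    segments = []
    for lo, hi in zip(ts[:-1], ts[1:]):
        if hi - lo <= 1e-12:
            continue
        mid = origin + 0.5 * (lo + hi) * direction
        owner = phantom.region_at(mid)
        if owner is not None:
            segments.append((lo, hi, owner))
    return segments, origin, direction


def chord_lengths(ray: Ray, phantom: Phantom) -> list[tuple[int, float]]:
    """Per-region path lengths (cm) from the ray origin to the phantom exit.

    Returns ``[(region_index, length), ...]`` in traversal order with
    contiguous same-region segments merged; empty if the ray misses the
    phantom entirely.
    """
    segments, _, _ = _segments(ray, phantom)
    out: list[tuple[int, float]] = []
    for lo, hi, owner in segments:
        if out and out[-1][0] == owner:
            out[-1] = (owner, out[-1][1] + hi - lo)
        else:
            out.append((owner, hi - lo))
    return out


def water_equivalent_thickness(ray: Ray, phantom: Phantom) -> float:
    """WET (cm) of the forward path: sum of length x (rho/rho_water) x
    relative stopping factor over the traversed regions."""
    wet = 0.0
    for idx, length in chord_lengths(ray, phantom):
        reg = phantom.regions[idx]
        wet += length * (reg.density / WATER.density) * phantom.stopping_factor(reg)
    return wet


def exit_path_thickness(vertex, direction, phantom: Phantom) -> float:
    """WET (cm) from an emission vertex inside the phantom to its boundary
    along ``direction`` -- the crossed-material x of the absorption model."""
    vertex = np.asarray(vertex, dtype=float)
    if not phantom.contains(vertex):
        raise GeometryError(f"vertex {vertex.tolist()} lies outside the phantom")
    return water_equivalent_thickness(Ray(tuple(vertex), tuple(direction)), phantom)
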