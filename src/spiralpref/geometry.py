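"""Parametric spiral families used as stimuli.

Two families of polar curves are supported:

* (generalized) Archimedean spirals  rho(phi) = a * phi**(1/c), where ``c``
  controls how strongly the spacing between turns inflates (c = 1 gives the
  plain Archimedean spiral with constant spacing), and
* logarithmic spirals  r(phi) = a * exp(b * phi), whose spacing grows
  exponentially; the special case b ~ 0.306349 is the golden spiral, which
  widens by the golden ratio every quarter turn.

Curves are sampled on a fixed angular grid (0.01 rad by default) and measured:
per-vertex curvature, arc length (numeric and closed-form/quadrature), and
summary curvature statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np
from scipy.integrate import quad

GOLDEN_B = 0.306349
#: radians between consecutive sample angles
DEFAULT_STEP = 0.01


class Family(str, Enum):
    ARCHIMEDEAN = "archimedean"
    GENERALIZED_ARCHIMEDEAN = "generalized_archimedean"
    LOGARITHMIC = "logarithmic"
    GOLDEN = "golden"


_ARCHIMEDEAN_FAMILIES = (Family.ARCHIMEDEAN, Family.GENERALIZED_ARCHIMEDEAN)
_LOG_FAMILIES = (Family.LOGARITHMIC, Family.GOLDEN)


@dataclass(frozen=True)
class SpiralSpec:
    """One stimulus definition: family, shape parameters and angular range."""

    stimulus_id: str
    family: Family
    version: int
    a: float
    c: float = 1.0
    b: float = 0.0
    phi_start: float = 0.0
    phi_end: float = 6 * math.pi
    step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"{self.stimulus_id}: scale parameter a must be > 0")
        if self.step <= 0:
            raise ValueError(f"{self.stimulus_id}: step must be > 0")
        if self.phi_end <= self.phi_start:
            raise ValueError(f"{self.stimulus_id}: phi_end must exceed phi_start")
        if self.family is Family.GOLDEN and abs(self.b - GOLDEN_B) >= 1e-6:
            raise ValueError(
                f"{self.stimulus_id}: golden spiral requires b = {GOLDEN_B}"
            )

    @property
    def is_logarithmic(self) -> bool:
        return self.family in _LOG_FAMILIES


@dataclass(frozen=True)
class Polyline:
    """Sampled planar curve with per-vertex sampling angle and curvature."""

    vertices: np.ndarray  # (n, 2)
    phis: np.ndarray  # (n,)
    curvatures: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = len(self.phis)
        if n < 2 or self.vertices.shape != (n, 2) or len(self.curvatures) != n:
            raise ValueError("polyline arrays must align and hold >= 2 vertices")
        if np.any(np.diff(self.phis) <= 0):
            raise ValueError("sampling angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.phis)


def catalog() -> list[SpiralSpec]:
    """The 15 stimulus specifications (5 families x 3 versions).

    Versions 1 and 2 run three turns (phi up to 6*pi) at normal and large
    size; version 3 runs four turns (8*pi) at the version-1 scale.  Version 2
    of every family is sized to match the footprint of its version 3.
    """
    six, eight = 6 * math.pi, 8 * math.pi
    rows: list[tuple[str, Family, int, float, float, float, float]] = [
        ("AR-v1", Family.ARCHIMEDEAN, 1, 0.13151, 1.0, 0.0, six),
        ("AR-v2", Family.ARCHIMEDEAN, 2, 0.17941, 1.0, 0.0, six),
        ("AR-v3", Family.ARCHIMEDEAN, 3, 0.13151, 1.0, 0.0, eight),
        ("GA-v1", Family.GENERALIZED_ARCHIMEDEAN, 1, 0.0133, 0.58, 0.0, six),
        ("GA-v2", Family.GENERALIZED_ARCHIMEDEAN, 2, 0.0226, 0.58, 0.0, six),
        ("GA-v3", Family.GENERALIZED_ARCHIMEDEAN, 3, 0.0133, 0.58, 0.0, eight),
        ("L1-v1", Family.LOGARITHMIC, 1, 0.1114, 1.0, 0.14, six),
        ("L1-v2", Family.LOGARITHMIC, 2, 0.2685, 1.0, 0.14, six),
        ("L1-v3", Family.LOGARITHMIC, 3, 0.1114, 1.0, 0.14, eight),
        ("L2-v1", Family.LOGARITHMIC, 1, 0.014, 1.0, 0.2262, six),
        ("L2-v2", Family.LOGARITHMIC, 2, 0.058, 1.0, 0.2262, six),
        ("L2-v3", Family.LOGARITHMIC, 3, 0.014, 1.0, 0.2262, eight),
        ("GO-v1", Family.GOLDEN, 1, 0.002007, 1.0, GOLDEN_B, six),
        ("GO-v2", Family.GOLDEN, 2, 0.01378, 1.0, GOLDEN_B, six),
        ("GO-v3", Family.GOLDEN, 3, 0.002007, 1.0, GOLDEN_B, eight),
    ]
    return [
        SpiralSpec(sid, fam, ver, a=a, c=c, b=b, phi_end=end)
        for sid, fam, ver, a, c, b, end in rows
    ]


def catalog_by_id() -> dict[str, SpiralSpec]:
    return {spec.stimulus_id: spec for spec in catalog()}


def radius_at(spec: SpiralSpec, phi):
    """Polar radius of the spiral at angle ``phi`` (radians, >= 0)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("phi must be non-negative")
    if spec.is_logarithmic:
        out = spec.a * np.exp(spec.b * phi)
    else:
        out = spec.a * np.power(phi, 1.0 / spec.c)
    return out if out.ndim else float(out)


def _rho_derivatives(spec: SpiralSpec, phi: np.ndarray):
    """(rho, rho', rho'') for the polar-curve curvature formula."""
    if spec.is_logarithmic:
        rho = spec.a * np.exp(spec.b * phi)
        return rho, spec.b * rho, spec.b**2 * rho
    p = 1.0 / spec.c
    rho = spec.a * np.power(phi, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = spec.a * p * np.power(phi, p - 1.0)
        d2 = spec.a * p * (p - 1.0) * np.power(phi, p - 2.0)
    if spec.family is Family.ARCHIMEDEAN:  # p == 1: derivatives are exact
        d1 = np.full_like(rho, spec.a)
        d2 = np.zeros_like(rho)
    return rho, d1, d2


def curvature_at(spec: SpiralSpec, phi):
    """Unsigned curvature kappa = |rho^2 + 2 rho'^2 - rho rho''| / (rho^2 + rho'^2)^(3/2).

    For generalized Archimedean spirals with c != 1 the derivatives are
    singular at phi = 0, which is rejected as a domain error.
    """
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    if np.any(phi_arr < 0):
        raise ValueError("phi must be non-negative")
    singular = (
        spec.family is Family.GENERALIZED_ARCHIMEDEAN and spec.c != 1.0
    )
    if singular and np.any(phi_arr == 0):
        raise ValueError("curvature of a generalized Archimedean spiral is singular at phi=0")
    rho, d1, d2 = _rho_derivatives(spec, phi_arr)
    denom = np.power(rho**2 + d1**2, 1.5)
    if np.any(denom == 0):
        raise ValueError("curvature undefined where rho = rho' = 0")
    kappa = np.abs(rho**2 + 2 * d1**2 - rho * d2) / denom
    return kappa if np.ndim(phi) else float(kappa[0])


def _grid(spec: SpiralSpec) -> np.ndarray:
    n = int(math.floor((spec.phi_end - spec.phi_start) / spec.step + 1e-9))
    phis = spec.phi_start + spec.step * np.arange(n + 1)
    if phis[-1] < spec.phi_end - 1e-12:
        phis = np.append(phis, spec.phi_end)
    return phis


def sample_polyline(spec: SpiralSpec) -> Polyline:
    """Sample the spiral on its angular grid and attach per-vertex curvature.

    The grid is phi_start + k*step; phi_end is appended as a final vertex when
    it falls off-grid.  Where the curvature is singular at the first vertex
    (generalized Archimedean, c != 1), the value from the next grid point is
    carried back so every vertex carries a finite curvature.
    """
    phis = _grid(spec)
    rho = radius_at(spec, phis)
    vertices = np.column_stack((rho * np.cos(phis), rho * np.sin(phis)))
    singular_origin = (
        spec.family is Family.GENERALIZED_ARCHIMEDEAN
        and spec.c != 1.0
        and phis[0] == 0.0
    )
    if singular_origin:
        curv = np.empty_like(phis)
        curv[1:] = curvature_at(spec, phis[1:])
        curv[0] = curv[1]
    else:
        curv = curvature_at(spec, phis)
    return Polyline(vertices=vertices, phis=phis, curvatures=curv)


def arc_length_numeric(p: Polyline) -> float:
    """Sum of Euclidean segment lengths along the polyline."""
    return float(np.linalg.norm(np.diff(p.vertices, axis=0), axis=1).sum())


def arc_length_closed(spec: SpiralSpec) -> float:
    """Arc length over [phi_start, phi_end].

    Plain Archimedean and logarithmic spirals use their closed forms;
    generalized Archimedean spirals fall back on adaptive quadrature of
    sqrt(rho^2 + rho'^2).
    """
    p0, p1 = spec.phi_start, spec.phi_end
    if spec.is_logarithmic:
        return math.sqrt(1 + spec.b**2) / spec.b * (
            radius_at(spec, p1) - radius_at(spec, p0)
        )
    if spec.family is Family.ARCHIMEDEAN or spec.c == 1.0:

        def antideriv(phi: float) -> float:
            return 0.5 * spec.a * (phi * math.hypot(1.0, phi) + math.asinh(phi))

        return antideriv(p1) - antideriv(p0)

    def integrand(phi: float) -> float:
        rho, d1, _ = _rho_derivatives(spec, np.asarray(phi))
        return math.hypot(float(rho), float(d1))

    value, _ = quad(integrand, p0, p1, limit=400, epsabs=1e-10, epsrel=1e-10)
    return value


def curvature_stats(
    spec: SpiralSpec, weight_by_arc_length: bool = False
) -> tuple[float, float]:
    """Mean and population variance of per-vertex curvature.

    Defaults to the unweighted per-sample convention (one curvature value per
    angular step); arc-length weighting is available as an option.
    """
    p = sample_polyline(spec)
    k = p.curvatures
    if not weight_by_arc_length:
        mean = float(k.mean())
        return mean, float(((k - mean) ** 2).mean())
    seg = np.linalg.norm(np.diff(p.vertices, axis=0), axis=1)
    w = np.zeros_like(k)
    w[:-1] += seg / 2
    w[1:] += seg / 2
    w /= w.sum()
    mean = float(np.sum(w * k))
    return mean, float(np.sum(w * (k - mean) ** 2))
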