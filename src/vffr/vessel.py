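"""Analytic stenosis surrogate for the paired steady pressure-drop evaluations.

A reduced-order tool needs two steady (flow, pressure-drop) evaluations of the
arterial segment to characterize the lesion. At desk scale those evaluations
come from a canonical stenosis loss model instead of a 3D solver:

* a distributed Poiseuille (viscous) term, ``z1* = (8 mu / pi) * int ds / r(s)^4``,
  integrated by the trapezoidal rule over the sampled radius profile;
* a Young-Tsai-type sudden-expansion loss,
  ``z2* = (rho K_t / 2) * (1/A_min - 1/A_prox)^2``,

so the steady drop has exactly the linear-plus-quadratic flow dependence the
characterization assumes, ``dP = z1* Q + z2* Q^2``, with an optional cubic
perturbation to emulate a solver that deviates from the quadratic law.

Interfaces use clinical units (mmHg, ml/s, mm); SI is used only internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .lesion import LesionCharacteristic

__all__ = [
    "VesselGeometry",
    "BloodProperties",
    "SurrogateOptions",
    "make_stenosed_vessel",
    "surrogate_pressure_drop",
    "surrogate_coefficients",
    "read_geometry",
    "write_geometry",
]

MMHG_PER_PA = 1.0 / 133.322
ML_PER_M3 = 1e6


@dataclass(frozen=True)
class VesselGeometry:
    """Axisymmetric centerline radius profile: arc length and radius in mm."""

    arc_length: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.arc_length, dtype=float)
        r = np.asarray(self.radius, dtype=float)
        object.__setattr__(self, "arc_length", s)
        object.__setattr__(self, "radius", r)
        if s.ndim != 1 or s.size < 2 or r.shape != s.shape:
            raise ParameterError("geometry needs >= 2 (arc_length, radius) samples")
        if s[0] != 0 or np.any(np.diff(s) <= 0):
            raise ParameterError("arc_length must increase strictly from 0")
        if np.any(r <= 0):
            raise ParameterError("all radii must be positive")


@dataclass(frozen=True)
class BloodProperties:
    viscosity: float = 0.0035  # Pa s
    density: float = 1056.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ParameterError("viscosity and density must be positive")


@dataclass(frozen=True)
class SurrogateOptions:
    """Loss-model options.

    ``turbulent_loss_coefficient`` is the expansion-loss constant K_t;
    ``cubic_perturbation`` (mmHg s^3/ml^3) adds an eps*Q^3 term so that flow-pair
    selection experiments are non-degenerate.
    """

    turbulent_loss_coefficient: float = 1.52
    cubic_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if self.turbulent_loss_coefficient < 0:
            raise ParameterError("turbulent_loss_coefficient must be >= 0")


def make_stenosed_vessel(
    r_prox: float,
    r_min: float,
    l_prox: float,
    l_sten: float,
    l_dist: float,
    profile: str = "cosine",
    samples_per_mm: float = 10.0,
) -> VesselGeometry:
    """Build a stenosed radius profile narrowing from ``r_prox`` to ``r_min``.

    ``step`` gives a piecewise-constant throat; ``cosine`` a smooth taper with
    minimum radius at the stenosis midpoint.
    """
    if not 0 < r_min <= r_prox:
        raise ParameterError("require 0 < r_min <= r_prox")
    if min(l_prox, l_sten, l_dist) <= 0:
        raise ParameterError("segment lengths must be positive")
    total = l_prox + l_sten + l_dist
    n = max(int(round(total * samples_per_mm)), 30)
    s = np.linspace(0.0, total, n + 1)
    if profile == "step":
        r = np.where((s >= l_prox) & (s <= l_prox + l_sten), r_min, r_prox)
    elif profile == "cosine":
        xi = (s - l_prox) / l_sten  # 0..1 across the stenotic segment
        taper = 0.5 * (1 - np.cos(2 * np.pi * np.clip(xi, 0.0, 1.0)))
        r = r_prox - (r_prox - r_min) * taper
    else:
        raise ParameterError(f"unknown profile: {profile!r}")
    return VesselGeometry(s, r)


def surrogate_coefficients(
    geom: VesselGeometry,
    blood: BloodProperties = BloodProperties(),
    opts: SurrogateOptions = SurrogateOptions(),
) -> LesionCharacteristic:
    """Analytic (z1*, z2*) of the surrogate in clinical units."""
    s_m = geom.arc_length * 1e-3
    r_m = geom.radius * 1e-3
    z1_si = (8.0 * blood.viscosity / np.pi) * np.trapezoid(r_m ** -4, s_m)
    a = np.pi * r_m ** 2
    a_min = a.min()
    a_prox = a[0]
    z2_si = 0.5 * blood.density * opts.turbulent_loss_coefficient * (
        1.0 / a_min - 1.0 / a_prox
    ) ** 2
    z1 = z1_si * MMHG_PER_PA / ML_PER_M3
    z2 = z2_si * MMHG_PER_PA / ML_PER_M3 ** 2
    return LesionCharacteristic(z1, z2)


def surrogate_pressure_drop(
    geom: VesselGeometry,
    blood: BloodProperties = BloodProperties(),
    opts: SurrogateOptions = SurrogateOptions(),
    Q: float = 1.0,
) -> float:
    """Steady pressure drop (mmHg) at forward flow ``Q`` (ml/s)."""
    if Q < 0:
        raise ParameterError("steady characterization is forward-flow only (Q >= 0)")
    c = surrogate_coefficients(geom, blood, opts)
    return c.z1 * Q + c.z2 * Q ** 2 + opts.cubic_perturbation * Q ** 3


def read_geometry(path) -> VesselGeometry:
    """Read a two-column ``s_mm,r_mm`` CSV."""
    df = pd.read_csv(path)
    try:
        return VesselGeometry(
            df["s_mm"].to_numpy(dtype=float), df["r_mm"].to_numpy(dtype=float)
        )
    except KeyError as exc:
        raise ParameterError(f"missing required CSV column: {exc}") from exc


def write_geometry(path, geom: VesselGeometry) -> None:
    pd.DataFrame({"s_mm": geom.arc_length, "r_mm": geom.radius}).to_csv(
        path, index=False
    )
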