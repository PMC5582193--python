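"""Quadratic lesion characterization: the pressure-drop/flow law and its inverse.

A diseased arterial segment is summarized by two coefficients fitted from
paired steady evaluations at prescribed flows:

    dP(Q) = z1 * Q + z2 * Q * |Q|        (mmHg; Q in ml/s)

z1 captures viscous (Poiseuille-like) losses, z2 the convective/expansion
losses. The law is odd in Q so that retrograde instants in a transient solve
dissipate with the correct sign; the steady characterization itself only uses
forward flow.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, SingularSystemError

__all__ = [
    "LesionCharacteristic",
    "FlowDropPair",
    "fit_z_coefficients",
    "lesion_dp",
    "solve_flow_given_dp",
    "read_lesion_json",
    "write_lesion_json",
    "DEFAULT_CHARACTERIZATION_FLOWS",
    "CANDIDATE_CHARACTERIZATION_FLOWS",
]

#: operational flow pair (ml/s) used to fit (z1, z2).
DEFAULT_CHARACTERIZATION_FLOWS = (1.0, 3.0)
#: full sub- to supra-physiological sweep set (ml/s).
CANDIDATE_CHARACTERIZATION_FLOWS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class LesionCharacteristic:
    """Linear (mmHg s/ml) and quadratic (mmHg s^2/ml^2) loss coefficients."""

    z1: float
    z2: float
    clamped: bool = field(default=False, compare=False)
    fit_flows: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.z1 < 0 or self.z2 < 0:
            raise ParameterError("z1 and z2 must be >= 0 (clamp before constructing)")


@dataclass(frozen=True)
class FlowDropPair:
    """One steady evaluation: forward flow Q (ml/s) and pressure drop dP (mmHg)."""

    Q: float
    dP: float

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ParameterError("characterization flows must be positive")
        if self.dP < 0:
            raise ParameterError("steady pressure drops must be >= 0")


def fit_z_coefficients(pairs: Sequence[FlowDropPair]) -> LesionCharacteristic:
    """Fit (z1, z2) from steady (flow, drop) pairs.

    With exactly two pairs the 2x2 linear system is solved exactly; with more,
    an ordinary least-squares fit on the same [Q, Q^2] design is used. Negative
    fitted coefficients (possible with noisy external inputs) are clamped to 0
    and flagged via ``clamped`` with a warning.
    """
    if len(pairs) < 2:
        raise ParameterError("need at least 2 (flow, drop) pairs")
    q = np.array([p.Q for p in pairs], dtype=float)
    dp = np.array([p.dP for p in pairs], dtype=float)
    if np.unique(q).size < len(pairs):
        raise SingularSystemError("duplicate characterization flows")
    design = np.column_stack([q, q ** 2])
    if len(pairs) == 2:
        z1, z2 = np.linalg.solve(design, dp)
    else:
        (z1, z2), *_ = np.linalg.lstsq(design, dp, rcond=None)
    clamped = bool(z1 < -1e-12 or z2 < -1e-12)  # ignore pure rounding negatives
    if clamped:
        warnings.warn(
            "negative fitted lesion coefficient clamped to 0", stacklevel=2
        )
    return LesionCharacteristic(
        max(float(z1), 0.0), max(float(z2), 0.0), clamped, tuple(q)
    )


def lesion_dp(lesion: LesionCharacteristic, Q: float) -> float:
    """Instantaneous translesional pressure drop at (possibly retrograde) flow."""
    return lesion.z1 * Q + lesion.z2 * Q * abs(Q)


def solve_flow_given_dp(
    lesion: LesionCharacteristic, dP: float, extra_series_resistance: float = 0.0
) -> float:
    """Unique forward flow with ``(z1 + extra) Q + z2 Q^2 = dP``.

    Uses the cancellation-stable root ``Q = 2 dP / (b + sqrt(b^2 + 4 z2 dP))``
    with ``b = z1 + extra``, exact in the linear (z2 = 0) limit.
    """
    if dP < 0:
        raise ParameterError("dP must be >= 0")
    b = lesion.z1 + extra_series_resistance
    if dP == 0:
        return 0.0
    denom = b + math.sqrt(b * b + 4.0 * lesion.z2 * dP)
    if denom == 0.0:
        raise ParameterError("no solution: zero total resistance with dP > 0")
    return 2.0 * dP / denom


def write_lesion_json(path, lesion: LesionCharacteristic) -> None:
    payload = {
        "z1_mmhg_s_per_ml": lesion.z1,
        "z2_mmhg_s2_per_ml2": lesion.z2,
        "fit_flows_ml_s": list(lesion.fit_flows),
        "clamped": lesion.clamped,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_lesion_json(path) -> LesionCharacteristic:
    with open(path) as fh:
        payload = json.load(fh)
    return LesionCharacteristic(
        payload["z1_mmhg_s_per_ml"],
        payload["z2_mmhg_s2_per_ml2"],
        bool(payload.get("clamped", False)),
        tuple(payload.get("fit_flows_ml_s", ())),
    )
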