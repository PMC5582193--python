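"""The two vFFR computations: pseudotransient 0D-coupled and closed-form steady.

Pseudotransient model
---------------------
A two-compartment differential-algebraic system couples the algebraic lesion
law to a lumped coronary-microvasculature (CMV) afterload:

* algebraic (lesion + series impedance):
  ``Pa(t) - Pc = z1 Q + z2 Q|Q| + Zc Q`` with distal pressure ``Pd = Pc + Zc Q``;
* differential (compliance referenced to the intramyocardial pressure Pim(t),
  in parallel with resistance R to venous pressure Pv):
  ``dPc/dt = dPim/dt + (Q - (Pc - Pv)/R) / C``.

Cycles are repeated until the cycle-mean distal pressure settles; vFFR is the
ratio of final-cycle mean distal to mean proximal pressure. Because the
capacitor pressure rides on the Pim source, the cycle-start reset of Pim is
applied to Pc as an equal jump (charge continuity).

Steady model
------------
All CMV physiology collapses to one resistance: the mean flow solves
``Pa_mean - Pv = (z1 + R_total) Q + z2 Q^2`` in closed form and
``vFFR = (Pv + R_total Q) / Pa_mean``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalInstabilityError, ParameterError
from .lesion import LesionCharacteristic, solve_flow_given_dp
from .waveforms import (
    IntramyocardialParams,
    PressureTrace,
    _check_pim_fits,
    _pim_raw,
    _pim_raw_derivative,
    intramyocardial_pressure_derivative,
)

__all__ = [
    "CMVParameters",
    "SimulationConfig",
    "VFFRResult",
    "steady_vffr",
    "pseudotransient_step",
    "simulate_pseudotransient",
]


@dataclass(frozen=True)
class CMVParameters:
    """Lumped coronary-microvasculature afterload.

    R: total microvascular resistance (mmHg s/ml); C: compliance (ml/mmHg);
    Z_c: optional series characteristic impedance (mmHg s/ml); P_v: venous
    outflow pressure (mmHg); pim: intramyocardial pressure pulse parameters.
    """

    R: float
    C: float
    Z_c: float = 0.0
    P_v: float = 0.0
    pim: IntramyocardialParams = field(default_factory=IntramyocardialParams)

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0:
            raise ParameterError("R and C must be positive")
        if self.Z_c < 0 or self.P_v < 0:
            raise ParameterError("Z_c and P_v must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 1e-3  # s
    max_cycles: int = 20
    convergence_tol: float = 1e-4  # mmHg, on cycle-mean distal pressure change
    integrator: str = "rk4"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.max_cycles < 2:
            raise ParameterError("max_cycles must be >= 2")
        if self.integrator not in ("rk4", "heun"):
            raise ParameterError("integrator must be 'rk4' or 'heun'")


@dataclass(frozen=True)
class VFFRResult:
    """Computed vFFR with cycle means, final-cycle traces and diagnostics."""

    vffr: float
    mean_pa: float
    mean_pd: float
    pd_trace: PressureTrace
    q_trace: np.ndarray  # ml/s on the pd_trace grid
    cycles_run: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "vffr": self.vffr,
            "mean_pa_mmhg": self.mean_pa,
            "mean_pd_mmhg": self.mean_pd,
            "cycles_run": self.cycles_run,
            "converged": self.converged,
        }


def _constant_trace(value: float, period: float = 1.0) -> PressureTrace:
    return PressureTrace(
        np.array([0.0, period]), np.array([value, value]), period
    )


def steady_vffr(
    pa_mean: float,
    lesion: LesionCharacteristic,
    R_total: float,
    P_v: float = 0.0,
) -> VFFRResult:
    """Closed-form steady vFFR from mean proximal pressure, (z1, z2) and R_total."""
    if R_total <= 0:
        raise ParameterError("R_total must be positive")
    if not pa_mean > P_v >= 0:
        raise ParameterError("require pa_mean > P_v >= 0")
    q = solve_flow_given_dp(lesion, pa_mean - P_v, extra_series_resistance=R_total)
    mean_pd = P_v + R_total * q
    return VFFRResult(
        vffr=mean_pd / pa_mean,
        mean_pa=pa_mean,
        mean_pd=mean_pd,
        pd_trace=_constant_trace(mean_pd),
        q_trace=np.array([q, q]),
        cycles_run=1,
        converged=True,
    )


def _q_from_dp(dp, b: float, z2: float):
    """Signed flow through lesion+Zc at translesional drop dp (array or scalar)."""
    ad = np.abs(dp)
    denom = b + np.sqrt(b * b + 4.0 * z2 * ad)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(ad > 0, 2.0 * ad / denom, 0.0)
    return np.sign(dp) * q


def pseudotransient_step(
    Pc: float,
    t: float,
    pa_of_t,
    lesion: LesionCharacteristic,
    cmv: CMVParameters,
    dt: float,
    period: float,
    integrator: str = "rk4",
) -> tuple[float, float, float]:
    """Advance the compartment state by one explicit step.

    ``pa_of_t`` maps time (s) to proximal pressure (mmHg). Returns
    ``(Pc_new, Pd, Q)`` where Pd and Q are evaluated at the *start* of the step.
    Kinks of the intramyocardial pulse use right-hand derivatives.
    """
    b = lesion.z1 + cmv.Z_c
    z2 = lesion.z2

    def rhs(time: float, pc: float) -> float:
        q = float(_q_from_dp(pa_of_t(time) - pc, b, z2))
        dpim = intramyocardial_pressure_derivative(cmv.pim, time, period)
        return dpim + (q - (pc - cmv.P_v) / cmv.R) / cmv.C

    q0 = float(_q_from_dp(pa_of_t(t) - Pc, b, z2))
    pd0 = Pc + cmv.Z_c * q0
    if integrator == "rk4":
        k1 = rhs(t, Pc)
        k2 = rhs(t + dt / 2, Pc + dt / 2 * k1)
        k3 = rhs(t + dt / 2, Pc + dt / 2 * k2)
        k4 = rhs(t + dt, Pc + dt * k3)
        pc_new = Pc + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    elif integrator == "heun":
        k1 = rhs(t, Pc)
        k2 = rhs(t + dt, Pc + dt * k1)
        pc_new = Pc + dt / 2 * (k1 + k2)
    else:
        raise ParameterError("integrator must be 'rk4' or 'heun'")
    if not math.isfinite(pc_new):
        raise NumericalInstabilityError(
            f"compartment pressure became non-finite at t={t:.6f} s"
        )
    return pc_new, pd0, q0


def _integrate_cycle(pc0, m, dt, pa_h, dpim_h, b, z2, R, C, Pv, integrator):
    """One cardiac cycle of the compartment ODE; returns Pc at the m+1 nodes.

    ``pa_h``/``dpim_h`` are precomputed on the half-step grid (2m+1 points).
    """
    pc_nodes = np.empty(m + 1)
    pc_nodes[0] = pc = pc0
    sqrt = math.sqrt
    inv_c = 1.0 / C
    inv_r = 1.0 / R
    half = dt / 2.0
    rk4 = integrator == "rk4"

    def f(j: int, p: float) -> float:
        dp = pa_h[j] - p
        ad = abs(dp)
        if ad > 0.0:
            q = math.copysign(2.0 * ad / (b + sqrt(b * b + 4.0 * z2 * ad)), dp)
        else:
            q = 0.0
        return dpim_h[j] + (q - (p - Pv) * inv_r) * inv_c

    for i in range(m):
        j = 2 * i
        k1 = f(j, pc)
        if rk4:
            k2 = f(j + 1, pc + half * k1)
            k3 = f(j + 1, pc + half * k2)
            k4 = f(j + 2, pc + dt * k3)
            pc += dt / 6.0 * (k1 + 2.0 * (k2 + k3) + k4)
        else:
            k2 = f(j + 2, pc + dt * k1)
            pc += half * (k1 + k2)
        pc_nodes[i + 1] = pc
    if not math.isfinite(pc):
        raise NumericalInstabilityError("compartment pressure became non-finite")
    return pc_nodes


def _trapmean(values: np.ndarray, dt: float, period: float) -> float:
    return float(np.trapezoid(values, dx=dt) / period)


def simulate_pseudotransient(
    pa: PressureTrace,
    lesion: LesionCharacteristic,
    cmv: CMVParameters,
    config: SimulationConfig = SimulationConfig(),
) -> VFFRResult:
    """Run the pseudotransient solver to periodic convergence.

    Cycles repeat until the cycle-mean distal pressure changes by at most
    ``config.convergence_tol`` (mmHg) or ``config.max_cycles`` is reached;
    non-convergence is reported via ``converged=False``, not an exception.
    """
    T = pa.period
    _check_pim_fits(cmv.pim, T)
    m = max(int(round(T / config.dt)), 2)
    dt = T / m
    t_half = np.arange(2 * m + 1) * (dt / 2.0)
    pa_half = pa.interp(t_half)
    pa_half[-1] = pa_half[0]  # exact periodic closure
    pa_nodes = pa_half[0::2]
    mean_pa = _trapmean(pa_nodes, dt, T)

    b = lesion.z1 + cmv.Z_c
    z2 = lesion.z2

    if b == 0.0 and z2 == 0.0:
        # No lesion and no series impedance: the algebraic constraint pins
        # Pd = Pa; flow follows the afterload identity
        # Q = C d(Pa - Pim)/dt + (Pa - Pv)/R.
        pim_nodes = _pim_raw(cmv.pim, t_half[0::2])
        dpa = np.gradient(pa_nodes - pim_nodes, dt)
        q_nodes = cmv.C * dpa + (pa_nodes - cmv.P_v) / cmv.R
        pd_trace = PressureTrace(t_half[0::2], pa_nodes, T)
        mean_pd = _trapmean(pa_nodes, dt, T)
        return VFFRResult(
            mean_pd / mean_pa, mean_pa, mean_pd, pd_trace, q_nodes, 1, True
        )

    dpim_h = _pim_raw_derivative(cmv.pim, t_half)
    pim_end = float(_pim_raw(cmv.pim, np.array([T]))[0])  # residual before reset

    # Linearized steady estimate speeds periodic convergence; the converged
    # answer is initialization-independent.
    pc = mean_pa * cmv.R / (cmv.R + lesion.z1)
    prev_mean = None
    mean_pd = math.nan
    converged = False
    cycles = 0
    for cycle in range(config.max_cycles):
        if cycle > 0:
            pc += 0.0 - pim_end  # Pim resets to 0 at cycle start; Pc follows
        pc_nodes = _integrate_cycle(
            pc, m, dt, pa_half, dpim_h, b, z2, cmv.R, cmv.C, cmv.P_v,
            config.integrator,
        )
        pc = float(pc_nodes[-1])
        q_nodes = _q_from_dp(pa_nodes - pc_nodes, b, z2)
        pd_nodes = pc_nodes + cmv.Z_c * q_nodes
        mean_pd = _trapmean(pd_nodes, dt, T)
        cycles = cycle + 1
        if prev_mean is not None and abs(mean_pd - prev_mean) <= config.convergence_tol:
            converged = True
            break
        prev_mean = mean_pd

    pd_trace = PressureTrace(t_half[0::2], pd_nodes, T)
    return VFFRResult(
        vffr=mean_pd / mean_pa,
        mean_pa=mean_pa,
        mean_pd=mean_pd,
        pd_trace=pd_trace,
        q_trace=q_nodes,
        cycles_run=cycles,
        converged=converged,
    )
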