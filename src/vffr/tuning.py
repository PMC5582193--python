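"""Derive CMV parameters from paired proximal/distal pressure traces.

The tuning problem mirrors the clinical workflow: the proximal (catheter) and
distal (wire) pressure traces are known, the lesion law (z1, z2) has been
characterized, and the afterload parameters are found by minimizing the
normalized RMS mismatch between the simulated and measured distal pressure.
The search is a bounded derivative-free simplex (log-scaled for R, C and Z_c)
with seeded multistarts; a single free parameter uses a bounded scalar search.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ParameterError
from .hemodynamics import CMVParameters, SimulationConfig, simulate_pseudotransient
from .lesion import LesionCharacteristic, solve_flow_given_dp
from .metrics import rms_norm
from .waveforms import PressureTrace, cycle_mean

__all__ = [
    "TuningProblem",
    "TuningResult",
    "initial_resistance_estimate",
    "tune_cmv",
    "TUNABLE_PARAMETERS",
    "DEFAULT_FREE_PARAMETERS",
]

TUNABLE_PARAMETERS = (
    "R",
    "C",
    "Z_c",
    "pim.amplitude",
    "pim.t_gen",
    "pim.t_plateau",
    "pim.tau_decay",
)
#: parameters freed by default, following the invasive-trace workflow.
DEFAULT_FREE_PARAMETERS = ("R", "C", "pim.amplitude")
_LOG_SCALED = ("R", "C", "Z_c")
_TIMING_PARAMETERS = ("pim.t_gen", "pim.t_plateau", "pim.tau_decay")
#: pulse pressure (mmHg) below which Pim timing is unidentifiable.
_MIN_PULSE_PRESSURE = 1.0


def _get_param(cmv: CMVParameters, name: str) -> float:
    if name.startswith("pim."):
        return getattr(cmv.pim, name[4:])
    return getattr(cmv, name)


def _set_params(cmv: CMVParameters, updates: dict) -> CMVParameters:
    pim_updates = {k[4:]: v for k, v in updates.items() if k.startswith("pim.")}
    cmv_updates = {k: v for k, v in updates.items() if not k.startswith("pim.")}
    if pim_updates:
        cmv_updates["pim"] = dataclasses.replace(cmv.pim, **pim_updates)
    return dataclasses.replace(cmv, **cmv_updates)


@dataclass(frozen=True)
class TuningProblem:
    pa: PressureTrace
    pd_measured: PressureTrace
    lesion: LesionCharacteristic
    free_parameters: tuple = DEFAULT_FREE_PARAMETERS
    bounds: dict = field(default_factory=dict)
    initial_guess: CMVParameters = None

    def __post_init__(self) -> None:
        if self.initial_guess is None:
            raise ParameterError("initial_guess is required")
        if abs(self.pa.period - self.pd_measured.period) > 1e-9:
            raise ParameterError("pa and pd_measured must share the cycle period")
        unknown = set(self.free_parameters) - set(TUNABLE_PARAMETERS)
        if unknown:
            raise ParameterError(f"unknown free parameters: {sorted(unknown)}")
        for name in self.free_parameters:
            lo, hi = self.resolved_bounds(name)
            x0 = _get_param(self.initial_guess, name)
            if not lo <= x0 <= hi:
                raise ParameterError(
                    f"initial guess for {name} ({x0}) outside bounds ({lo}, {hi})"
                )

    def resolved_bounds(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return tuple(self.bounds[name])
        x0 = _get_param(self.initial_guess, name)
        if name in _LOG_SCALED:
            return (max(x0 / 10.0, 1e-6), x0 * 10.0 + 1e-6)
        if name == "pim.amplitude":
            return (0.0, max(4.0 * x0, 60.0))
        return (max(x0 / 3.0, 1e-3), 3.0 * x0)  # timing parameters


@dataclass(frozen=True)
class TuningResult:
    fitted: CMVParameters
    objective: float
    n_evaluations: int
    converged: bool
    multistart_spread: float


def initial_resistance_estimate(
    pa: PressureTrace,
    pd_measured: PressureTrace,
    lesion: LesionCharacteristic,
    r_max: float = 500.0,
) -> float:
    """Mean-pressure resistance estimate used to seed the optimization.

    The mean translesional drop is inverted through the lesion law to get the
    mean flow, and R = mean(Pd)/Q. When the drop (hence flow) is unidentifiable
    the configured cap ``r_max`` is returned.
    """
    mean_pa = cycle_mean(pa)
    mean_pd = cycle_mean(pd_measured)
    drop = mean_pa - mean_pd
    if drop < -1e-9:
        raise ParameterError("mean distal pressure exceeds mean proximal pressure")
    q = solve_flow_given_dp(lesion, max(drop, 0.0))
    if q <= mean_pd / r_max:
        return r_max
    return min(mean_pd / q, r_max)


def _make_objective(problem: TuningProblem, config: SimulationConfig, free):
    measured = problem.pd_measured.final_cycle()
    base = problem.initial_guess
    counter = {"n": 0}

    def objective(theta: np.ndarray) -> float:
        counter["n"] += 1
        cmv = _set_params(base, dict(zip(free, theta)))
        try:
            sim = simulate_pseudotransient(problem.pa, problem.lesion, cmv, config)
        except (ParameterError, FloatingPointError):
            return np.inf
        pd_sim = sim.pd_trace.interp(measured.times)
        sim_on_grid = PressureTrace(measured.times, pd_sim, measured.period)
        return rms_norm(sim_on_grid, measured)

    return objective, counter


def tune_cmv(
    problem: TuningProblem,
    config: SimulationConfig = SimulationConfig(),
    n_multistarts: int = 5,
    seed: int = 0,
    maxiter: int = 400,
    tol: float = 1e-8,
) -> TuningResult:
    """Fit the free CMV parameters by minimizing the normalized RMS mismatch.

    Runs a bounded local search from ``initial_guess`` plus ``n_multistarts - 1``
    seeded random starts within bounds and returns the best result.
    """
    free = list(problem.free_parameters)
    pulse = float(np.ptp(problem.pa.values))
    if pulse < _MIN_PULSE_PRESSURE and "pim.amplitude" in free:
        frozen = [p for p in free if p in _TIMING_PARAMETERS]
        if frozen:
            warnings.warn(
                "near-zero pulse pressure: freezing Pim timing parameters "
                f"{frozen} at their initial values", stacklevel=2
            )
            free = [p for p in free if p not in _TIMING_PARAMETERS]
    if not free:
        raise ParameterError("no free parameters to tune")

    objective, counter = _make_objective(problem, config, free)
    bounds = [problem.resolved_bounds(name) for name in free]

    if len(free) == 1:
        (lo, hi) = bounds[0]
        res = optimize.minimize_scalar(
            lambda x: objective(np.array([x])),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": max(1e-6 * (hi - lo), 1e-12)},
        )
        fitted = _set_params(problem.initial_guess, {free[0]: float(res.x)})
        return TuningResult(
            fitted, float(res.fun), counter["n"], bool(res.success), 0.0
        )

    # transform to unconstrained-ish scaled coordinates: log for R/C/Zc
    logscale = [name in _LOG_SCALED and bounds[i][0] > 0 for i, name in enumerate(free)]

    def to_internal(x):
        return np.array(
            [np.log(v) if ls else v for v, ls in zip(x, logscale)]
        )

    def to_physical(u):
        return np.array(
            [np.exp(v) if ls else v for v, ls in zip(u, logscale)]
        )

    internal_bounds = [
        (np.log(lo) if ls else lo, np.log(hi) if ls else hi)
        for (lo, hi), ls in zip(bounds, logscale)
    ]

    def internal_objective(u):
        return objective(to_physical(u))

    rng = np.random.default_rng(seed)
    x0 = np.array([_get_param(problem.initial_guess, name) for name in free])
    starts = [to_internal(x0)]
    for _ in range(max(n_multistarts - 1, 0)):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in internal_bounds])
        )

    best = None
    finals = []
    any_success = False
    for u0 in starts:
        res = optimize.minimize(
            internal_objective,
            u0,
            method="Nelder-Mead",
            bounds=internal_bounds,
            options={"maxiter": maxiter, "fatol": tol, "xatol": 1e-8},
        )
        finals.append(res.fun)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    fitted = _set_params(problem.initial_guess, dict(zip(free, to_physical(best.x))))
    spread = float(np.max(finals) - np.min(finals)) if len(finals) > 1 else 0.0
    return TuningResult(
        fitted, float(best.fun), counter["n"], any_success, spread
    )
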