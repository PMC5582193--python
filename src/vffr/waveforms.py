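"""Periodic pressure signals: aortic (proximal) pressure and intramyocardial pressure.

The solvers in :mod:`vffr.hemodynamics` consume two periodic signals:

* the proximal (aortic) pressure :math:`P_a(t)`, clinically measured at the
  guiding catheter and synthesized here by a smooth four-parameter waveform
  (half-sine systolic ejection with an exponential diastolic decay back to the
  diastolic pressure);
* the intramyocardial pressure :math:`P_{im}(t)` exerted by the contracting
  myocardium on the microvascular bed, modeled as a piecewise
  rise / plateau / exponential-decay pulse restarting at each cycle.

All pressures are in mmHg, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "PressureTrace",
    "AorticWaveformParams",
    "IntramyocardialParams",
    "synthesize_aortic_pressure",
    "intramyocardial_pressure",
    "intramyocardial_pressure_derivative",
    "cycle_mean",
    "read_pressure_trace",
    "write_pressure_trace",
]

#: phase (radians) spanned by the systolic half-sine; the dicrotic junction sits
#: at sin(3*pi/4) of the pulse pressure so systole peaks inside the ejection phase.
_SYSTOLIC_PHASE = 0.75 * np.pi
_GRID_TOL = 1e-9


@dataclass(frozen=True)
class PressureTrace:
    """A uniformly sampled periodic pressure signal covering >= 1 full cycle."""

    times: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.size < 2 or values.shape != times.shape:
            raise ParameterError("trace needs >= 2 samples with matching times/values")
        steps = np.diff(times)
        if np.any(steps <= 0) or np.ptp(steps) > _GRID_TOL:
            raise ParameterError("times must be a strictly increasing uniform grid")
        if not np.all(np.isfinite(values)):
            raise ParameterError("pressure values must be finite")
        if not self.period > 0:
            raise ParameterError("period must be positive")
        n_cycles = (times[-1] - times[0]) / self.period
        if n_cycles < 1 - 1e-6 or abs(n_cycles - round(n_cycles)) > 1e-6:
            raise ParameterError(
                "trace must cover an integer number (>= 1) of periods"
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_cycles(self) -> int:
        return int(round((self.times[-1] - self.times[0]) / self.period))

    def samples_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    def final_cycle(self) -> "PressureTrace":
        """The last full period of the trace (times rebased to start at 0)."""
        m = self.samples_per_cycle()
        times = self.times[-(m + 1):]
        return PressureTrace(times - times[0], self.values[-(m + 1):], self.period)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of the final cycle at arbitrary times."""
        cyc = self.final_cycle()
        phase = np.mod(np.asarray(t, dtype=float), self.period)
        return np.interp(phase, cyc.times, cyc.values)


@dataclass(frozen=True)
class AorticWaveformParams:
    """Shape parameters of the synthetic aortic pressure waveform."""

    heart_rate: float = 70.0  # beats/min
    p_sys: float = 120.0  # mmHg
    p_dia: float = 80.0  # mmHg
    systolic_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not (self.p_sys >= self.p_dia > 0):
            raise ParameterError("require p_sys >= p_dia > 0")
        if not (20.0 <= self.heart_rate <= 220.0):
            raise ParameterError("heart rate outside 20-220 beats/min")
        if not (0.0 < self.systolic_fraction < 1.0):
            raise ParameterError("systolic_fraction must lie in (0, 1)")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class IntramyocardialParams:
    """Four-parameter description of the systolic intramyocardial pressure pulse.

    ``amplitude`` is the plateau pressure (mmHg); ``t_gen`` the linear rise
    time, ``t_plateau`` the hold time and ``tau_decay`` the exponential
    relaxation constant (all seconds).
    """

    amplitude: float = 0.0
    t_gen: float = 0.1
    t_plateau: float = 0.15
    tau_decay: float = 0.05

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if min(self.t_gen, self.t_plateau, self.tau_decay) <= 0:
            raise ParameterError("t_gen, t_plateau and tau_decay must be > 0")


def _aortic_values(params: AorticWaveformParams, phase: np.ndarray) -> np.ndarray:
    """Closed-form waveform evaluated at phases in [0, period]."""
    T = params.period
    ts = params.systolic_fraction * T
    pp = params.p_sys - params.p_dia
    tau = (T - ts) / 3.0
    kappa = np.sin(_SYSTOLIC_PHASE)  # notch pressure fraction of pulse pressure
    decay_span = 1.0 - np.exp(-(T - ts) / tau)
    systole = np.sin(_SYSTOLIC_PHASE * phase / ts)
    diastole = kappa * (np.exp(-(phase - ts) / tau) - np.exp(-(T - ts) / tau)) / decay_span
    return params.p_dia + pp * np.where(phase <= ts, systole, diastole)


def synthesize_aortic_pressure(
    params: AorticWaveformParams, dt: float, n_cycles: int = 1
) -> PressureTrace:
    """Synthesize a periodic aortic pressure trace.

    The waveform rises from ``p_dia`` along a half-sine reaching ``p_sys``
    within systole, meets the diastolic branch continuously at the dicrotic
    junction, and decays exponentially back to exactly ``p_dia`` at end
    diastole, so consecutive cycles are bit-identical and continuous.

    ``dt`` is snapped to an integer divisor of the period (requires
    ``dt < period / 50``).
    """
    T = params.period
    if not 0 < dt < T / 50:
        raise ParameterError("dt must satisfy 0 < dt < period/50")
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    m = int(round(T / dt))
    dt_eff = T / m
    phase = np.arange(m) * dt_eff
    one_cycle = _aortic_values(params, phase)
    values = np.concatenate([np.tile(one_cycle, n_cycles), one_cycle[:1]])
    times = np.arange(n_cycles * m + 1) * dt_eff
    return PressureTrace(times, values, T)


def _pim_raw(params: IntramyocardialParams, phase: np.ndarray) -> np.ndarray:
    """Pulse evaluated at unwrapped phases in [0, period] (no cycle reset)."""
    a, tg, tp, tau = params.amplitude, params.t_gen, params.t_plateau, params.tau_decay
    phase = np.asarray(phase, dtype=float)
    rise = a * phase / tg
    decay = a * np.exp(-(phase - tg - tp) / tau)
    return np.where(phase < tg, rise, np.where(phase < tg + tp, a, decay))


def _pim_raw_derivative(params: IntramyocardialParams, phase: np.ndarray) -> np.ndarray:
    """Right-hand derivative of the pulse at unwrapped phases."""
    a, tg, tp, tau = params.amplitude, params.t_gen, params.t_plateau, params.tau_decay
    phase = np.asarray(phase, dtype=float)
    decay = -(a / tau) * np.exp(-(phase - tg - tp) / tau)
    return np.where(phase < tg, a / tg, np.where(phase < tg + tp, 0.0, decay))


def _check_pim_fits(params: IntramyocardialParams, period: float) -> None:
    if params.t_gen + params.t_plateau >= period:
        raise ParameterError("t_gen + t_plateau must be shorter than the cycle period")


def intramyocardial_pressure(
    params: IntramyocardialParams, t, period: float
):
    """Intramyocardial pressure at time(s) ``t`` (wrapped modulo ``period``)."""
    _check_pim_fits(params, period)
    phase = np.mod(np.asarray(t, dtype=float), period)
    out = _pim_raw(params, phase)
    return float(out) if np.isscalar(t) else out


def intramyocardial_pressure_derivative(
    params: IntramyocardialParams, t, period: float
):
    """Right-hand time derivative of the intramyocardial pulse (mmHg/s)."""
    _check_pim_fits(params, period)
    phase = np.mod(np.asarray(t, dtype=float), period)
    out = _pim_raw_derivative(params, phase)
    return float(out) if np.isscalar(t) else out


def cycle_mean(trace: PressureTrace) -> float:
    """Time average (trapezoidal) of the final full period of the trace."""
    cyc = trace.final_cycle()
    return float(np.trapezoid(cyc.values, cyc.times) / trace.period)


def read_pressure_trace(path, period: float | None = None) -> PressureTrace:
    """Read a two-column ``time_s,pressure_mmhg`` CSV.

    When ``period`` is omitted the file is assumed to cover exactly one cycle.
    """
    df = pd.read_csv(path)
    try:
        times = df["time_s"].to_numpy(dtype=float)
        values = df["pressure_mmhg"].to_numpy(dtype=float)
    except KeyError as exc:
        raise ParameterError(f"missing required CSV column: {exc}") from exc
    if period is None:
        period = float(times[-1] - times[0])
    return PressureTrace(times, values, period)


def write_pressure_trace(path, trace: PressureTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "pressure_mmhg": trace.values}).to_csv(
        path, index=False
    )
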