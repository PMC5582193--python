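"""Method-agreement and diagnostic statistics.

Bland-Altman bias and limits of agreement, the normalized RMS norm used both
as goodness-of-fit and as the tuning objective, the 2x2 diagnostic table at
the ischemic threshold (FFR <= 0.80), and the two-way random-effects absolute-
agreement single-measurement intraclass correlation coefficient, ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateOutputError, ParameterError
from .waveforms import PressureTrace, cycle_mean

__all__ = [
    "BlandAltman",
    "DiagnosticMetrics",
    "bland_altman",
    "rms_norm",
    "diagnostic_metrics",
    "icc",
    "ISCHEMIC_THRESHOLD",
]

#: FFR at or below this value indicates physiologically significant disease.
ISCHEMIC_THRESHOLD = 0.80


class BlandAltman(NamedTuple):
    bias: float
    sd_delta: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class DiagnosticMetrics:
    """2x2-table rates in percent; undefined rates are NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("inputs must be equal-length 1D sequences")
    return a, b


def bland_altman(estimates: Sequence[float], references: Sequence[float]) -> BlandAltman:
    """Bias (mean delta) and 1.96-SD limits of agreement of estimate - reference."""
    est, ref = _paired(estimates, references)
    if est.size < 2:
        raise ParameterError("need at least 2 paired observations")
    delta = est - ref
    bias = float(np.mean(delta))
    sd = float(np.std(delta, ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


def rms_norm(pd_computed: PressureTrace, pd_measured: PressureTrace) -> float:
    """Normalized RMS mismatch over the final cycle.

    The computed minus measured distal-pressure vector is normalized by the
    mean measured pressure; the root-mean-square (length-invariant 2-norm) of
    the normalized vector is returned.
    """
    c = pd_computed.final_cycle()
    m = pd_measured.final_cycle()
    if c.times.shape != m.times.shape or np.max(np.abs(c.times - m.times)) > 1e-9:
        raise ParameterError("traces must share the same final-cycle grid")
    mean_measured = cycle_mean(pd_measured)
    if mean_measured <= 0:
        raise ParameterError("mean measured pressure must be positive")
    resid = (c.values - m.values) / mean_measured
    return float(np.sqrt(np.mean(resid ** 2)))


def diagnostic_metrics(
    vffr: Sequence[float],
    reference: Sequence[float],
    threshold: float = ISCHEMIC_THRESHOLD,
) -> DiagnosticMetrics:
    """Diagnostic performance of vFFR for predicting reference FFR <= threshold.

    'Positive' (significant disease) means reference <= threshold, matching the
    clinical convention that the ischemic threshold is FFR of <= 0.80.
    """
    est, ref = _paired(vffr, reference)
    pred_pos = est <= threshold
    true_pos = ref <= threshold
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))

    def rate(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    return DiagnosticMetrics(
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
        accuracy=rate(tp + tn, est.size),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def icc(estimates: Sequence[float], references: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the ANOVA mean squares of the n x 2 table whose columns are
    the two measurement methods. Raises if between-subject variance is zero
    (the statistic is undefined).
    """
    est, ref = _paired(estimates, references)
    n = est.size
    if n < 3:
        raise ParameterError("ICC needs at least 3 paired observations")
    table = np.column_stack([est, ref])
    k = 2
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    scale = max(1.0, grand * grand)
    if msr <= 1e-12 * scale or abs(denom) <= 1e-12 * scale:
        raise DegenerateOutputError("zero between-subject variance: ICC undefined")
    return float((msr - mse) / denom)
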