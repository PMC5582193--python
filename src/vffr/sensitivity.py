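"""Sobol variance decomposition of vFFR over model inputs.

The steady vFFR model is treated as a function of four uncertain inputs —
CMV resistance R, lesion coefficients z1 and z2, and mean proximal pressure
Pa — each uniform over a configurable range. First-order ("main") indices use
the Saltelli-2010 estimator and total-order indices the Jansen estimator on a
Saltelli A/B/AB design; confidence intervals come from row bootstrap. Sampling
defaults to a seeded scrambled Sobol sequence (deterministic for a given seed,
with far lower estimator variance than pseudo-random draws at practical N);
plain seeded pseudo-random sampling remains available.

Default ranges are artifact defaults (the underlying patient-cohort ranges are
not published) and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateOutputError, ParameterError

__all__ = [
    "SobolSpec",
    "SobolDesign",
    "SobolResult",
    "saltelli_sample",
    "sobol_indices",
    "run_vffr_sensitivity",
    "steady_vffr_model",
    "DEFAULT_VFFR_RANGES",
]

#: artifact-default uniform ranges for the steady-vFFR inputs.
DEFAULT_VFFR_RANGES = {
    "R_cmv": (5.0, 40.0),   # mmHg s/ml
    "z1": (0.0, 5.0),       # mmHg s/ml
    "z2": (0.0, 2.0),       # mmHg s^2/ml^2
    "pa_mean": (70.0, 110.0),  # mmHg
}


@dataclass(frozen=True)
class SobolSpec:
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_VFFR_RANGES))
    n_base: int = 1024
    seed: int = 0
    n_bootstrap: int = 200

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo <= hi:
                raise ParameterError(f"range for {name} has lower > upper")
        n = self.n_base
        if n < 64 or (n & (n - 1)) != 0:
            raise ParameterError("n_base must be a power of two >= 64")

    @property
    def names(self) -> list[str]:
        return list(self.ranges)


@dataclass(frozen=True)
class SobolDesign:
    """Saltelli design: A, B (N x k) and AB[i] = A with column i from B."""

    names: list
    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray  # shape (k, N, k)

    def all_rows(self) -> np.ndarray:
        """All N*(k+2) evaluation points stacked: A, B, AB[0], ..., AB[k-1]."""
        return np.vstack([self.A, self.B, self.AB.reshape(-1, self.A.shape[1])])


@dataclass(frozen=True)
class SobolResult:
    names: list
    s_main: np.ndarray
    s_total: np.ndarray
    s_main_ci: np.ndarray  # (k, 2) percentile bootstrap
    s_total_ci: np.ndarray

    @property
    def s_interaction(self) -> np.ndarray:
        return self.s_total - self.s_main

    @property
    def total_interaction_fraction(self) -> float:
        return float(1.0 - np.sum(self.s_main))

    @property
    def ranking(self) -> list:
        order = np.argsort(self.s_main)[::-1]
        return [self.names[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        """Heatmap-style table of main, total and interaction indices."""
        return pd.DataFrame(
            {
                "s_main": self.s_main,
                "s_total": self.s_total,
                "s_interaction": self.s_interaction,
                "s_main_lo": self.s_main_ci[:, 0],
                "s_main_hi": self.s_main_ci[:, 1],
                "s_total_lo": self.s_total_ci[:, 0],
                "s_total_hi": self.s_total_ci[:, 1],
            },
            index=self.names,
        )


def saltelli_sample(spec: SobolSpec, low_discrepancy: bool = True) -> SobolDesign:
    """Draw the A/B/AB design, uniform over the configured ranges.

    A seeded scrambled Sobol (low-discrepancy) sequence by default — still
    bit-reproducible for a fixed seed; plain pseudo-random draws optionally.
    """
    names = spec.names
    k = len(names)
    n = spec.n_base
    lo = np.array([spec.ranges[p][0] for p in names])
    hi = np.array([spec.ranges[p][1] for p in names])
    if low_discrepancy:
        from scipy.stats import qmc

        sampler = qmc.Sobol(d=2 * k, scramble=True, seed=spec.seed)
        u = sampler.random(n)
    else:
        u = np.random.default_rng(spec.seed).uniform(size=(n, 2 * k))
    A = lo + (hi - lo) * u[:, :k]
    B = lo + (hi - lo) * u[:, k:]
    AB = np.repeat(A[None, :, :], k, axis=0)
    for i in range(k):
        AB[i, :, i] = B[:, i]
    return SobolDesign(names, A, B, AB)


def _estimate(f_a, f_b, f_ab):
    pooled = np.concatenate([f_a, f_b])
    v = np.var(pooled, ddof=0)
    s_main = np.array(
        [np.mean(f_b * (f_ab[i] - f_a)) for i in range(f_ab.shape[0])]
    ) / v
    s_total = np.array(
        [np.mean((f_a - f_ab[i]) ** 2) for i in range(f_ab.shape[0])]
    ) / (2.0 * v)
    return s_main, s_total


def sobol_indices(
    names,
    f_a: np.ndarray,
    f_b: np.ndarray,
    f_ab: np.ndarray,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> SobolResult:
    """Saltelli-2010 main and Jansen total indices with bootstrap CIs.

    ``f_ab`` has shape (k, N). Negative estimates are reported as-is (they are
    a useful Monte-Carlo diagnostic), not clamped.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    f_ab = np.asarray(f_ab, dtype=float)
    if f_ab.ndim != 2 or f_ab.shape[1] != f_a.size or f_b.size != f_a.size:
        raise ParameterError("inconsistent evaluation counts")
    pooled = np.concatenate([f_a, f_b])
    if np.var(pooled) <= 1e-20 * max(1.0, float(np.mean(pooled)) ** 2):
        raise DegenerateOutputError("model output has zero variance")
    s_main, s_total = _estimate(f_a, f_b, f_ab)

    rng = np.random.default_rng(seed)
    n = f_a.size
    k = f_ab.shape[0]
    boots_main = np.empty((n_bootstrap, k))
    boots_total = np.empty((n_bootstrap, k))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boots_main[b], boots_total[b] = _estimate(
            f_a[idx], f_b[idx], f_ab[:, idx]
        )
    ci_main = np.percentile(boots_main, [2.5, 97.5], axis=0).T
    ci_total = np.percentile(boots_total, [2.5, 97.5], axis=0).T
    return SobolResult(list(names), s_main, s_total, ci_main, ci_total)


def steady_vffr_model(x: np.ndarray, p_v: float = 0.0) -> np.ndarray:
    """Vectorized steady vFFR over rows (R_cmv, z1, z2, pa_mean).

    Identical closed form as :func:`vffr.hemodynamics.steady_vffr`, evaluated
    columnwise for sensitivity sampling.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    r, z1, z2, pa = x.T
    d = pa - p_v
    b = z1 + r
    denom = b + np.sqrt(b * b + 4.0 * z2 * d)
    q = 2.0 * d / denom
    return (p_v + r * q) / pa


def run_vffr_sensitivity(
    spec: SobolSpec = SobolSpec(), low_discrepancy: bool = True
) -> SobolResult:
    """Sobol decomposition of steady vFFR over the configured input ranges."""
    if list(spec.names) != list(DEFAULT_VFFR_RANGES):
        raise ParameterError(
            f"expected input names {list(DEFAULT_VFFR_RANGES)}, got {spec.names}"
        )
    design = saltelli_sample(spec, low_discrepancy=low_discrepancy)
    f_a = steady_vffr_model(design.A)
    f_b = steady_vffr_model(design.B)
    f_ab = np.stack([steady_vffr_model(design.AB[i]) for i in range(len(spec.names))])
    return sobol_indices(
        spec.names, f_a, f_b, f_ab, n_bootstrap=spec.n_bootstrap, seed=spec.seed
    )
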