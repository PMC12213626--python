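"""Degeneration time-course statistics.

Exponential-decay fitting with half-decay time, linear correlation with
bootstrap confidence intervals for R^2, and paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ExpDecayFit",
    "CorrelationResult",
    "PairedTResult",
    "fit_exp_decay",
    "linfit_r2",
    "paired_t",
]

_K_GRID = (0.01, 2.0)  # bounded search range for the decay rate, 1/day


@dataclass
class ExpDecayFit:
    """Least-squares fit of ``T(t) = C + A * exp(-k*t)``."""

    floor_C: float
    amplitude_A: float
    rate_k: float
    rss: float
    n: int
    identifiable: bool = True

    @property
    def half_decay_days(self) -> float:
        if not self.identifiable or self.rate_k <= 0:
            return float("nan")
        return float(np.log(2.0) / self.rate_k)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.floor_C + self.amplitude_A * np.exp(-self.rate_k * t)


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    ci95_low: float
    ci95_high: float
    n: int


@dataclass
class PairedTResult:
    t_stat: float
    df: int
    p_two_sided: float
    zero_difference: bool = False
    below_machine_floor: bool = False


def _linear_ls_at_k(k: float, t: np.ndarray, y: np.ndarray):
    """Closed-form linear LS for (C, A) with the decay rate held fixed."""
    X = np.column_stack([np.ones_like(t), np.exp(-k * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), float(beta[0]), float(beta[1])


def fit_exp_decay(times, values, n_grid: int = 400) -> ExpDecayFit:
    """Fit ``T(t) = C + A*exp(-k*t)`` by grid search over k + refinement.

    For each candidate k the optimal (C, A) is the exact linear
    least-squares solution, so the search is 1-D, global on the grid and
    deterministic.  The grid optimum is refined by bounded scalar
    minimisation (golden-section / Brent).

    Parameters
    ----------
    times, values
        Sample times (days) and measurements; at least 4 points over at
        least 3 distinct times.

    Returns
    -------
    ExpDecayFit
        With ``identifiable=False`` when the series carries no decay
        signal (constant values), in which case ``rate_k`` is NaN.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D of equal length")
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct times")

    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        return ExpDecayFit(float(y.mean()), 0.0, float("nan"),
                           0.0, len(t), identifiable=False)

    ks = np.linspace(*_K_GRID, n_grid)
    rss = np.array([_linear_ls_at_k(k, t, y)[0] for k in ks])
    i = int(np.argmin(rss))
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda k: _linear_ls_at_k(k, t, y)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(res.x)
    r, C, A = _linear_ls_at_k(k, t, y)
    # A ~ 0 means the exponential term is doing no work: k is arbitrary.
    identifiable = abs(A) > 1e-9 * max(1.0, np.abs(y).max())
    if not identifiable:
        k = float("nan")
    return ExpDecayFit(C, A, k, r, len(t), identifiable=identifiable)


def linfit_r2(x, y, n_boot: int = 2000, seed: int | None = None) -> CorrelationResult:
    """Ordinary least squares with R^2 and a percentile-bootstrap 95% CI.

    The CI resamples cases (x, y pairs) with replacement, ``n_boot``
    times, seeded; resamples with constant x are redrawn.
    ``R^2 = 1 - RSS/TSS``; constant y gives R^2 = 0 by convention,
    constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")

    def _fit(xs, ys):
        slope, intercept = np.polyfit(xs, ys, 1)
        tss = float(np.sum((ys - ys.mean()) ** 2))
        if tss == 0:
            return float(slope), float(intercept), 0.0
        rss = float(np.sum((ys - (slope * xs + intercept)) ** 2))
        r2 = 1.0 - rss / tss
        return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))

    slope, intercept, r2 = _fit(x, y)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(x[idx]) > 0:
                break
        boots[b] = _fit(x[idx], y[idx])[2]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(slope, intercept, r2, float(lo), float(hi), n)


def paired_t(before, after) -> PairedTResult:
    """Two-sided paired t-test: t = mean(d)/(sd(d)/sqrt(n)), df = n-1.

    d = after - before.  All-zero differences return t=0, p=1 with the
    ``zero_difference`` flag; nonzero differences with zero variance are
    reported at the machine floor with ``below_machine_floor`` set.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before and after must be 1-D of equal length")
    n = len(b)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    df = n - 1
    sd = float(np.std(d, ddof=1))
    m = float(np.mean(d))
    if sd == 0:
        if m == 0:
            return PairedTResult(0.0, df, 1.0, zero_difference=True)
        t = np.inf if m > 0 else -np.inf
        return PairedTResult(float(t), df, float(np.nextafter(0.0, 1.0)),
                             below_machine_floor=True)
    t = m / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTResult(float(t), df, p)
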