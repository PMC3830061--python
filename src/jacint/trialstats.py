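"""Clinical-trial power analysis for cohort atrophy rates.

Converts per-subject annualized percent-volume-change rates (or a cohort
mean and SD) into the per-arm sample size required to detect a fractional
treatment effect with a two-sided two-sample t-test, with percentile
bootstrap confidence intervals and a Monte-Carlo simulation oracle.

The detectable difference for a treatment effect ``tau`` is ``tau * |mean|``
(the treatment slows atrophy by that fraction), giving the standardized
effect size ``d = tau * |mean| / sd``.  The required per-arm ``n`` solves
the noncentral-t power equation with ``df = 2n - 2`` and noncentrality
``d * sqrt(n/2)`` at 80% power and alpha 0.05 (two-sided) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRates",
    "PowerSpec",
    "SampleSizeTable",
    "annualize_and_filter",
    "effect_size",
    "power_at_n",
    "sample_size_per_arm",
    "sweep_table",
    "bootstrap_ci",
    "simulate_trial_power",
    "ratio_report",
]

CENSOR_AT = 10_000  # cells above this render as "> 10,000"


@dataclass
class CohortRates:
    """Per-subject annualized atrophy rates (%/yr) with outlier flags.

    Outliers are flagged, never silently dropped: ``rates`` keeps every
    subject and ``excluded`` marks those beyond the a-priori threshold.
    """

    rates: np.ndarray
    excluded: np.ndarray
    intervals: Optional[np.ndarray] = None
    resolution: str = ""
    pipeline: str = ""

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    def retained(self) -> np.ndarray:
        return self.rates[~self.excluded]

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def summary(self) -> tuple[float, float]:
        r = self.retained()
        return float(r.mean()), float(r.std(ddof=1))


@dataclass
class PowerSpec:
    """Power target, significance level, treatment-effect grid and bootstrap size."""

    power: float = 0.80
    alpha: float = 0.05                      # two-sided
    effects: tuple = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))
    bootstrap: int = 10_000
    seed: int = 0
    rounding: str = "nearest"                # or "ceil"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if any(not 0 < t < 1 for t in self.effects):
            raise ValueError("treatment effects must lie in (0, 1)")
        if self.bootstrap < 1:
            raise ValueError("bootstrap replicates must be >= 1")


@dataclass
class SampleSizeTable:
    """Per-effect required sample size per arm, optionally with bootstrap CIs.

    ``n`` holds the point estimates (np.inf for censored cells); CI bounds
    are np.nan when not computed and np.inf when unbounded.
    """

    effects: np.ndarray
    n: np.ndarray
    ci_low: np.ndarray = None
    ci_high: np.ndarray = None

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.ci_low is None:
            self.ci_low = np.full_like(self.n, np.nan)
        if self.ci_high is None:
            self.ci_high = np.full_like(self.n, np.nan)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)

    def lookup(self, effect: float) -> float:
        i = np.argmin(np.abs(self.effects - effect))
        if abs(self.effects[i] - effect) > 1e-9:
            raise KeyError(f"effect {effect} not in table")
        return float(self.n[i])

    @staticmethod
    def render(value: float) -> str:
        return "> 10,000" if not np.isfinite(value) or value > CENSOR_AT else f"{value:.0f}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "effect": self.effects,
            "n_per_arm": [self.render(v) for v in self.n],
            "ci_low": [self.render(v) if np.isfinite(v) else "" for v in self.ci_low],
            "ci_high": ["-" if np.isinf(v) else ("" if np.isnan(v) else f"{v:.0f}")
                        for v in self.ci_high],
        })


# ----------------------------------------------------------------------
# rates
# ----------------------------------------------------------------------

def annualize_and_filter(pvcs: Sequence[float], intervals: Sequence[float],
                         threshold: float = 10.0, **tags) -> CohortRates:
    """Annualize percent volume changes and flag a-priori outliers.

    ``rate = pvc / interval``; subjects with ``|rate|`` strictly greater
    than ``threshold`` (%/yr) are flagged excluded.  A rate of exactly the
    threshold is retained.
    """
    pvcs = np.asarray(pvcs, dtype=float)
    intervals = np.asarray(intervals, dtype=float)
    if intervals.ndim == 0:
        intervals = np.full(pvcs.shape, float(intervals))
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    rates = pvcs / intervals
    excluded = np.abs(rates) > threshold
    return CohortRates(rates, excluded, intervals, **tags)


# ----------------------------------------------------------------------
# analytic power
# ----------------------------------------------------------------------

def effect_size(mean_rate: float, sd_rate: float, tau: float) -> float:
    """Standardized detectable effect ``d = tau * |mean| / sd``."""
    if sd_rate <= 0:
        raise ValueError("sd must be positive")
    if mean_rate == 0 and tau != 0:
        raise ValueError("mean rate of zero gives no detectable effect")
    return float(tau * abs(mean_rate) / sd_rate)


def power_at_n(n, d, alpha: float = 0.05):
    """Two-sided two-sample t-test power at per-arm size ``n`` (vectorized).

    Uses the noncentral t distribution with ``df = 2n - 2`` and
    noncentrality ``d sqrt(n/2)``; falls back to the asymptotic normal form
    where scipy's noncentral t overflows (very large df).
    """
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    df = 2.0 * (n - 1.0)
    nc = d * np.sqrt(n / 2.0)
    tc = stats.t.isf(alpha / 2.0, df)
    with np.errstate(all="ignore"):
        p = stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc)
    bad = ~np.isfinite(p)
    if np.any(bad):
        approx = stats.norm.sf(tc - nc) + stats.norm.cdf(-tc - nc)
        p = np.where(bad, approx, p)
    return p if p.ndim else float(p)


def _solve_n_continuous(d, power: float, alpha: float) -> np.ndarray:
    """Vectorized bisection for the real n solving the power equation."""
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(d <= 0):
        raise ValueError("effect size must be positive (n is infinite at d = 0)")
    za = stats.norm.isf(alpha / 2.0)
    zb = stats.norm.isf(1.0 - power)
    n0 = 2.0 * ((za + zb) / d) ** 2
    lo = np.full(d.shape, 2.0 + 1e-9)
    hi = np.maximum(4.0 * n0, 8.0)
    # ensure the bracket contains the root
    for _ in range(60):
        need = power_at_n(hi, d, alpha) < power
        if not np.any(need):
            break
        hi[need] *= 2.0
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        under = power_at_n(mid, d, alpha) < power
        lo = np.where(under, mid, lo)
        hi = np.where(under, hi, mid)
    return 0.5 * (lo + hi)


def sample_size_per_arm(d: float, power: float = 0.8, alpha: float = 0.05,
                        rounding: str = "nearest") -> int:
    """Smallest per-arm n giving the target power at effect size ``d``.

    Solves the noncentral-t power equation for real n and reports the
    nearest integer (``rounding='ceil'`` for the conservative convention);
    never below 2.
    """
    n = float(_solve_n_continuous([d], power, alpha)[0])
    if rounding == "nearest":
        out = int(round(n))
    elif rounding == "ceil":
        out = int(np.ceil(n - 1e-9))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return max(out, 2)


def sweep_table(mean_rate: float, sd_rate: float,
                spec: Optional[PowerSpec] = None) -> SampleSizeTable:
    """Required n per arm across the treatment-effect grid.

    Cells above 10,000 are censored (rendered "> 10,000" on output).
    """
    spec = spec or PowerSpec()
    taus = np.asarray(spec.effects, dtype=float)
    d = np.array([effect_size(mean_rate, sd_rate, t) for t in taus])
    n = _solve_n_continuous(d, spec.power, spec.alpha)
    if spec.rounding == "ceil":
        n = np.ceil(n - 1e-9)
    else:
        n = np.round(n)
    n = np.maximum(n, 2.0)
    n = np.where(n > CENSOR_AT, np.inf, n)
    return SampleSizeTable(taus, n)


def bootstrap_ci(rates: CohortRates, spec: Optional[PowerSpec] = None) -> SampleSizeTable:
    """Percentile bootstrap 95% CI of the required n per treatment effect.

    Resamples retained subjects with replacement ``spec.bootstrap`` times,
    recomputing mean, SD and n per effect each time.  Unbounded or censored
    upper ends are reported as np.inf.
    """
    spec = spec or PowerSpec()
    r = rates.retained()
    if r.size < 2:
        raise ValueError("need at least 2 retained subjects to bootstrap")
    taus = np.asarray(spec.effects, dtype=float)
    if np.ptp(r) == 0:
        # identical rates: zero SD means any n >= 2 attains the power;
        # the CI collapses onto the degenerate point estimate
        n = np.full(taus.shape, 2.0)
        return SampleSizeTable(taus, n, n.copy(), n.copy())
    point = sweep_table(*_mean_sd(r), spec)

    rng = np.random.default_rng(spec.seed)
    B = spec.bootstrap
    samples = rng.choice(r, size=(B, r.size), replace=True)
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    ok = (sds > 0) & (means != 0)
    d = taus[None, :] * np.abs(means)[:, None] / sds[:, None]  # (B, n_tau)
    nboot = np.full(d.shape, np.inf)
    dok = d[ok, :].ravel()
    sol = _solve_n_continuous(np.maximum(dok, 1e-9), spec.power, spec.alpha)
    if spec.rounding == "ceil":
        sol = np.ceil(sol - 1e-9)
    else:
        sol = np.round(sol)
    nboot[ok, :] = sol.reshape(-1, taus.size)
    lo = np.nanpercentile(nboot, 2.5, axis=0)
    hi = np.nanpercentile(nboot, 97.5, axis=0)
    hi = np.where(hi > CENSOR_AT, np.inf, hi)
    lo = np.where(lo > CENSOR_AT, np.inf, lo)
    return SampleSizeTable(taus, point.n, lo, hi)


def _mean_sd(r: np.ndarray) -> tuple[float, float]:
    return float(r.mean()), float(r.std(ddof=1))


# ----------------------------------------------------------------------
# Monte-Carlo oracle
# ----------------------------------------------------------------------

def simulate_trial_power(mean_rate: float, sd_rate: float, tau: float, n: int,
                         reps: int = 20_000, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Empirical power of the two-arm trial by direct simulation.

    Control subjects ~ Normal(mean, sd), treated ~ Normal(mean*(1-tau), sd),
    ``n`` per arm; returns the fraction of two-sided pooled t-tests
    rejecting at ``alpha``.  Serves as an independent check of the analytic
    solver.
    """
    if n < 2:
        raise ValueError("need n >= 2 per arm")
    rng = np.random.default_rng(seed)
    df = 2 * n - 2
    tcrit = stats.t.isf(alpha / 2.0, df)
    reject = 0
    chunk = max(1, int(5e6 // max(n, 1)))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        ctrl = rng.normal(mean_rate, sd_rate, size=(b, n))
        trt = rng.normal(mean_rate * (1.0 - tau), sd_rate, size=(b, n))
        m1, m2 = ctrl.mean(axis=1), trt.mean(axis=1)
        v1, v2 = ctrl.var(axis=1, ddof=1), trt.var(axis=1, ddof=1)
        sp = np.sqrt((v1 + v2) / 2.0)
        t = (m1 - m2) / (sp * np.sqrt(2.0 / n))
        reject += int(np.sum(np.abs(t) > tcrit))
        done += b
    return reject / reps


def ratio_report(table_a: SampleSizeTable, table_b: SampleSizeTable) -> pd.DataFrame:
    """Per-effect sample-size ratios n_a / n_b over shared, uncensored effects."""
    shared = np.intersect1d(np.round(table_a.effects, 9), np.round(table_b.effects, 9))
    rows = []
    for tau in shared:
        na = table_a.lookup(tau)
        nb = table_b.lookup(tau)
        if np.isfinite(na) and np.isfinite(nb):
            rows.append((tau, na, nb, na / nb))
    return pd.DataFrame(rows, columns=["effect", "n_a", "n_b", "ratio"])
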