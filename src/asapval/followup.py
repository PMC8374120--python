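"""Time-to-event outcome analysis of at-risk patients by risk group.

After risk stratification, patients without prevalent disease are followed
for incident HCC.  Cumulative incidence per risk group is the complement of
the Kaplan–Meier survival estimate (lifelines' product-limit fitter);
groups are compared with the log-rank test.

The log-rank statistic is computed in-package because the result type
exposes the per-group observed and expected event counts (O_j and
E_j = sum_i d_i n_ij / n_i over distinct event times), with the usual
hypergeometric covariance and df = groups - 1.  A pairwise variant reports
each unadjusted two-group test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank",
    "pairwise_logrank",
    "cumulative_incidence_table",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate on the grid of observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    @property
    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def incidence_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "cumulative_incidence": self.cumulative_incidence,
                "at_risk": self.at_risk,
            }
        )


def _check_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if len(t) != len(e):
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier survival curve; censored subjects leave the risk set
    after their censoring time, ties at a time are processed together."""
    t, e = _check_times(times, events)
    if len(t) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=tbl["at_risk"].to_numpy())


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray  # per-group expected events under H0


def logrank(groups: Sequence[tuple]) -> LogRankResult:
    """Log-rank test across ``groups`` = [(times, events), ...]."""
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    data = [_check_times(t, e) for t, e in groups]
    k = len(data)
    all_events = np.concatenate([t[e == 1] for t, e in data])
    if all_events.size == 0:
        raise ValueError("log-rank undefined: no events in any group")
    event_times = np.unique(all_events)

    O = np.array([e.sum() for _, e in data], dtype=float)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ti in event_times:
        n_ij = np.array([np.sum(t >= ti) for t, _ in data], dtype=float)
        d_ij = np.array([np.sum((t == ti) & (e == 1)) for t, e in data], dtype=float)
        n_i = n_ij.sum()
        d_i = d_ij.sum()
        if n_i <= 1 or d_i == 0:
            E += d_i * n_ij / n_i if n_i > 0 else 0.0
            continue
        E += d_i * n_ij / n_i
        c = d_i * (n_i - d_i) / (n_i - 1)
        V += c * (np.diag(n_ij) * n_i - np.outer(n_ij, n_ij)) / n_i**2

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(
        chi_square=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        observed=O,
        expected=E,
    )


def pairwise_logrank(
    groups: dict[str, tuple]
) -> pd.DataFrame:
    """Unadjusted two-group log-rank tests for every pair of named groups."""
    rows = []
    for a, b in combinations(groups, 2):
        res = logrank([groups[a], groups[b]])
        rows.append(
            {"group_a": a, "group_b": b,
             "chi_square": res.chi_square, "p_value": res.p_value}
        )
    return pd.DataFrame(rows)


def cumulative_incidence_table(
    groups: dict[str, tuple], at_months: Sequence[float] = (3.0, 6.0, 18.0)
) -> pd.DataFrame:
    """Per-group KM cumulative incidence at the given horizons (months)."""
    rows = []
    for name, (t, e) in groups.items():
        curve = km_estimate(t, e)
        row = {"group": name, "n": len(np.asarray(t)),
               "events": int(np.asarray(e).sum())}
        for m in at_months:
            row[f"incidence_{m:g}m"] = curve.incidence_at(m)
        rows.append(row)
    return pd.DataFrame(rows)
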