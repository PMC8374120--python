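"""Threshold-based clinical utility: classification statistics, net
benefit / decision curves, two-threshold risk stratification and group
contrasts.

A probability threshold ``pt`` turns a risk model into a classifier
(positive iff predicted probability >= pt).  Its clinical value at that
threshold is the *net benefit*

    NB = TP/n - (FP/n) * pt / (1 - pt),

the true-positive rate penalized by the false-positive rate at the odds a
patient (implicitly) places on treatment at that threshold.  Decision curve
analysis compares the model's NB across thresholds against treating
everyone and treating no one.

Risk stratification splits a cohort at two probability thresholds into
low / medium / high groups; the canonical choices here are the median
predicted probability of the non-case patients (lower threshold) and the
cohort event rate (upper threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import bootstrap_ci

__all__ = [
    "ThresholdStats",
    "RiskStrata",
    "confusion_at_threshold",
    "classification_stats",
    "stats_from_counts",
    "net_benefit",
    "decision_curve",
    "stratify",
    "relative_risk",
    "compare_proportions",
    "named_thresholds",
    "threshold_report",
    "PRESET_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: preset threshold list: median non-case prediction, optimal (Youden)
#: cutoff, cohort event rate, the model's published low/high tierce points,
#: the sigmoid midpoint, and the median case prediction
PRESET_THRESHOLDS: tuple[float, ...] = (
    0.013, 0.131, 0.155, 1.0 / 3.0, 0.5, 2.0 / 3.0, 0.983
)


def _check_pt(pt: float) -> float:
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {pt}")
    return float(pt)


def confusion_at_threshold(probs, labels, pt: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with positive call iff prob >= pt (inclusive)."""
    _check_pt(pt)
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = p >= pt
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    tn = int(np.sum(~pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    return tp, fp, tn, fn


def net_benefit(tp: int, fp: int, n: int, pt: float) -> float:
    """NB = TP/n - (FP/n) * pt/(1-pt)."""
    _check_pt(pt)
    return tp / n - (fp / n) * pt / (1.0 - pt)


@dataclass(frozen=True)
class ThresholdStats:
    """Classification statistics at one probability threshold, with
    stratified-bootstrap confidence intervals."""

    pt: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    nb: float
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None
    nb_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def stats_from_counts(tp: int, fp: int, tn: int, fn: int, pt: float) -> ThresholdStats:
    """Pure-arithmetic classification statistics from confusion counts."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion table")
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    if ppv is None:
        warnings.warn("empty predicted-positive set: PPV undefined", stacklevel=2)
    npv = tn / (tn + fn) if tn + fn > 0 else None
    if npv is None:
        warnings.warn("empty predicted-negative set: NPV undefined", stacklevel=2)
    return ThresholdStats(
        pt=_check_pt(pt),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        ppv=ppv,
        npv=npv,
        nb=net_benefit(tp, fp, n, pt),
    )


def classification_stats(
    probs, labels, pt: float, reps: int = 2000, seed: int = 0
) -> ThresholdStats:
    """Classification statistics at ``pt`` with percentile bootstrap CIs
    from outcome-stratified resampling (``reps`` replicates)."""
    base = stats_from_counts(*confusion_at_threshold(probs, labels, pt), pt)
    df = pd.DataFrame({"p": np.asarray(probs, dtype=float),
                       "hcc": np.asarray(labels).astype(int)})

    def _stat(extract):
        def f(d: pd.DataFrame) -> float:
            s = stats_from_counts(*confusion_at_threshold(d["p"], d["hcc"], pt), pt)
            v = extract(s)
            return np.nan if v is None else v
        return f

    cis = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, extract in (
            ("sensitivity", lambda s: s.sensitivity),
            ("specificity", lambda s: s.specificity),
            ("ppv", lambda s: s.ppv),
            ("npv", lambda s: s.npv),
            ("nb", lambda s: s.nb),
        ):
            _, lo, hi = bootstrap_ci(_stat(extract), df, reps=reps, seed=seed)
            cis[name] = (lo, hi)
    return ThresholdStats(
        pt=base.pt, tp=base.tp, fp=base.fp, tn=base.tn, fn=base.fn,
        sensitivity=base.sensitivity, specificity=base.specificity,
        ppv=base.ppv, npv=base.npv, nb=base.nb,
        sensitivity_ci=cis["sensitivity"], specificity_ci=cis["specificity"],
        ppv_ci=cis["ppv"], npv_ci=cis["npv"], nb_ci=cis["nb"],
    )


def decision_curve(
    probs, labels, grid=None
) -> pd.DataFrame:
    """Net benefit of the model, treat-all and treat-none per threshold.

    Default grid 0.01..0.99 step 0.01.  Treat-none is identically 0;
    treat-all is ``prevalence - (1-prevalence)*pt/(1-pt)``.
    """
    if grid is None:
        grid = np.arange(0.01, 0.995, 0.01)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("grid thresholds must lie in (0, 1)")
    y = np.asarray(labels).astype(int)
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in grid:
        tp, fp, _, _ = confusion_at_threshold(probs, y, pt)
        rows.append(
            {
                "pt": pt,
                "nb_model": net_benefit(tp, fp, n, pt),
                "nb_all": prev - (1 - prev) * pt / (1 - pt),
                "nb_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RiskStrata:
    """Risk-group partition of a cohort at two probability thresholds."""

    t_low: float
    t_high: float
    groups: np.ndarray  # per patient: "low" | "medium" | "high"
    summary: pd.DataFrame  # per group: n, events, incidence, rr, rr CI

    def counts(self) -> dict[str, int]:
        return self.summary.set_index("group")["n"].to_dict()


def relative_risk(
    events_a: int, n_a: int, events_b: int, n_b: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Risk ratio of group a vs group b with a log-normal (Katz) CI.

    Zero events in group a give RR 0; a zero reference incidence gives an
    infinite RR (both with undefined CI bounds).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if events_b == 0:
        return float("inf"), float("nan"), float("nan")
    rr = (events_a / n_a) / (events_b / n_b)
    if events_a == 0:
        return 0.0, float("nan"), float("nan")
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / events_a - 1 / n_a + 1 / events_b - 1 / n_b)
    return rr, float(rr * np.exp(-z * se)), float(rr * np.exp(z * se))


def stratify(probs, labels, t_low: float, t_high: float) -> RiskStrata:
    """Partition patients into low (< t_low), medium ([t_low, t_high]) and
    high (> t_high) risk groups; the medium group is the reference for
    relative risks."""
    if not 0.0 < t_low < t_high < 1.0:
        raise ValueError("thresholds must satisfy 0 < t_low < t_high < 1")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    groups = np.where(p < t_low, "low", np.where(p > t_high, "high", "medium"))
    rows = []
    ref_events = int(y[groups == "medium"].sum())
    ref_n = int((groups == "medium").sum())
    for g in ("low", "medium", "high"):
        mask = groups == g
        n = int(mask.sum())
        ev = int(y[mask].sum())
        if g == "medium":
            rr = 1.0 if n else np.nan
            lo = hi = np.nan
        elif n == 0 or ref_n == 0:
            rr = lo = hi = np.nan
        else:
            rr, lo, hi = relative_risk(ev, n, ref_events, ref_n)
        rows.append(
            {
                "group": g,
                "n": n,
                "events": ev,
                "incidence": ev / n if n else np.nan,
                "rr_vs_medium": rr,
                "rr_lower": lo,
                "rr_upper": hi,
            }
        )
    return RiskStrata(
        t_low=float(t_low), t_high=float(t_high),
        groups=groups, summary=pd.DataFrame(rows),
    )


def compare_proportions(
    events_a: int, n_a: int, events_b: int, n_b: int
) -> float:
    """Pearson chi-square p-value (Yates continuity corrected) for the
    difference between two incidences."""
    table = np.array(
        [[events_a, n_a - events_a], [events_b, n_b - events_b]], dtype=float
    )
    if np.any(table < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def named_thresholds(probs, labels) -> dict[str, float]:
    """The study's threshold menu computed from a cohort's predictions:
    median non-case prediction, Youden-optimal cutoff, event rate, the
    published 1/3 and 2/3 tierce points, 0.5, and the median case
    prediction."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    # Youden-index maximizer over observed prediction cutoffs
    cand = [c for c in np.unique(p) if 0.0 < c < 1.0]
    best_j, best_c = -np.inf, float("nan")
    for c in cand:
        tp, fp, tn, fn = confusion_at_threshold(p, y, c)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best_j:
            best_j, best_c = j, c
    return {
        "median_noncase": float(np.median(p[y == 0])),
        "optimal": float(best_c),
        "event_rate": float(y.mean()),
        "third": 1.0 / 3.0,
        "half": 0.5,
        "two_thirds": 2.0 / 3.0,
        "median_case": float(np.median(p[y == 1])),
    }


def threshold_report(
    probs, labels, thresholds=None, reps: int = 2000, seed: int = 0,
    subset_label: str = "all",
) -> pd.DataFrame:
    """Classification-statistics table: one row per threshold with counts,
    sensitivity/specificity/PPV/NPV and net benefit, each with bootstrap
    CIs."""
    if thresholds is None:
        thresholds = PRESET_THRESHOLDS
    rows = []
    for pt in thresholds:
        s = classification_stats(probs, labels, pt, reps=reps, seed=seed)
        rows.append(
            {
                "subset": subset_label,
                "pt": s.pt,
                "tp": s.tp, "fp": s.fp, "tn": s.tn, "fn": s.fn,
                "sensitivity": s.sensitivity,
                "sensitivity_lo": s.sensitivity_ci[0],
                "sensitivity_hi": s.sensitivity_ci[1],
                "specificity": s.specificity,
                "specificity_lo": s.specificity_ci[0],
                "specificity_hi": s.specificity_ci[1],
                "ppv": s.ppv, "ppv_lo": s.ppv_ci[0], "ppv_hi": s.ppv_ci[1],
                "npv": s.npv, "npv_lo": s.npv_ci[0], "npv_hi": s.npv_ci[1],
                "nb": s.nb, "nb_lo": s.nb_ci[0], "nb_hi": s.nb_ci[1],
            }
        )
    return pd.DataFrame(rows)
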