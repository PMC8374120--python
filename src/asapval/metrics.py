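"""Discrimination, overall performance and calibration of risk predictions.

External validation of a clinical prediction model asks three questions:
does the model rank cases above controls (discrimination, C-statistic), are
its probabilities numerically right (calibration intercept/slope and the
loess-smoothed calibration curve with its Emax/Eavg summaries), and how
accurate is it overall (Brier score, deviance, AIC)?

Calibration follows the standard offset-logistic framework: the model's
linear predictor LP enters a logistic regression of the observed outcome
either as a pure offset (fixed slope 1, free intercept — the
calibration-in-the-large intercept) or with a free slope
(``logit p = a + b*LP``).  A perfectly calibrated model has a = 0, b = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .model import P_EPS, RiskModel, linear_predictor, predict_probability

__all__ = [
    "ValidationReport",
    "CalibrationCurve",
    "c_statistic",
    "brier_score",
    "bootstrap_ci",
    "calibration_intercept_slope",
    "calibration_curve",
    "binomial_deviance",
    "fit_offset_logistic",
    "validate_model",
]

logger = logging.getLogger(__name__)

IRLS_TOL = 1e-10
IRLS_MAXITER = 100


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return y.astype(float)


def c_statistic(scores, labels) -> float:
    """Concordance: fraction of case/control pairs where the case scores
    higher, ties credited 0.5.  Computed via midranks in O(n log n)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("c_statistic undefined: both outcome classes required")
    r = rankdata(s)  # average ranks handle ties as 0.5 credit
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def brier_score(probs, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def binomial_deviance(probs, labels) -> float:
    """-2 log-likelihood of Bernoulli outcomes (saturated model has 0)."""
    y = _check_binary(labels)
    p = np.clip(np.asarray(probs, dtype=float), P_EPS, 1 - P_EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    reps: int = 2000,
    seed: int = 0,
    strata_col: str | None = "hcc",
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI with resampling stratified by outcome class
    (``strata_col=None`` gives the plain bootstrap).

    The point estimate is the statistic of the original sample.  Replicates
    that leave a stratum without both classes (possible only when a stratum
    mixes classes) are redrawn and logged.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng([3, seed])
    point = float(statistic(cohort))
    if strata_col is None:
        strata = [cohort.index.to_numpy()]
    else:
        strata = [g.index.to_numpy() for _, g in cohort.groupby(strata_col, sort=True)]
    vals = np.empty(reps)
    for i in range(reps):
        for _attempt in range(100):
            idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
            resample = cohort.loc[idx].reset_index(drop=True)
            if "hcc" in resample and resample["hcc"].nunique() < 2 <= cohort["hcc"].nunique():
                logger.info("bootstrap replicate %d single-class; redrawn", i)
                continue
            break
        vals[i] = statistic(resample)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def fit_offset_logistic(
    labels,
    exog: np.ndarray | None,
    offset: np.ndarray | None = None,
):
    """IRLS logistic fit with an optional offset (statsmodels GLM engine)."""
    y = _check_binary(labels)
    if exog is None:
        exog = np.ones((len(y), 1))
    res = sm.GLM(
        y, exog, family=sm.families.Binomial(), offset=offset
    ).fit(tol=IRLS_TOL, maxiter=IRLS_MAXITER)
    if not res.converged:
        raise RuntimeError(
            "offset logistic fit did not converge after "
            f"{IRLS_MAXITER} IRLS iterations; deviance trace: "
            f"{getattr(res, 'fit_history', {}).get('deviance', [])!r}"
        )
    return res


def calibration_intercept_slope(
    lp,
    labels,
    mode: Literal["intercept_only", "intercept_slope"] = "intercept_slope",
) -> tuple[float, float]:
    """Calibration parameters of a linear predictor.

    ``intercept_only`` fits ``logit p = a + LP`` (LP as offset, slope fixed
    at 1) and returns ``(a, 1.0)``; ``intercept_slope`` fits
    ``logit p = a + b*LP`` by maximum likelihood and returns ``(a, b)``.
    """
    lp = np.asarray(lp, dtype=float)
    y = _check_binary(labels)
    if y.min() == y.max():
        raise ValueError("both outcome classes required for calibration fit")
    if mode == "intercept_only":
        res = fit_offset_logistic(y, None, offset=lp)
        return float(res.params[0]), 1.0
    if mode == "intercept_slope":
        res = fit_offset_logistic(y, sm.add_constant(lp))
        return float(res.params[0]), float(res.params[1])
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Loess calibration curve: smoothed observed frequency at each
    observed predicted probability, with max/mean absolute error."""

    predicted: np.ndarray
    observed: np.ndarray
    emax: float
    eavg: float


def calibration_curve(probs, labels, span: float = 0.75) -> CalibrationCurve:
    """Locally weighted (loess, degree 1) calibration curve.

    The observed outcome is smoothed against the predicted probability and
    evaluated at every observed prediction; ``emax``/``eavg`` are the
    maximum/mean absolute differences between predicted and smoothed
    probabilities.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if len(p) < 20:
        raise ValueError("calibration curve requires at least 20 observations")
    # delta collapses near-duplicate abscissae; keeps loess O(n) in practice
    delta = 0.001 * (p.max() - p.min())
    sm_xy = sm.nonparametric.lowess(
        y, p, frac=span, it=0, delta=delta, return_sorted=True
    )
    order = np.argsort(p, kind="stable")
    pred = p[order]
    obs = np.clip(np.interp(pred, sm_xy[:, 0], sm_xy[:, 1]), 0.0, 1.0)
    err = np.abs(pred - obs)
    return CalibrationCurve(
        predicted=pred, observed=obs, emax=float(err.max()), eavg=float(err.mean())
    )


@dataclass(frozen=True)
class ValidationReport:
    """Full external-validation summary of one model on one cohort."""

    c_statistic: float
    c_lower: float
    c_upper: float
    brier: float
    residual_deviance: float
    df_resid: int
    aic: float
    calibration_intercept: float
    calibration_slope: float
    emax: float
    eavg: float
    curve: CalibrationCurve = field(repr=False)

    def to_dict(self) -> dict[str, float]:
        d = {
            "c_statistic": self.c_statistic,
            "c_lower": self.c_lower,
            "c_upper": self.c_upper,
            "brier": self.brier,
            "residual_deviance": self.residual_deviance,
            "df_resid": self.df_resid,
            "aic": self.aic,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
            "emax": self.emax,
            "eavg": self.eavg,
        }
        return d


def validate_model(
    model: RiskModel,
    cohort: pd.DataFrame,
    reps: int = 2000,
    seed: int = 0,
    n_free: int = 0,
    span: float = 0.75,
) -> ValidationReport:
    """Validate ``model`` on ``cohort``: C-statistic with stratified
    bootstrap CI, Brier, deviance/AIC (``n_free`` free parameters counted in
    the AIC penalty and residual df), calibration intercept/slope, and the
    loess calibration curve with Emax/Eavg."""
    lp = linear_predictor(model, cohort)
    p = predict_probability(model, cohort)
    y = np.asarray(cohort["hcc"])

    def _c(df: pd.DataFrame) -> float:
        return c_statistic(linear_predictor(model, df), df["hcc"])

    c, c_lo, c_hi = bootstrap_ci(_c, cohort, reps=reps, seed=seed)
    dev = binomial_deviance(p, y)
    a, b = calibration_intercept_slope(lp, y, mode="intercept_slope")
    curve = calibration_curve(p, y, span=span)
    return ValidationReport(
        c_statistic=c,
        c_lower=c_lo,
        c_upper=c_hi,
        brier=brier_score(p, y),
        residual_deviance=dev,
        df_resid=len(y) - n_free,
        aic=dev + 2 * n_free,
        calibration_intercept=a,
        calibration_slope=b,
        emax=curve.emax,
        eavg=curve.eavg,
        curve=curve,
    )
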