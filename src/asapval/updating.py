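"""Model updating: recalibration strategies, closed testing, optimism.

When an externally validated model is miscalibrated, three nested updates
are available, in increasing order of complexity:

1. **Recalibration-in-the-large** — refit only the intercept, keeping the
   original linear predictor as an offset (1 free parameter).
2. **Logistic recalibration** — refit intercept and a single slope on the
   original linear predictor (2 free parameters).
3. **Model revision** — refit all coefficients on the new cohort
   (5 free parameters).

The *closed testing procedure* selects the simplest adequate strategy by a
fixed chain of likelihood-ratio tests of the revision against, in order,
the original model (df 5), recalibration-in-the-large (df 4) and
recalibration (df 3): the first non-significant comparison stops the chain
and that strategy is adopted; if all are significant the revision is
adopted.  A p-value of exactly alpha counts as non-significant.

Degrees of freedom follow the external-validation convention that the
original model has zero free parameters (its residual df equals n), and
``AIC = deviance + 2 * free parameters`` (exact for Bernoulli outcomes).

Bootstrap optimism correction (Harrell): the revision is refit on each
bootstrap resample and evaluated on the original cohort; the mean drop in
the C-statistic estimates the optimism, and the mean calibration slope of
the bootstrap models on the original data estimates the shrinkage factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import (
    binomial_deviance,
    c_statistic,
    calibration_intercept_slope,
    brier_score,
    fit_offset_logistic,
)
from .model import RiskModel, linear_predictor, predict_probability, _design

__all__ = [
    "FitResult",
    "LRTResult",
    "ClosedTestResult",
    "SeparationError",
    "fit_original",
    "recalibrate_in_the_large",
    "recalibrate",
    "revise",
    "likelihood_ratio_test",
    "closed_test",
    "bootstrap_optimism",
    "OptimismResult",
    "updating_report",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("original", "in_the_large", "recalibrated", "revised")


class SeparationError(RuntimeError):
    """Raised when a logistic fit has no finite maximum likelihood."""


@dataclass(frozen=True)
class FitResult:
    """A fitted (or fixed) risk model with its likelihood bookkeeping."""

    model: RiskModel
    loglik: float
    deviance: float
    n_free: int
    n_obs: int

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_free

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_free


def _check_cohort(cohort: pd.DataFrame) -> np.ndarray:
    y = np.asarray(cohort["hcc"])
    if not np.isin(y, (0, 1)).all():
        raise ValueError("hcc labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes required to fit")
    return y.astype(float)


def fit_original(model: RiskModel, cohort: pd.DataFrame) -> FitResult:
    """Evaluate the model as-is: zero free parameters, LP as pure offset."""
    y = _check_cohort(cohort)
    dev = binomial_deviance(predict_probability(model, cohort), y)
    return FitResult(model=model, loglik=-dev / 2, deviance=dev,
                     n_free=0, n_obs=len(y))


def recalibrate_in_the_large(model: RiskModel, cohort: pd.DataFrame) -> FitResult:
    """Update only the intercept; the original LP enters as an offset."""
    y = _check_cohort(cohort)
    lp = linear_predictor(model, cohort)
    res = fit_offset_logistic(y, None, offset=lp)
    a = float(res.params[0])
    return FitResult(
        model=model.shift_intercept(a),
        loglik=float(res.llf),
        deviance=float(res.deviance),
        n_free=1,
        n_obs=len(y),
    )


def recalibrate(model: RiskModel, cohort: pd.DataFrame) -> FitResult:
    """Refit intercept and a single slope on the original LP.

    The returned model's coefficients are exactly slope times the original
    coefficients, and its intercept is slope*original_intercept + a.
    """
    y = _check_cohort(cohort)
    lp = linear_predictor(model, cohort)
    res = fit_offset_logistic(y, sm.add_constant(lp))
    a, b = float(res.params[0]), float(res.params[1])
    return FitResult(
        model=model.rescale(a, b),
        loglik=float(res.llf),
        deviance=float(res.deviance),
        n_free=2,
        n_obs=len(y),
    )


_SEP_COEF_LIMIT = 1e3


def revise(model: RiskModel, cohort: pd.DataFrame) -> FitResult:
    """Full refit of intercept and all four coefficients on the cohort."""
    y = _check_cohort(cohort)
    X = sm.add_constant(_design(cohort))
    res = fit_offset_logistic(y, X)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:])) > _SEP_COEF_LIMIT:
        names = ["intercept", "age", "sex", "ln afp", "ln pivka2"]
        worst = names[int(np.argmax(np.abs(params)))]
        raise SeparationError(
            f"revision fit appears separated (runaway coefficient on {worst})"
        )
    new = RiskModel(
        intercept=params[0],
        b_age=params[1],
        b_sex=params[2],
        b_afp=params[3],
        b_pivka=params[4],
        provenance="revised",
    )
    return FitResult(
        model=new,
        loglik=float(res.llf),
        deviance=float(res.deviance),
        n_free=5,
        n_obs=len(y),
    )


@dataclass(frozen=True)
class LRTResult:
    label: str
    chi_square: float
    df: int
    p_value: float


def likelihood_ratio_test(restricted: FitResult, full: FitResult,
                          label: str = "") -> LRTResult:
    """LRT of a restricted model against a full model it is nested in."""
    chi2 = restricted.deviance - full.deviance
    df = full.n_free - restricted.n_free
    if df <= 0:
        raise ValueError("full model must have more free parameters")
    if chi2 < -1e-8:
        raise ValueError(
            f"negative LRT statistic ({chi2:.3g}): models not nested or a "
            "fit did not converge"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LRTResult(label=label, chi_square=float(chi2), df=df, p_value=p)


@dataclass(frozen=True)
class ClosedTestResult:
    chain: tuple[LRTResult, ...]
    adopted: str
    fits: dict[str, FitResult]

    @property
    def model(self) -> RiskModel:
        return self.fits[self.adopted].model


def closed_test(model: RiskModel, cohort: pd.DataFrame,
                alpha: float = 0.05) -> ClosedTestResult:
    """Closed testing procedure selecting the updating strategy.

    Tests the revision against the original model, then
    recalibration-in-the-large, then recalibration, adopting the first
    restricted model not rejected at ``alpha`` (ties non-significant);
    adopts the revision if all three are rejected.
    """
    fits: dict[str, FitResult] = {}
    for name, fn in (
        ("original", fit_original),
        ("in_the_large", recalibrate_in_the_large),
        ("recalibrated", recalibrate),
        ("revised", revise),
    ):
        try:
            fits[name] = fn(model, cohort)
        except Exception as exc:
            raise RuntimeError(f"closed test aborted at stage {name!r}: {exc}") from exc

    chain = []
    adopted = "revised"
    for name in ("original", "in_the_large", "recalibrated"):
        lrt = likelihood_ratio_test(
            fits[name], fits["revised"], label=f"revision vs {name}"
        )
        chain.append(lrt)
        if lrt.p_value >= alpha:
            adopted = name
            break
    return ClosedTestResult(chain=tuple(chain), adopted=adopted, fits=fits)


@dataclass(frozen=True)
class OptimismResult:
    apparent_c: float
    optimism: float
    corrected_c: float
    shrinkage: float
    reps: int


def bootstrap_optimism(cohort: pd.DataFrame, reps: int = 200,
                       seed: int = 0) -> OptimismResult:
    """Harrell bootstrap optimism correction for the revision fit.

    Refits the full 5-parameter model on each stratified resample,
    evaluates it on the original cohort, and reports the optimism-corrected
    C-statistic and the shrinkage factor (mean calibration slope of the
    bootstrap models on the original data).  Replicates whose fit is
    separated are redrawn (logged).
    """
    if reps < 50:
        raise ValueError("reps must be >= 50 for a stable optimism estimate")
    rng = np.random.default_rng([4, seed])
    y = np.asarray(cohort["hcc"])
    base = revise(_any_model(), cohort)
    apparent = c_statistic(linear_predictor(base.model, cohort), y)
    strata = [g.index.to_numpy() for _, g in cohort.groupby("hcc", sort=True)]

    optimisms = np.empty(reps)
    slopes = np.empty(reps)
    for i in range(reps):
        for _attempt in range(100):
            idx = np.concatenate(
                [rng.choice(s, size=len(s), replace=True) for s in strata]
            )
            boot = cohort.loc[idx].reset_index(drop=True)
            try:
                fit_b = revise(_any_model(), boot)
            except (SeparationError, RuntimeError) as exc:
                logger.info("optimism replicate %d redrawn: %s", i, exc)
                continue
            break
        else:
            raise RuntimeError("could not draw a fittable bootstrap replicate")
        c_boot = c_statistic(linear_predictor(fit_b.model, boot), boot["hcc"])
        lp_orig = linear_predictor(fit_b.model, cohort)
        c_orig = c_statistic(lp_orig, y)
        optimisms[i] = c_boot - c_orig
        _, slopes[i] = calibration_intercept_slope(lp_orig, y, "intercept_slope")

    opt = float(np.mean(optimisms))
    return OptimismResult(
        apparent_c=float(apparent),
        optimism=opt,
        corrected_c=float(apparent - opt),
        shrinkage=float(np.mean(slopes)),
        reps=reps,
    )


def _any_model() -> RiskModel:
    # revision ignores the starting coefficients; any finite model works
    return RiskModel(0.0, 0.0, 0.0, 0.0, 0.0, provenance="original")


def updating_report(model: RiskModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side characteristics of the four strategies on one cohort:
    coefficients, own-data calibration, deviance/df, LRT against the
    revision, AIC, Brier and C-statistic."""
    ct = closed_test(model, cohort)
    y = np.asarray(cohort["hcc"])
    lrt_by_name = {l.label.split(" vs ")[1]: l for l in ct.chain}
    rows = []
    for name in STRATEGIES:
        fit = ct.fits[name]
        lp = linear_predictor(fit.model, cohort)
        p = predict_probability(fit.model, cohort)
        a, b = calibration_intercept_slope(lp, y, "intercept_slope")
        lrt = lrt_by_name.get(name)
        rows.append(
            {
                "strategy": name,
                "adopted": name == ct.adopted,
                "intercept": fit.model.intercept,
                "b_age": fit.model.b_age,
                "b_sex": fit.model.b_sex,
                "b_afp": fit.model.b_afp,
                "b_pivka": fit.model.b_pivka,
                "calibration_intercept": a,
                "calibration_slope": b,
                "residual_deviance": fit.deviance,
                "df": fit.df_resid,
                "lrt_p_vs_revision": lrt.p_value if lrt else np.nan,
                "aic": fit.aic,
                "brier": brier_score(p, y),
                "c_statistic": c_statistic(lp, y),
            }
        )
    return pd.DataFrame(rows)
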