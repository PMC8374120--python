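"""Four-covariate logistic HCC risk models and nomogram score tables.

The ASAP model predicts the probability that a patient under liver
surveillance has hepatocellular carcinoma from age (years), sex (0 = male,
1 = female), and the serum markers AFP (ng/mL) and PIVKA-II (mAU/mL).  Both
markers enter on the **natural-log** scale — the published coefficient
magnitudes only make sense for natural log (e.g. a mean log PIVKA-II of
8.47 corresponds to exp(8.47) ~ 4,770 mAU/mL, a realistic HCC value).

The linear predictor is

    LP = intercept + b_age*age + b_sex*sex + b_afp*ln(AFP) + b_pivka*ln(PIVKA-II)

and the risk is ``p = 1 / (1 + exp(-LP))``.  Updated variants of a model
(intercept shift, logistic recalibration) are plain coefficient transforms
and live on :class:`RiskModel`; the fitting procedures that estimate them
are in :mod:`asapval.updating`.

A :class:`ScoreTable` is the tabular form of a nomogram: each covariate's
contribution ``b*x`` is mapped linearly to 0–100 points (100 = the largest
single-covariate contribution range), and the total over covariates maps
back to a probability through the logistic — an exact, invertible
construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "RiskModel",
    "ASAP_MODEL",
    "ScoreTable",
    "linear_predictor",
    "predict_probability",
    "build_score_table",
    "score_to_probability",
    "P_EPS",
]

#: probabilities are clipped to [P_EPS, 1 - P_EPS] before log-likelihoods
P_EPS = 1e-12

_COVARIATES = ("age", "sex", "afp", "pivka2")
_LOG_COVARIATES = frozenset({"afp", "pivka2"})


@dataclass(frozen=True)
class RiskModel:
    """Logistic risk model on age, sex, ln AFP and ln PIVKA-II.

    ``provenance`` records how the model arose: the published original, an
    intercept update (``in_the_large``), a logistic recalibration, or a full
    refit (``revised``).
    """

    intercept: float
    b_age: float
    b_sex: float
    b_afp: float
    b_pivka: float
    provenance: str = "original"

    def __post_init__(self) -> None:
        for name in ("intercept", "b_age", "b_sex", "b_afp", "b_pivka"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "age": self.b_age,
            "sex": self.b_sex,
            "afp": self.b_afp,
            "pivka2": self.b_pivka,
        }

    def shift_intercept(self, a: float, provenance: str = "in_the_large") -> "RiskModel":
        """Recalibration-in-the-large: add ``a`` to the intercept."""
        return replace(self, intercept=self.intercept + a, provenance=provenance)

    def rescale(self, a: float, b: float, provenance: str = "recalibrated") -> "RiskModel":
        """Logistic recalibration: LP -> a + b*LP, i.e. every coefficient is
        multiplied by the slope ``b`` and the intercept becomes
        ``b*intercept + a``."""
        return RiskModel(
            intercept=b * self.intercept + a,
            b_age=b * self.b_age,
            b_sex=b * self.b_sex,
            b_afp=b * self.b_afp,
            b_pivka=b * self.b_pivka,
            provenance=provenance,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls(**json.load(fh))


#: the published ASAP model (development-cohort coefficients)
ASAP_MODEL = RiskModel(
    intercept=-7.57711770,
    b_age=0.04666357,
    b_sex=-0.57611693,
    b_afp=0.42243533,
    b_pivka=1.10518910,
    provenance="original",
)


def _design(cohort: pd.DataFrame) -> np.ndarray:
    """Model-scale covariate matrix [age, sex, ln afp, ln pivka2]."""
    afp = np.asarray(cohort["afp"], dtype=float)
    pivka = np.asarray(cohort["pivka2"], dtype=float)
    for name, vals in (("afp", afp), ("pivka2", pivka)):
        bad = ~(vals > 0)
        if bad.any():
            rows = np.flatnonzero(bad)[:10].tolist()
            raise ValueError(
                f"{name} must be positive to take logs; offending rows {rows}"
            )
    return np.column_stack(
        [
            np.asarray(cohort["age"], dtype=float),
            np.asarray(cohort["sex"], dtype=float),
            np.log(afp),
            np.log(pivka),
        ]
    )


def linear_predictor(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Per-patient linear predictor (logit of the predicted risk)."""
    X = _design(cohort)
    beta = np.array([model.b_age, model.b_sex, model.b_afp, model.b_pivka])
    return model.intercept + X @ beta


def predict_probability(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Predicted HCC probability, strictly inside (0, 1)."""
    p = expit(linear_predictor(model, cohort))
    return np.clip(p, P_EPS, 1.0 - P_EPS)


# ---------------------------------------------------------------------------
# nomogram score tables


@dataclass(frozen=True)
class ScoreTable:
    """Nomogram point assignments for a :class:`RiskModel`.

    ``breakpoints`` maps covariate name to a two-column frame (native value,
    points).  Internally the table stores the affine map from total points
    back to the linear predictor: ``LP = lp0 + lp_per_point * total``.
    """

    model: RiskModel
    ranges: Mapping[str, tuple[float, float]]
    refs: Mapping[str, float]  # reference endpoint (native units) per covariate
    lp0: float  # LP with every covariate at its reference endpoint
    lp_per_point: float  # M / 100 in logit units
    max_total: float
    breakpoints: Mapping[str, pd.DataFrame]

    def points(self, cohort: pd.DataFrame) -> np.ndarray:
        """Total nomogram points per patient."""
        X = _design(cohort)
        total = np.zeros(len(X))
        for j, name in enumerate(_COVARIATES):
            b = self.model.coefficients[name]
            ref = _to_model_scale(name, self.refs[name])
            total = total + b * (X[:, j] - ref) / self.lp_per_point
        return total

    def to_frame(self) -> pd.DataFrame:
        """Long-format export of per-covariate breakpoints."""
        rows = []
        for name, bp in self.breakpoints.items():
            out = bp.copy()
            out.insert(0, "covariate", name)
            rows.append(out)
        return pd.concat(rows, ignore_index=True)


def _to_model_scale(name: str, value: float) -> float:
    if name in _LOG_COVARIATES:
        if value <= 0:
            raise ValueError(f"{name} range must be positive")
        return math.log(value)
    return float(value)


def build_score_table(
    model: RiskModel,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    n_breaks: int = 11,
) -> ScoreTable:
    """Construct a 0–100 point nomogram score table.

    ``ranges`` gives each covariate's plausible span in native units (AFP and
    PIVKA-II in ng/mL / mAU/mL; logs are taken internally).  The covariate
    with the widest contribution range ``|b*(u_max - u_min)|`` spans 0–100
    points; the reference endpoint of each covariate (0 points) is the end
    minimizing its contribution ``b*u``.
    """
    if ranges is None:
        ranges = {
            "age": (35.0, 90.0),
            "sex": (0.0, 1.0),
            "afp": (1.0, 1.21e6),
            "pivka2": (1.0, 7.5e5),
        }
    missing = set(_COVARIATES) - set(ranges)
    if missing:
        raise ValueError(f"missing ranges for covariates: {sorted(missing)}")

    contrib_range: dict[str, float] = {}
    refs: dict[str, float] = {}
    for name in _COVARIATES:
        lo, hi = ranges[name]
        if not lo < hi:
            raise ValueError(f"range for {name} must satisfy min < max")
        b = model.coefficients[name]
        u_lo, u_hi = _to_model_scale(name, lo), _to_model_scale(name, hi)
        contrib_range[name] = abs(b * (u_hi - u_lo))
        # reference endpoint: the end with the smaller contribution b*u
        refs[name] = lo if b * u_lo <= b * u_hi else hi

    M = max(contrib_range.values())
    if M <= 0:
        raise ValueError("widest covariate contribution range is zero; "
                         "cannot scale points")

    lp0 = model.intercept + sum(
        model.coefficients[n] * _to_model_scale(n, refs[n]) for n in _COVARIATES
    )
    lp_per_point = M / 100.0
    max_total = 100.0 * sum(contrib_range.values()) / M

    breakpoints: dict[str, pd.DataFrame] = {}
    for name in _COVARIATES:
        lo, hi = ranges[name]
        b = model.coefficients[name]
        u_ref = _to_model_scale(name, refs[name])
        u_grid = np.linspace(
            _to_model_scale(name, lo), _to_model_scale(name, hi), n_breaks
        )
        native = np.exp(u_grid) if name in _LOG_COVARIATES else u_grid
        pts = b * (u_grid - u_ref) / lp_per_point
        breakpoints[name] = pd.DataFrame({"value": native, "points": pts})

    return ScoreTable(
        model=model,
        ranges=dict(ranges),
        refs=refs,
        lp0=lp0,
        lp_per_point=lp_per_point,
        max_total=max_total,
        breakpoints=breakpoints,
    )


def score_to_probability(table: ScoreTable, total_points) -> np.ndarray | float:
    """Map total nomogram points back to a predicted probability."""
    pts = np.asarray(total_points, dtype=float)
    tol = 1e-9 * max(1.0, table.max_total)
    if np.any(pts < -tol) or np.any(pts > table.max_total + tol):
        raise ValueError(
            f"total points outside table range [0, {table.max_total:.3f}]"
        )
    p = expit(table.lp0 + table.lp_per_point * pts)
    return float(p) if np.isscalar(total_points) else p
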