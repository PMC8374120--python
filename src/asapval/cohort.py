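"""Synthetic surveillance cohorts with the case mix of an HCC validation study.

The generator emulates a hospital cohort of patients under surveillance for
hepatocellular carcinoma (HCC), composed of four diagnostic subgroups
(hepatitis, cirrhosis, benign space-occupying lesion, HCC).  Within each
subgroup, age is drawn from a normal distribution truncated at the study's
inclusion age of 35 years, sex is Bernoulli, and the two serum markers AFP
(ng/mL) and PIVKA-II (mAU/mL) are jointly log-normal: a correlated bivariate
normal is drawn on the natural-log scale and exponentiated.  The outcome
label ``hcc`` is 1 exactly for members of the HCC subgroup.

Follow-up for at-risk (non-HCC) patients is simulated with exponential event
times whose hazard depends on an externally supplied risk-group assignment,
censored by loss to follow-up and by study end under uniform accrual.

All randomness flows from a single integer seed; each operation derives its
own sub-stream deterministically (``default_rng([op_code, seed])``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubgroupParams",
    "FollowupParams",
    "DEFAULT_SUBGROUPS",
    "DEFAULT_FOLLOWUP",
    "AGE_MIN",
    "HCC_LABEL",
    "generate_cohort",
    "generate_followup",
]

#: inclusion criterion: patients aged 35 years or older
AGE_MIN = 35.0

#: subgroup label whose members carry the outcome
HCC_LABEL = "HCC"

# sub-stream opcodes (documented part of the determinism contract)
_OP_COHORT = 1
_OP_FOLLOWUP = 2


@dataclass(frozen=True)
class SubgroupParams:
    """Marginal distribution of one diagnostic subgroup.

    Marker moments are on the natural-log scale (log ng/mL for AFP, log
    mAU/mL for PIVKA-II); ``marker_corr`` is the within-subgroup correlation
    of the two log-markers, a free parameter since only marginals are
    reported for real cohorts.
    """

    label: str
    n: int
    age_mean: float
    age_sd: float
    male_frac: float
    logafp_mean: float
    logafp_sd: float
    logpivka_mean: float
    logpivka_sd: float
    marker_corr: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"subgroup {self.label!r}: n must be >= 0, got {self.n}")
        for name in ("age_sd", "logafp_sd", "logpivka_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"subgroup {self.label!r}: {name} must be >= 0")
        if not 0.0 <= self.male_frac <= 1.0:
            raise ValueError(f"subgroup {self.label!r}: male_frac must be in [0, 1]")
        if not -1.0 <= self.marker_corr <= 1.0:
            raise ValueError(f"subgroup {self.label!r}: marker_corr must be in [-1, 1]")


#: default case mix: subgroup sizes, age and log-marker moments, male fractions
#: of a 1012-patient surveillance cohort (overall HCC prevalence 15.5%)
DEFAULT_SUBGROUPS: tuple[SubgroupParams, ...] = (
    SubgroupParams("hepatitis", 451, 50.7, 9.4, 0.765, 1.46, 1.09, 3.14, 0.58),
    SubgroupParams("cirrhosis", 308, 58.1, 10.7, 0.669, 1.70, 1.32, 3.33, 1.00),
    SubgroupParams("benign_SOL", 96, 58.5, 12.4, 0.604, 1.87, 1.55, 3.54, 1.08),
    SubgroupParams(HCC_LABEL, 157, 59.6, 12.0, 0.847, 5.94, 3.85, 8.47, 2.56),
)


@dataclass(frozen=True)
class FollowupParams:
    """Follow-up simulation parameters for at-risk patients.

    ``hazards`` maps risk-group label to a constant event hazard in
    events/month.  Loss to follow-up censors a ``loss_frac`` fraction of
    patients uniformly before their administrative censoring time; the
    administrative time itself is uniform on ``[0, horizon]`` (study-end
    censoring under uniform accrual over a study window of ``horizon``
    months).
    """

    hazards: Mapping[str, float] = field(
        default_factory=lambda: {"low": 5.0e-4, "medium": 3.3e-3, "high": 1.4e-2}
    )
    loss_frac: float = 0.188
    horizon: float = 24.0

    def __post_init__(self) -> None:
        for group, h in self.hazards.items():
            if h < 0:
                raise ValueError(f"hazard for group {group!r} must be >= 0, got {h}")
        if not 0.0 <= self.loss_frac <= 1.0:
            raise ValueError("loss_frac must be in [0, 1]")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")


DEFAULT_FOLLOWUP = FollowupParams()


def _draw_subgroup(sp: SubgroupParams, rng: np.random.Generator) -> pd.DataFrame:
    if sp.n == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=d) for c, d in _EMPTY_DTYPES.items()}
        )
    # age: normal truncated below at the inclusion age
    if sp.age_sd > 0:
        a = (AGE_MIN - sp.age_mean) / sp.age_sd
        age = stats.truncnorm.rvs(
            a, np.inf, loc=sp.age_mean, scale=sp.age_sd, size=sp.n, random_state=rng
        )
    else:
        age = np.full(sp.n, max(sp.age_mean, AGE_MIN))
    sex = (rng.random(sp.n) >= sp.male_frac).astype(int)  # 0=male, 1=female
    cov = sp.marker_corr * sp.logafp_sd * sp.logpivka_sd
    sigma = np.array([[sp.logafp_sd**2, cov], [cov, sp.logpivka_sd**2]])
    logmk = rng.multivariate_normal(
        [sp.logafp_mean, sp.logpivka_mean], sigma, size=sp.n, method="cholesky"
    )
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "afp": np.exp(logmk[:, 0]),
            "pivka2": np.exp(logmk[:, 1]),
            "hcc": int(sp.label == HCC_LABEL),
            "subgroup": sp.label,
        }
    )


_EMPTY_DTYPES = {
    "age": float,
    "sex": int,
    "afp": float,
    "pivka2": float,
    "hcc": int,
    "subgroup": object,
}


def generate_cohort(
    params: Iterable[SubgroupParams] = DEFAULT_SUBGROUPS, seed: int = 0
) -> pd.DataFrame:
    """Generate a patient-level cohort table from subgroup parameters.

    Parameters
    ----------
    params
        Per-subgroup marginal distributions; row counts equal each
        subgroup's configured ``n`` and rows are ordered by subgroup.
    seed
        Integer seed; identical seed and params give an identical table.

    Returns
    -------
    pandas.DataFrame
        Columns ``age, sex, afp, pivka2, hcc, subgroup``; ``hcc`` is 1
        exactly for the HCC subgroup.
    """
    params = list(params)
    if not params:
        raise ValueError("at least one subgroup is required")
    rng = np.random.default_rng([_OP_COHORT, seed])
    frames = [_draw_subgroup(sp, rng) for sp in params]
    out = pd.concat(frames, ignore_index=True)
    return out.astype(_EMPTY_DTYPES)


def generate_followup(
    cohort: pd.DataFrame,
    fp: FollowupParams,
    group_assign: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Attach simulated follow-up (``time`` in months, ``event`` 0/1).

    Event times are exponential with the per-group hazard; censoring is the
    minimum of a uniform administrative time on [0, horizon] and, for the
    loss-to-follow-up fraction, a uniform earlier loss time.  ``event`` is 1
    iff the event time precedes the censoring time.
    """
    groups = np.asarray(group_assign, dtype=object)
    if len(groups) != len(cohort):
        raise ValueError(
            f"group_assign has length {len(groups)}, cohort has {len(cohort)} rows"
        )
    if pd.isna(groups).any():
        raise ValueError("missing group assignment")
    unknown = set(groups) - set(fp.hazards)
    if unknown:
        raise ValueError(f"no hazard configured for groups: {sorted(unknown)}")

    rng = np.random.default_rng([_OP_FOLLOWUP, seed])
    n = len(cohort)
    hazard = np.array([fp.hazards[g] for g in groups], dtype=float)
    with np.errstate(divide="ignore"):
        t_event = np.where(
            hazard > 0, rng.exponential(1.0, size=n) / np.where(hazard > 0, hazard, 1.0), np.inf
        )
    t_admin = rng.uniform(0.0, fp.horizon, size=n) if fp.horizon > 0 else np.zeros(n)
    lost = rng.random(n) < fp.loss_frac
    t_loss = np.where(lost, rng.uniform(0.0, 1.0, size=n) * t_admin, np.inf)
    t_censor = np.minimum(t_admin, t_loss)

    out = cohort.copy()
    out["time"] = np.minimum(t_event, t_censor)
    out["event"] = (t_event <= t_censor).astype(int)
    return out
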