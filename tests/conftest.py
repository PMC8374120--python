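import numpy as np
import pandas as pd
import pytest

from asapval import ASAP_MODEL, generate_cohort, predict_probability
from asapval.cohort import DEFAULT_SUBGROUPS, SubgroupParams


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The default 1012-patient synthetic cohort (fixed seed)."""
    return generate_cohort(DEFAULT_SUBGROUPS, seed=20240101)


@pytest.fixture(scope="session")
def asap_lp(default_cohort):
    from asapval import linear_predictor

    return linear_predictor(ASAP_MODEL, default_cohort)


def scaled_subgroups(factor: float) -> list[SubgroupParams]:
    """Default case mix with every subgroup size scaled by ``factor``."""
    from dataclasses import replace

    return [replace(sp, n=int(round(sp.n * factor))) for sp in DEFAULT_SUBGROUPS]


def simulate_outcomes(model, cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Cohort whose 0/1 outcome is drawn from the model's own probabilities,
    so the model is perfectly calibrated for it by construction."""
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["hcc"] = (rng.random(len(out)) < predict_probability(model, out)).astype(int)
    return out


@pytest.fixture(scope="session")
def big_selfconsistent_cohort() -> pd.DataFrame:
    """~50,000-patient cohort with outcomes simulated from the ASAP model
    itself; shared by the parameter-recovery and calibration checks."""
    cov = generate_cohort(scaled_subgroups(50), seed=7)
    return simulate_outcomes(ASAP_MODEL, cov, seed=77)
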