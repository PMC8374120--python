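"""End-to-end validation pipeline: cohort -> validation -> updating ->
thresholds -> stratification -> follow-up, with an auditable report bundle.

Every numeric report is written as CSV (or JSON) prefixed with comment
lines echoing the seed and a SHA-256 hash of the configuration, so any two
runs can be diffed and attributed.  All randomness flows from the single
``seed`` field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_FOLLOWUP,
    DEFAULT_SUBGROUPS,
    generate_cohort,
    generate_followup,
)
from .decision import decision_curve, named_thresholds, stratify, threshold_report
from .followup import cumulative_incidence_table, logrank, pairwise_logrank
from .io import read_cohort, write_cohort
from .metrics import validate_model
from .model import ASAP_MODEL, RiskModel, predict_probability
from .updating import closed_test, updating_report

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "validate", "update", "thresholds", "stratify", "followup")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_path`` (read an existing cohort CSV) or
    ``simulate=True`` (generate the default synthetic cohort) must be set.
    ``strat_thresholds`` may be an explicit ``(t_low, t_high)`` pair or
    ``"auto"`` (median non-case prediction and cohort event rate under the
    adopted model).
    """

    simulate: bool = True
    cohort_path: str | None = None
    model_path: str | None = None
    thresholds: list[float] | None = None
    strat_thresholds: str | tuple[float, float] = "auto"
    reps: int = 2000
    seed: int = 0
    outdir: str = "asapval_out"
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.simulate == (self.cohort_path is not None):
            raise ValueError(
                "exactly one of simulate=True or cohort_path must be set"
            )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if isinstance(data.get("strat_thresholds"), list):
            data["strat_thresholds"] = tuple(data["strat_thresholds"])
        return cls(**data)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(cfg: PipelineConfig) -> str:
    return f"# asapval {__version__} seed={cfg.seed} config_sha256={cfg.sha256()}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, index=False)


def _write_json(obj, path: Path, cfg: PipelineConfig) -> None:
    payload = {"seed": cfg.seed, "config_sha256": cfg.sha256(), **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages; returns {report name: path}.

    Any stage failure aborts with the stage name and cause.  Reports:
    ``cohort`` (if simulated), ``validation``, ``updating`` (Table-2-style
    strategy comparison + closed-test decision), ``thresholds``
    (Table-3-style), ``strata``, ``km_curves``/``logrank``, and ``run_log``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}
    stage = "setup"
    try:
        model = (
            RiskModel.from_json(cfg.model_path) if cfg.model_path else ASAP_MODEL
        )

        stage = "simulate"
        if cfg.simulate:
            cohort = generate_cohort(DEFAULT_SUBGROUPS, seed=cfg.seed)
            if "simulate" in cfg.stages:
                path = out / "cohort.csv"
                with open(path, "w") as fh:
                    fh.write(_stamp(cfg))
                    write_cohort(cohort, fh)
                bundle["cohort"] = path
        else:
            cohort = read_cohort(cfg.cohort_path)

        stage = "validate"
        if "validate" in cfg.stages:
            report = validate_model(model, cohort, reps=cfg.reps, seed=cfg.seed)
            path = out / "validation.json"
            _write_json({"model": asdict(model), **report.to_dict()}, path, cfg)
            bundle["validation"] = path
        else:
            logger.info("stage 'validate' skipped by config")

        stage = "update"
        adopted_model = model
        if "update" in cfg.stages:
            table = updating_report(model, cohort)
            ct = closed_test(model, cohort)
            adopted_model = ct.model
            path = out / "updating.csv"
            _write_csv(table, path, cfg)
            bundle["updating"] = path
            txt = out / "closed_test.txt"
            with open(txt, "w") as fh:
                fh.write(_stamp(cfg))
                for l in ct.chain:
                    fh.write(
                        f"{l.label}: chi2={l.chi_square:.4f} df={l.df} "
                        f"p={l.p_value:.4g}\n"
                    )
                fh.write(f"adopted strategy: {ct.adopted}\n")
                fh.write(f"adopted model: {asdict(ct.model)}\n")
            bundle["closed_test"] = txt
        else:
            logger.info("stage 'update' skipped by config")

        probs = predict_probability(adopted_model, cohort)
        y = np.asarray(cohort["hcc"])

        stage = "thresholds"
        if "thresholds" in cfg.stages:
            ths = cfg.thresholds or sorted(named_thresholds(probs, y).values())
            table3 = threshold_report(
                probs, y, thresholds=ths, reps=cfg.reps, seed=cfg.seed
            )
            path = out / "thresholds.csv"
            _write_csv(table3, path, cfg)
            bundle["thresholds"] = path
            curve = decision_curve(probs, y)
            path = out / "decision_curve.csv"
            _write_csv(curve, path, cfg)
            bundle["decision_curve"] = path
        else:
            logger.info("stage 'thresholds' skipped by config")

        stage = "stratify"
        strata = None
        if "stratify" in cfg.stages or "followup" in cfg.stages:
            if cfg.strat_thresholds == "auto":
                named = named_thresholds(probs, y)
                t_low, t_high = named["median_noncase"], named["event_rate"]
            else:
                t_low, t_high = cfg.strat_thresholds
            strata = stratify(probs, y, t_low, t_high)
        if "stratify" in cfg.stages:
            path = out / "strata.csv"
            _write_csv(strata.summary, path, cfg)
            bundle["strata"] = path
        else:
            logger.info("stage 'stratify' skipped by config")

        stage = "followup"
        if "followup" in cfg.stages:
            at_risk = cohort[cohort["hcc"] == 0].copy()
            groups_arr = strata.groups[np.asarray(cohort["hcc"]) == 0]
            if cfg.simulate or "time" not in cohort.columns:
                at_risk = generate_followup(
                    at_risk, DEFAULT_FOLLOWUP, groups_arr, seed=cfg.seed
                )
            groups = {
                g: (
                    at_risk.loc[groups_arr == g, "time"].to_numpy(),
                    at_risk.loc[groups_arr == g, "event"].to_numpy(),
                )
                for g in ("low", "medium", "high")
                if (groups_arr == g).any()
            }
            inc = cumulative_incidence_table(groups)
            path = out / "km_incidence.csv"
            _write_csv(inc, path, cfg)
            bundle["km_incidence"] = path
            lr = logrank(list(groups.values()))
            pw = pairwise_logrank(groups)
            txt = out / "logrank.txt"
            with open(txt, "w") as fh:
                fh.write(_stamp(cfg))
                fh.write(
                    f"overall log-rank: chi2={lr.chi_square:.4f} df={lr.df} "
                    f"p={lr.p_value:.4g}\n"
                )
                fh.write(f"groups: {list(groups)}\n")
                fh.write(f"observed: {lr.observed.tolist()}\n")
                fh.write(f"expected: {lr.expected.tolist()}\n\n")
                fh.write(pw.to_string(index=False) + "\n")
            bundle["logrank"] = txt
        else:
            logger.info("stage 'followup' skipped by config")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log = out / "run_log.json"
    with open(log, "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": cfg.seed,
                "config_sha256": cfg.sha256(),
                "config": asdict(cfg),
                "stages_run": [s for s in cfg.stages],
                "reports": {k: str(v) for k, v in bundle.items()},
                "versions": _versions(),
            },
            fh,
            indent=2,
            default=str,
        )
    bundle["run_log"] = log
    return bundle


def _versions() -> dict[str, str]:
    import lifelines
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
    }
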