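"""Cohort CSV input/output with validation.

The on-disk cohort format is a plain CSV with the fixed header
``age,sex,afp,pivka2,hcc,subgroup,time,event``; ``time`` (months) and
``event`` are optional per row and encoded as empty fields when absent.
Extra columns are preserved as passthrough metadata.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["COHORT_COLUMNS", "read_cohort", "write_cohort", "CohortFormatError"]

#: documented cohort header; time/event optional
COHORT_COLUMNS = ("age", "sex", "afp", "pivka2", "hcc", "subgroup", "time", "event")
_REQUIRED = ("age", "sex", "afp", "pivka2", "hcc")


class CohortFormatError(ValueError):
    """A cohort file violates the documented format."""


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Rejects files missing a required column (naming it) and rows with
    missing or nonpositive marker values (listing 1-based data row
    numbers).  ``event=1`` requires ``time`` to be present.
    """
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED:
        if col not in df.columns:
            raise CohortFormatError(f"missing required column {col!r}")
    for col in ("afp", "pivka2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            rows = (df.index[bad] + 1).tolist()
            raise CohortFormatError(
                f"column {col!r}: missing or nonpositive values in data rows {rows}"
            )
        df[col] = vals.astype(float)
    for col in ("age",):
        df[col] = pd.to_numeric(df[col]).astype(float)
    for col in ("sex", "hcc"):
        vals = pd.to_numeric(df[col]).astype(int)
        if not vals.isin((0, 1)).all():
            raise CohortFormatError(f"column {col!r} must be 0/1")
        df[col] = vals
    if "event" in df.columns:
        has_event = pd.to_numeric(df["event"], errors="coerce") == 1
        if "time" not in df.columns:
            if has_event.any():
                raise CohortFormatError("event=1 rows require a time column")
        else:
            no_time = has_event & pd.to_numeric(df["time"], errors="coerce").isna()
            if no_time.any():
                rows = (df.index[no_time] + 1).tolist()
                raise CohortFormatError(
                    f"event=1 without a follow-up time in data rows {rows}"
                )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the documented column order (known columns
    first, passthrough columns after); missing time/event become empty
    fields."""
    known = [c for c in COHORT_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in COHORT_COLUMNS]
    cohort[known + extra].to_csv(path, index=False)
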