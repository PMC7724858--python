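"""Case-control odds-ratio analysis from a cohort table.

Only crude (unadjusted) odds ratios are computed; covariate-adjusted
estimates require individual-level covariates that are out of scope here.
Reported values are rounded to 2 decimals at the reporting layer only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ArgumentError, DataError
from .stats_core import ContingencyTable2x2, ORResult, woolf_or

logger = logging.getLogger(__name__)

STATUSES = ("case", "control")


def load_cohort(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a cohort CSV with at least (id, status) columns; status must be
    'case' or 'control'."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if "status" not in df.columns:
        raise DataError("cohort table must have a 'status' column")
    bad = set(df["status"].astype(str)) - set(STATUSES)
    if bad:
        raise DataError(f"unknown status values {sorted(bad)}")
    return df


def tabulate(
    records: pd.DataFrame,
    exposure_field: str,
    exposed_level: str,
    reference_level: str,
) -> ContingencyTable2x2:
    """Count records into a 2x2 exposure-by-status table.

    Records whose exposure value is neither level are excluded.
    """
    if exposure_field not in records.columns:
        raise DataError(f"exposure field {exposure_field!r} missing from cohort")
    exp = records[exposure_field].astype(str)
    status = records["status"].astype(str)
    return ContingencyTable2x2(
        exposed_cases=int(((exp == str(exposed_level)) & (status == "case")).sum()),
        exposed_controls=int(
            ((exp == str(exposed_level)) & (status == "control")).sum()
        ),
        unexposed_cases=int(
            ((exp == str(reference_level)) & (status == "case")).sum()
        ),
        unexposed_controls=int(
            ((exp == str(reference_level)) & (status == "control")).sum()
        ),
    )


def format_or(result: ORResult) -> str:
    return (
        f"{result.odds_ratio:.2f} "
        f"({result.ci_low:.2f}, {result.ci_high:.2f})"
    )


def or_table(
    records: pd.DataFrame,
    spec: Sequence[tuple[str, str, str]],
) -> pd.DataFrame:
    """One crude-OR row per (exposure_field, exposed_level, reference_level).

    Each exposed row is preceded by its reference-level row reported as
    OR 1.00 (the table convention for the baseline category).
    """
    rows = []
    for exposure_field, exposed_level, reference_level in spec:
        table = tabulate(records, exposure_field, exposed_level, reference_level)
        res = woolf_or(table)
        rows.append(
            {
                "exposure_field": exposure_field,
                "level": reference_level,
                "cases": table.unexposed_cases,
                "controls": table.unexposed_controls,
                "odds_ratio": 1.0,
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "report": "1.00",
                "corrected": False,
            }
        )
        rows.append(
            {
                "exposure_field": exposure_field,
                "level": exposed_level,
                "cases": table.exposed_cases,
                "controls": table.exposed_controls,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "report": format_or(res),
                "corrected": res.corrected,
            }
        )
    return pd.DataFrame(rows)


def stratified_or(
    records: pd.DataFrame,
    stratum_field: str,
    exposure_field: str,
    exposed_level: str = "yes",
    reference_level: str = "no",
) -> pd.DataFrame:
    """Crude exposure ORs within each case stratum against all controls.

    For each level of ``stratum_field`` among cases, a 2x2 table of exposure
    vs (stratum cases, all controls) is formed.  Strata with no case records
    are skipped with a warning.  Crude only: published stratified tables
    often print covariate-adjusted values, which are not reproduced.
    """
    if stratum_field not in records.columns:
        raise DataError(f"stratum field {stratum_field!r} missing from cohort")
    cases = records[records["status"].astype(str) == "case"]
    controls = records[records["status"].astype(str) == "control"]
    rows = []
    for level in sorted(cases[stratum_field].astype(str).unique()):
        sub_cases = cases[cases[stratum_field].astype(str) == level]
        if sub_cases.empty:
            logger.warning("stratum %r has no case records; skipped", level)
            continue
        sub = pd.concat([sub_cases, controls])
        table = tabulate(sub, exposure_field, exposed_level, reference_level)
        res = woolf_or(table)
        rows.append(
            {
                "stratum": level,
                "exposed_cases": table.exposed_cases,
                "exposed_controls": table.exposed_controls,
                "unexposed_cases": table.unexposed_cases,
                "unexposed_controls": table.unexposed_controls,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "report": format_or(res),
                "corrected": res.corrected,
            }
        )
    return pd.DataFrame(rows)


def expand_counts(table: ContingencyTable2x2, exposure_field: str = "exposure") -> pd.DataFrame:
    """Reconstruct a record-level cohort from a pre-tabulated 2x2 table, so
    printed table counts can be fed through the same tabulate->OR path."""
    rows = []
    spec = [
        ("case", "yes", table.exposed_cases),
        ("control", "yes", table.exposed_controls),
        ("case", "no", table.unexposed_cases),
        ("control", "no", table.unexposed_controls),
    ]
    i = 0
    for status, exposure, n in spec:
        for _ in range(n):
            rows.append({"id": f"r{i:05d}", "status": status, exposure_field: exposure})
            i += 1
    return pd.DataFrame(rows, columns=["id", "status", exposure_field])
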