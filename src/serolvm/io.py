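"""Cohort table readers and writers.

The on-disk format is a delimited text file with a one-line header.
Mandatory columns: id, group (MDD/HC), age (years), dose (μg/kg),
scanner (HRRT/GE), bp_neostriatum, bp_hippocampus, bp_amygdala,
bp_prefrontal (BP_ND, unitless), testosterone (nM), estradiol (nM;
stored at the LOQ when censored), estradiol_censored (0/1). Optional:
hamd_1..hamd_17 (may be blank for controls). Unknown extra columns are
preserved. Delimiter is sniffed from the extension (.tsv → tab,
otherwise comma).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import (
    BP_COLUMNS,
    GROUP_HC,
    GROUP_MDD,
    MANDATORY_COLUMNS,
    SCANNER_GE,
    SCANNER_HRRT,
)

__all__ = ["read_cohort", "write_cohort"]

log = logging.getLogger("serolvm")


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table; censor flag as 0/1, NaN as empty field."""
    df = table.copy()
    if "estradiol_censored" in df:
        df["estradiol_censored"] = df["estradiol_censored"].astype(int)
    df.to_csv(path, sep=_sep(path), index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Row-level validation problems are collected and reported together
    in a single error; unknown columns pass through with a log line.
    """
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory columns: {missing}")

    known = set(MANDATORY_COLUMNS) | {f"hamd_{i}" for i in range(1, 18)} \
        | {"estradiol_true"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.info("passing through %d unknown columns: %s", len(extra), extra)

    errors = []
    for col in BP_COLUMNS + ("age", "dose", "testosterone", "estradiol"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            errors.append(f"non-numeric {col} in rows {list(df.index[bad])}")
        df[col] = vals
    for col in BP_COLUMNS:
        if not np.isfinite(df[col].dropna()).all():
            errors.append(f"non-finite {col}")
    bad_grp = ~df["group"].isin([GROUP_MDD, GROUP_HC])
    if bad_grp.any():
        errors.append(f"group not in {{MDD, HC}} in rows {list(df.index[bad_grp])}")
    bad_sc = ~df["scanner"].isin([SCANNER_HRRT, SCANNER_GE])
    if bad_sc.any():
        errors.append(f"scanner not in {{HRRT, GE}} in rows {list(df.index[bad_sc])}")
    flag = pd.to_numeric(df["estradiol_censored"], errors="coerce")
    if not flag.isin([0, 1]).all():
        bad = list(df.index[~flag.isin([0, 1])])
        errors.append(f"estradiol_censored not in {{0,1}} in rows {bad}")
    else:
        df["estradiol_censored"] = flag.astype(int)
    if (pd.to_numeric(df["testosterone"], errors="coerce") < 0).any():
        errors.append("negative testosterone values")
    if errors:
        raise ValueError("invalid cohort file:\n  " + "\n  ".join(errors))
    return df
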