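"""Cohort assembly: the exclusion cascade, covariate preparation, descriptives.

The analytical sample is formed by a fixed sequential exclusion cascade —
(1) records missing the BMI z-score outcome, (2) records failing the
accelerometer wear-validity screen, (3) records missing the area-deprivation
(EIMD) decile — with per-stage counts recorded so the roster arithmetic
N_roster = N_retained + sum(stage counts) always holds.

Ages are group-mean centred within school to aid interpretation and reduce
collinearity with school-level covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_LABELS

__all__ = [
    "COHORT_COLUMNS",
    "exclusion_cascade",
    "center_age_by_group",
    "describe_cohort",
]

#: Expected covariate columns of a cohort frame (band columns come from
#: :data:`bandcoda.bands.BAND_LABELS`).
COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "school",
    "school_type",
    "eimd_decile",
    "accel_model",
    "sampling_freq",
    "bmi_z",
    "wear_ok",
]

CASCADE_STAGES = ("missing_outcome", "wear_criteria", "missing_ses")


def exclusion_cascade(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the sequential exclusion cascade and count removals per stage.

    Stages, in order: missing ``bmi_z`` outcome, failed wear screening
    (``wear_ok`` falsy), missing ``eimd_decile``.  The order matters — each
    stage counts only records surviving the previous ones.

    Returns
    -------
    (retained, report)
        ``retained`` is the analytical sample; ``report`` maps stage names to
        removal counts plus ``n_roster`` and ``n_retained``.
    """
    df = records
    n_roster = len(df)
    counts = {}

    stage1 = df["bmi_z"].notna()
    counts["missing_outcome"] = int((~stage1).sum())
    df = df[stage1]

    stage2 = df["wear_ok"].astype(bool)
    counts["wear_criteria"] = int((~stage2).sum())
    df = df[stage2]

    stage3 = df["eimd_decile"].notna()
    counts["missing_ses"] = int((~stage3).sum())
    df = df[stage3]

    report = {"n_roster": n_roster, **counts, "n_retained": len(df)}
    return df.reset_index(drop=True), report


def center_age_by_group(records: pd.DataFrame, group: str = "school") -> pd.DataFrame:
    """Add ``age_centred`` = age minus the group (school) mean age."""
    if records[group].isna().any():
        raise ValueError("every record needs a group for group-mean centering")
    out = records.copy()
    out["age_centred"] = out["age"] - out.groupby(group)["age"].transform("mean")
    return out


def describe_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: M (SD) for continuous fields, % for categoricals,
    overall and by sex."""

    def column(df: pd.DataFrame) -> dict:
        n = len(df)
        out = {"n": float(n)}
        for c in ("age", "bmi_z"):
            if c in df and n:
                out[f"{c}_mean"] = df[c].mean()
                out[f"{c}_sd"] = df[c].std(ddof=1)
        if n:
            out["girls_pct"] = 100.0 * (df["sex"] == "girl").mean()
            out["primary_pct"] = 100.0 * (df["school_type"] == "primary").mean()
            if "eimd_decile" in df:
                out["eimd_1_5_pct"] = 100.0 * (df["eimd_decile"] <= 5).mean()
        for band in BAND_LABELS:
            if band in df and n:
                out[f"band_{band}_mean"] = df[band].mean()
        return out

    table = {"all": column(records)}
    for sex in ("boy", "girl"):
        table[sex] = column(records[records["sex"] == sex])
    return pd.DataFrame(table)
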