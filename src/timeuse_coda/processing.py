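"""Turn day-level activity-monitor records into analysis-ready participants.

Input is a day-level table from a continuously worn thigh inclinometer
protocol (one row per participant-day) and a participant-level table with
covariates and glucose outcomes. This module applies the wear-validity
rules, derives sleep by subtraction, averages valid days into one closed
1440-minute composition per participant, assigns the HbA1c-based diabetes
risk group, and runs the exclusion cascade, keeping an auditable ledger.

Day-level CSV schema (empty field = missing):
    participant_id, day_index, sit_min, stand_min, step_min, nonwear_min,
    diary_sleep_available (0/1), waking_window_min, wear_during_waking_min

Participant-level CSV schema:
    participant_id, hba1c_mmol_mol, fpg_mmol_l, plg2h_mmol_l,
    known_diabetes (0/1), pregnant (0/1), age, menopausal_status,
    education, income, smoking, depression (0/1), diet_quality,
    energy_intake, alcohol, calcium
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import DAY_MINUTES, PARTS, close

#: Default HbA1c threshold (mmol/mol) splitting lower from higher diabetes risk.
HBA1C_THRESHOLD: float = 39.0

#: Fraction of the diary waking window the monitor must be worn for a valid day.
MIN_WAKING_WEAR_FRACTION: float = 0.80

#: Minimum total wear (minutes) for a valid day when the diary is missing.
MIN_WEAR_NO_DIARY_MIN: float = 600.0

#: Minimum number of valid days for a participant to enter the analysis.
MIN_VALID_DAYS: int = 4

COVARIATE_COLUMNS: tuple[str, ...] = (
    "age",
    "menopausal_status",
    "education",
    "income",
    "smoking",
    "depression",
    "diet_quality",
    "energy_intake",
    "alcohol",
    "calcium",
)

DAY_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "day_index",
    "sit_min",
    "stand_min",
    "step_min",
    "nonwear_min",
    "diary_sleep_available",
    "waking_window_min",
    "wear_during_waking_min",
)

OUTCOME_COLUMNS: dict[str, str] = {"fpg": "fpg_mmol_l", "2hplg": "plg2h_mmol_l"}


class MalformedDayError(ValueError):
    """A day record whose minute fields cannot form a 24-h day."""


@dataclass(frozen=True)
class InsufficientValidDays:
    """Typed exclusion signal: fewer than the required valid wear days."""

    participant_id: object
    n_valid: int


def derive_sleep_minutes(days: pd.DataFrame) -> pd.Series:
    """Sleep deduced by subtracting waking behaviours and non-wear from 24 h."""
    sleep = (
        DAY_MINUTES
        - days["sit_min"]
        - days["stand_min"]
        - days["step_min"]
        - days["nonwear_min"]
    )
    if (sleep < -1e-9).any():
        bad = days.loc[sleep < -1e-9].iloc[0]
        raise MalformedDayError(
            "behaviour + non-wear minutes exceed 1440 for participant "
            f"{bad['participant_id']!r} day {bad['day_index']!r}"
        )
    return sleep.clip(lower=0.0)


def is_valid_day(days: pd.DataFrame) -> pd.Series:
    """Wear-validity flag per day.

    With a sleep/wake diary a day is invalid when wear during the waking
    window is below 80% of that window; without a diary, when total wear is
    below 10 h. Both cut-offs are strict "less than", so a day exactly on
    the boundary is valid.
    """
    diary = days["diary_sleep_available"].astype(float) > 0
    total_wear = DAY_MINUTES - days["nonwear_min"]
    with_diary = (
        days["wear_during_waking_min"]
        >= MIN_WAKING_WEAR_FRACTION * days["waking_window_min"]
    )
    without_diary = total_wear >= MIN_WEAR_NO_DIARY_MIN
    return (diary & with_diary.fillna(False)) | (~diary & without_diary)


def average_participant(days: pd.DataFrame):
    """Average one participant's valid days into a closed 1440-min composition.

    Returns the composition as a length-4 array in canonical part order, or
    an :class:`InsufficientValidDays` signal when fewer than four days are
    valid (an exclusion, not an error).
    """
    pid = days["participant_id"].iloc[0]
    if (days["participant_id"] != pid).any():
        raise ValueError("average_participant expects days from one participant")
    valid = days.loc[is_valid_day(days)].copy()
    if len(valid) < MIN_VALID_DAYS:
        return InsufficientValidDays(pid, len(valid))
    valid["sleep_min"] = derive_sleep_minutes(valid)
    means = valid[["sit_min", "stand_min", "step_min", "sleep_min"]].mean(axis=0)
    return close(means.to_numpy())


def summarise_days(days: pd.DataFrame) -> pd.DataFrame:
    """Per-participant valid-day counts and averaged compositions.

    Participants below the valid-day minimum keep NaN composition columns.
    """
    records = []
    for pid, grp in days.groupby("participant_id", sort=True):
        result = average_participant(grp)
        if isinstance(result, InsufficientValidDays):
            records.append(
                {
                    "participant_id": pid,
                    "n_valid_days": result.n_valid,
                    **{p: np.nan for p in PARTS},
                }
            )
        else:
            records.append(
                {
                    "participant_id": pid,
                    "n_valid_days": int(is_valid_day(grp).sum()),
                    **dict(zip(PARTS, result)),
                }
            )
    return pd.DataFrame.from_records(records)


def assign_risk_group(hba1c, threshold: float = HBA1C_THRESHOLD) -> np.ndarray:
    """Diabetes risk group from HbA1c (mmol/mol): 'higher' iff ≥ threshold."""
    hba1c = np.asarray(hba1c, dtype=float)
    return np.where(hba1c >= threshold, "higher", "lower")


def apply_exclusions(
    participants: pd.DataFrame,
    covariates: tuple[str, ...] = COVARIATE_COLUMNS,
):
    """Run the exclusion cascade and return (analysis set, ledger).

    Removed in order: insufficient valid wear days, known diabetes,
    pregnancy, missing covariates. Missing FPG / 2-h post-load glucose are
    *flagged* per outcome (the participant stays in the other outcome's
    analysis set), matching per-outcome analysis samples.

    ``participants`` must already carry the composition columns (NaN when
    the participant had too few valid days) and an ``n_valid_days`` column.
    """
    df = participants.copy()
    ledger: dict[str, int] = {"n_input": len(df)}

    insufficient = df[list(PARTS)].isna().any(axis=1) | (
        df["n_valid_days"] < MIN_VALID_DAYS
    )
    ledger["insufficient_valid_days"] = int(insufficient.sum())
    df = df.loc[~insufficient]

    diabetes = df["known_diabetes"].astype(float) > 0
    ledger["known_diabetes"] = int(diabetes.sum())
    df = df.loc[~diabetes]

    pregnant = df["pregnant"].astype(float) > 0
    ledger["pregnant"] = int(pregnant.sum())
    df = df.loc[~pregnant]

    missing_cov = df[list(covariates)].isna().any(axis=1)
    ledger["missing_covariates"] = int(missing_cov.sum())
    df = df.loc[~missing_cov].copy()

    ledger["n_analysis"] = len(df)
    for outcome, col in OUTCOME_COLUMNS.items():
        missing = df[col].isna()
        ledger[f"missing_{outcome}"] = int(missing.sum())
        ledger[f"n_{outcome}"] = int((~missing).sum())

    if "risk_group" not in df.columns:
        df["risk_group"] = assign_risk_group(df["hba1c_mmol_mol"])
    return df.reset_index(drop=True), ledger


def build_analysis_table(
    days: pd.DataFrame,
    participants: pd.DataFrame,
    threshold: float = HBA1C_THRESHOLD,
    covariates: tuple[str, ...] = COVARIATE_COLUMNS,
):
    """Full processing pass: days + participants -> (analysis table, ledger)."""
    comps = summarise_days(days)
    merged = participants.merge(comps, on="participant_id", how="left")
    # participants with no day records at all count as zero valid days
    merged["n_valid_days"] = merged["n_valid_days"].fillna(0).astype(int)
    merged["risk_group"] = assign_risk_group(merged["hba1c_mmol_mol"], threshold)
    return apply_exclusions(merged, covariates)
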