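import numpy as np
import pandas as pd
import pytest

from timeuse_coda.cohort import GeneratorConfig, generate_participants
from timeuse_coda.processing import assign_risk_group


def make_day(pid, day, sit=520.0, stand=290.0, step=120.0, nonwear=0.0,
             diary=1, waking=None, wear=None):
    """One well-formed day record; waking window defaults to 24 h minus the
    implied sleep, wear defaults to the full waking window minus non-wear."""
    if waking is None:
        sleep = 1440.0 - sit - stand - step - nonwear
        waking = 1440.0 - sleep
    if wear is None:
        wear = waking - nonwear
    return {
        "participant_id": pid,
        "day_index": day,
        "sit_min": sit,
        "stand_min": stand,
        "step_min": step,
        "nonwear_min": nonwear,
        "diary_sleep_available": diary,
        "waking_window_min": waking if diary else np.nan,
        "wear_during_waking_min": wear if diary else np.nan,
    }


def make_participant(pid, hba1c=36.0, fpg=5.2, plg2h=5.4, diabetes=0,
                     pregnant=0, **overrides):
    row = {
        "participant_id": pid,
        "hba1c_mmol_mol": hba1c,
        "fpg_mmol_l": fpg,
        "plg2h_mmol_l": plg2h,
        "known_diabetes": diabetes,
        "pregnant": pregnant,
        "age": 55.0,
        "menopausal_status": "male",
        "education": "technical",
        "income": "mid",
        "smoking": "non",
        "depression": 0,
        "diet_quality": 66.0,
        "energy_intake": 1.7,
        "alcohol": 12.0,
        "calcium": 0.9,
    }
    row.update(overrides)
    return row


@pytest.fixture
def exclusion_fixture():
    """12-participant cohort with exactly one participant per exclusion
    reason plus one per missing-outcome flag; designed ledger counts are
    returned alongside the tables."""
    days = []
    for pid in [f"F{i:02d}" for i in range(1, 13)]:
        n_invalid = 4 if pid == "F01" else 0
        for d in range(7):
            if d < n_invalid:
                days.append(make_day(pid, d, sit=340.0, nonwear=300.0))
            else:
                days.append(make_day(pid, d))
    participants = [
        make_participant("F01"),                      # too few valid days
        make_participant("F02", diabetes=1),
        make_participant("F03", pregnant=1, hba1c=41.0),
        make_participant("F04", age=np.nan),          # missing covariate
        make_participant("F05", fpg=np.nan),          # flagged, kept for 2hPLG
        make_participant("F06", plg2h=np.nan, hba1c=41.0),
        *[make_participant(f"F{i:02d}", hba1c=36.0 if i % 2 else 41.0)
          for i in range(7, 13)],
    ]
    expected_ledger = {
        "n_input": 12,
        "insufficient_valid_days": 1,
        "known_diabetes": 1,
        "pregnant": 1,
        "missing_covariates": 1,
        "n_analysis": 8,
        "missing_fpg": 1,
        "n_fpg": 7,
        "missing_2hplg": 1,
        "n_2hplg": 7,
    }
    return pd.DataFrame(days), pd.DataFrame(participants), expected_ledger


@pytest.fixture(scope="session")
def analysis_df():
    """Mid-sized synthetic participant table with known generating truth,
    shaped like the post-processing analysis set."""
    cfg = GeneratorConfig(
        n_lower=160, n_higher=120,
        p_missing_covariate=0.0, p_missing_fpg=0.0, p_missing_2hplg=0.0,
    )
    df, truth = generate_participants(cfg, seed=20260919)
    df["risk_group"] = assign_risk_group(df["hba1c_mmol_mol"])
    return df, truth


def random_compositions(rng, n, total=1440.0, spread=1.0):
    """Strictly positive random compositions via logistic-normal draws."""
    from timeuse_coda.composition import ilr_inverse

    z = rng.normal(scale=spread, size=(n, 3))
    return ilr_inverse(z, "sit", total)
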