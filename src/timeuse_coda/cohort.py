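"""Synthetic cohort generator with known ground truth.

The real accelerometer subsample behind this analysis is not publicly
deposited, so every stage of the pipeline is exercised on synthetic cohorts
that emulate its statistical structure:

* two HbA1c-defined diabetes risk groups (default 376 lower / 272 higher);
* person-level 24-h compositions drawn logistic-normal — multivariate normal
  ilr coordinates around each group's compositional centre (defaults are the
  published group geometric means);
* day-level records (7-day continuous-wear protocol) perturbed around the
  person composition by ilr day noise, with diary-missing days, invalid
  low-wear days, and a small stratum of chronically low-wear participants so
  the validity and exclusion rules have work to do;
* log-normal glucose outcomes generated from the same linear model the
  analysis fits: ln(glucose) = group mean level + a'·clr(composition) +
  covariate effect + noise, where the zero-sum clr coefficient vector `a` is
  chosen so that the pivot-coordinate coefficient for each behaviour equals
  a configurable per-behaviour truth (beta1_P = sqrt(4/3)·a_P);
* covariates drawn from simple documented distributions matched to the
  cohort's published characteristics table.

Every generating parameter is returned in a truth record so parameter
recovery is testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .composition import DAY_MINUTES, PARTS, close, ilr_inverse, ilr_pivot, pivot_basis

PIVOT_SCALE = np.sqrt(4.0 / 3.0)  # beta1_P = PIVOT_SCALE * a_P (clr scale)

#: Published geometric-mean compositions (minutes within 1440) per risk group.
DEFAULT_CENTRE_LOWER = (526.4, 287.1, 120.6, 505.8)
DEFAULT_CENTRE_HIGHER = (530.7, 288.5, 116.0, 504.8)

#: Per-behaviour pivot-coordinate truths (confounder-adjusted associations of
#: relative time in each behaviour with log glucose), by outcome and group.
DEFAULT_BETA_TRUTH = {
    "fpg": {
        "lower": {"sit": 0.04, "stand": 0.02, "step": -0.01, "sleep": -0.06},
        "higher": {"sit": 0.03, "stand": -0.07, "step": -0.03, "sleep": 0.07},
    },
    "2hplg": {
        "lower": {"sit": 0.00, "stand": 0.01, "step": -0.12, "sleep": 0.11},
        "higher": {"sit": 0.01, "stand": -0.05, "step": -0.13, "sleep": 0.17},
    },
}

#: Group mean glucose (mmol/L) and log-scale residual SD (≈ sd/mean).
DEFAULT_MEAN_GLUCOSE = {
    "fpg": {"lower": 5.2, "higher": 5.5},
    "2hplg": {"lower": 5.2, "higher": 6.0},
}
DEFAULT_SD_LOG = {
    "fpg": {"lower": 0.09, "higher": 0.15},
    "2hplg": {"lower": 0.24, "higher": 0.33},
}


class GeneratorConfigError(ValueError):
    pass


def _cov3(spec) -> np.ndarray:
    """Accept a scalar SD or a full 3x3 covariance."""
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return float(arr) ** 2 * np.eye(3)
    if arr.shape != (3, 3):
        raise GeneratorConfigError(f"covariance must be scalar SD or 3x3, got {arr.shape}")
    return arr


@dataclass
class GeneratorConfig:
    """Generating parameters for a synthetic cohort; defaults are the study
    conditions the generator emulates."""

    n_lower: int = 376
    n_higher: int = 272
    centre_lower: tuple = DEFAULT_CENTRE_LOWER
    centre_higher: tuple = DEFAULT_CENTRE_HIGHER
    #: between-person ilr covariance (scalar = SD per coordinate)
    ilr_person_cov: object = 0.25
    #: within-person day-to-day ilr covariance
    ilr_day_cov: object = 0.15
    beta_truth: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_BETA_TRUTH)))
    mean_glucose: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_MEAN_GLUCOSE)))
    outcome_sd_log: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_SD_LOG)))
    #: effect of one within-group SD of age on ln(glucose), per outcome
    covariate_effects: dict = field(
        default_factory=lambda: {"fpg": {"age_per_sd": 0.02}, "2hplg": {"age_per_sd": 0.03}}
    )
    hba1c_threshold: float = 39.0
    days_per_person: tuple = (7, 7)
    p_diary_missing: float = 0.15
    p_invalid_day: float = 0.08
    #: chronically low-wear participants (mostly <4 valid days)
    p_low_wear: float = 21 / 741
    p_invalid_day_low_wear: float = 0.75
    p_known_diabetes: float = 37 / 741
    p_pregnant: float = 2 / 741
    p_missing_covariate: float = 33 / 741
    p_missing_fpg: float = 1 / 648
    p_missing_2hplg: float = 8 / 648
    total: float = DAY_MINUTES

    def validate(self) -> None:
        if self.n_lower < 0 or self.n_higher < 0 or self.n_lower + self.n_higher == 0:
            raise GeneratorConfigError("need a positive number of participants")
        for c in (self.centre_lower, self.centre_higher):
            if len(c) != 4 or any(v <= 0 for v in c):
                raise GeneratorConfigError(f"centre must be 4 positive parts, got {c}")
        for p in (
            self.p_diary_missing, self.p_invalid_day, self.p_low_wear,
            self.p_invalid_day_low_wear, self.p_known_diabetes, self.p_pregnant,
            self.p_missing_covariate, self.p_missing_fpg, self.p_missing_2hplg,
        ):
            if not 0 <= p <= 1:
                raise GeneratorConfigError(f"probability {p} outside [0, 1]")
        lo, hi = self.days_per_person
        if not (1 <= lo <= hi):
            raise GeneratorConfigError(f"bad days_per_person range {self.days_per_person}")
        for cov in (self.ilr_person_cov, self.ilr_day_cov):
            m = _cov3(cov)
            if np.any(np.linalg.eigvalsh(m) < -1e-12):
                raise GeneratorConfigError("ilr covariance must be positive semi-definite")


def clr_coefficients(beta_by_part: dict[str, float]) -> np.ndarray:
    """Zero-sum clr coefficient vector realising per-behaviour pivot truths.

    With only three free ilr slopes the four per-behaviour coefficients
    cannot be independent: beta1_P = sqrt(4/3)·a_P with sum(a) = 0. The
    configured values are projected onto that constraint (centred), which
    absorbs rounding in the configured table.
    """
    a = np.array([beta_by_part[p] for p in PARTS]) / PIVOT_SCALE
    return a - a.mean()


def effective_beta(beta_by_part: dict[str, float]) -> dict[str, float]:
    """The pivot-coordinate truths actually realised after the zero-sum
    projection — the values parameter-recovery tests should target."""
    a = clr_coefficients(beta_by_part)
    return {p: float(PIVOT_SCALE * a[i]) for i, p in enumerate(PARTS)}


# --- covariate population (frequencies matched to the emulated cohort) -----

_COVARIATE_TABLES = {
    "lower": dict(
        age=(56.0, 9.8), p_women=0.527,
        menopause=(0.369, 0.187, 0.444),  # pre, peri, post among women
        education=(0.247, 0.489, 0.263),  # high_school, technical, bachelor_plus
        income=(0.059, 0.173, 0.242, 0.527),  # none, low, mid, high
        smoking=(0.556, 0.370, 0.074),  # non, ex, current
        p_depression=0.061, diet=(65.7, 12.4), energy=(1.7, 0.65),
        alcohol=(15.5, 19.1), calcium=(0.9, 0.3), hba1c_mean=36.0,
    ),
    "higher": dict(
        age=(60.2, 9.3), p_women=0.607,
        menopause=(0.170, 0.121, 0.709),
        education=(0.349, 0.426, 0.224),
        income=(0.062, 0.243, 0.261, 0.434),
        smoking=(0.577, 0.357, 0.066),
        p_depression=0.107, diet=(67.2, 12.6), energy=(1.7, 0.67),
        alcohol=(11.5, 15.3), calcium=(0.9, 0.3), hba1c_mean=41.0,
    ),
}

_EDU_LEVELS = ("high_school", "technical", "bachelor_plus")
_INCOME_LEVELS = ("none", "low", "mid", "high")
_SMOKE_LEVELS = ("non", "ex", "current")
_MENO_LEVELS = ("pre", "peri", "post")


def _gamma_from_mean_sd(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    return rng.gamma(shape, sd**2 / mean, size=size)


def _trunc_hba1c(rng, mean, threshold, group, size, sd=1.5):
    """HbA1c consistent with the group's side of the threshold."""
    if group == "lower":
        a, b = (20.0 - mean) / sd, (threshold - 1e-6 - mean) / sd
    else:
        a, b = (threshold - mean) / sd, (70.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _choice(rng, levels, probs, size):
    p = np.asarray(probs, dtype=float)
    return rng.choice(levels, size=size, p=p / p.sum())


def generate_participants(cfg: GeneratorConfig, seed=None):
    """Generate the participant-level table and the hidden truth record.

    Returns ``(participants, truth)``; the frame includes the latent person
    composition columns (sit/stand/step/sleep), which the pipeline drops
    when writing the participant CSV (compositions are recovered from the
    day-level records).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    frames = []
    truth_beta = {}
    basis = pivot_basis("sit")
    for group, n, centre in (
        ("lower", cfg.n_lower, cfg.centre_lower),
        ("higher", cfg.n_higher, cfg.centre_higher),
    ):
        tab = _COVARIATE_TABLES[group]
        centre = close(np.asarray(centre, float), cfg.total)
        z_centre = ilr_pivot(centre, basis)
        z = rng.multivariate_normal(z_centre, _cov3(cfg.ilr_person_cov), size=n)
        comp = ilr_inverse(z, basis, cfg.total)

        age = np.clip(rng.normal(*tab["age"], size=n), 36.0, 80.0)
        women = rng.random(n) < tab["p_women"]
        meno = np.where(
            women, _choice(rng, _MENO_LEVELS, tab["menopause"], n), "male"
        )
        df = pd.DataFrame(
            {
                "hba1c_mmol_mol": _trunc_hba1c(
                    rng, tab["hba1c_mean"], cfg.hba1c_threshold, group, n
                ),
                "age": age,
                "menopausal_status": meno,
                "education": _choice(rng, _EDU_LEVELS, tab["education"], n),
                "income": _choice(rng, _INCOME_LEVELS, tab["income"], n),
                "smoking": _choice(rng, _SMOKE_LEVELS, tab["smoking"], n),
                "depression": (rng.random(n) < tab["p_depression"]).astype(int),
                "diet_quality": rng.normal(*tab["diet"], size=n),
                "energy_intake": np.clip(rng.normal(*tab["energy"], size=n), 0.3, None),
                "alcohol": _gamma_from_mean_sd(rng, *tab["alcohol"], n),
                "calcium": np.clip(rng.normal(*tab["calcium"], size=n), 0.1, None),
                "known_diabetes": (rng.random(n) < cfg.p_known_diabetes).astype(int),
                "pregnant": (
                    women & (age < 46) & (rng.random(n) < cfg.p_pregnant / 0.1)
                ).astype(int),
                "risk_group_true": group,
            }
        )
        df[list(PARTS)] = comp

        clr_comp = np.log(comp) - np.log(comp).mean(axis=1, keepdims=True)
        clr_centre = np.log(centre) - np.log(centre).mean()
        age_std = (age - tab["age"][0]) / tab["age"][1]
        for outcome in ("fpg", "2hplg"):
            a = clr_coefficients(cfg.beta_truth[outcome][group])
            lin = (
                np.log(cfg.mean_glucose[outcome][group])
                + (clr_comp - clr_centre) @ a
                + cfg.covariate_effects[outcome].get("age_per_sd", 0.0) * age_std
            )
            y = np.exp(lin + rng.normal(0.0, cfg.outcome_sd_log[outcome][group], n))
            df[{"fpg": "fpg_mmol_l", "2hplg": "plg2h_mmol_l"}[outcome]] = y
            truth_beta.setdefault(outcome, {})[group] = {
                "clr": a.tolist(),
                "beta_pivot": effective_beta(cfg.beta_truth[outcome][group]),
            }
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "participant_id", [f"P{i:04d}" for i in range(len(out))])

    # missingness injected after generation so truth stays complete
    miss_cov = rng.random(len(out)) < cfg.p_missing_covariate
    numeric_covs = ["age", "diet_quality", "energy_intake", "alcohol", "calcium"]
    which = rng.integers(0, len(numeric_covs), size=len(out))
    for j, cov in enumerate(numeric_covs):
        out.loc[miss_cov & (which == j), cov] = np.nan
    out.loc[rng.random(len(out)) < cfg.p_missing_fpg, "fpg_mmol_l"] = np.nan
    out.loc[rng.random(len(out)) < cfg.p_missing_2hplg, "plg2h_mmol_l"] = np.nan

    truth = {
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
        "beta": truth_beta,
        "centre_lower": close(np.asarray(cfg.centre_lower, float), cfg.total).tolist(),
        "centre_higher": close(np.asarray(cfg.centre_higher, float), cfg.total).tolist(),
        "config": _config_dict(cfg),
    }
    return out, truth


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    for k in ("ilr_person_cov", "ilr_day_cov"):
        d[k] = np.asarray(d[k], dtype=float).tolist()
    return d


def generate_day_records(cfg: GeneratorConfig, participants: pd.DataFrame, seed=None):
    """Generate the day-level table for already-generated participants.

    Valid days are fully worn (no non-wear); invalid days are produced
    either by too little wear within the diary waking window (< 80%) or,
    when the diary is missing, by under 10 h of total wear. A small
    low-wear stratum gets a high invalid-day probability so some
    participants fall below four valid days.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    basis = pivot_basis("sit")
    n = len(participants)
    lo, hi = cfg.days_per_person
    n_days = rng.integers(lo, hi + 1, size=n)
    low_wear = rng.random(n) < cfg.p_low_wear

    rows = []
    comp_cols = participants[list(PARTS)].to_numpy()
    day_cov = _cov3(cfg.ilr_day_cov)
    for i in range(n):
        pid = participants["participant_id"].iloc[i]
        z_person = ilr_pivot(comp_cols[i], basis)
        p_invalid = cfg.p_invalid_day_low_wear if low_wear[i] else cfg.p_invalid_day
        for day in range(int(n_days[i])):
            z_day = z_person + rng.multivariate_normal(np.zeros(3), day_cov)
            comp = ilr_inverse(z_day, basis, cfg.total)
            sit, stand, step, sleep = comp
            waking = cfg.total - sleep
            diary = rng.random() >= cfg.p_diary_missing
            invalid = rng.random() < p_invalid
            if diary:
                if invalid:
                    f = rng.uniform(0.22, 0.55)  # wear fraction drops below 0.8
                    nonwear = f * waking
                    scale = 1.0 - f
                else:
                    nonwear, scale = 0.0, 1.0
                rows.append(
                    (pid, day, sit * scale, stand * scale, step * scale,
                     nonwear, 1, waking, waking - nonwear)
                )
            else:
                if invalid:
                    nonwear = rng.uniform(850.0, 1150.0)  # total wear < 10 h
                    scale = (cfg.total - nonwear) / cfg.total
                else:
                    nonwear, scale = 0.0, 1.0
                rows.append(
                    (pid, day, sit * scale, stand * scale, step * scale,
                     nonwear, 0, np.nan, np.nan)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "day_index", "sit_min", "stand_min", "step_min",
            "nonwear_min", "diary_sleep_available", "waking_window_min",
            "wear_during_waking_min",
        ],
    )


def write_cohort(
    cfg: GeneratorConfig, out_dir, seed=None
) -> dict[str, Path]:
    """Generate and write participants.csv, days.csv and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_part, s_days = ss.spawn(2)
    participants, truth = generate_participants(cfg, s_part)
    days = generate_day_records(cfg, participants, s_days)
    paths = {
        "participants": out_dir / "participants.csv",
        "days": out_dir / "days.csv",
        "truth": out_dir / "truth.json",
    }
    participants.drop(columns=[*PARTS, "risk_group_true"]).to_csv(
        paths["participants"], index=False, float_format="%.6f"
    )
    days.to_csv(paths["days"], index=False, float_format="%.6f")
    truth["seed"] = seed if seed is None else int(seed)
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
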