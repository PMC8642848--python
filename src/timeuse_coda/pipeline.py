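"""End-to-end pipeline: data -> processing -> group comparison -> regression
-> reallocation, emitting the analysis tables as CSV/JSON artifacts.

One root seed drives every random element (cohort simulation and the
bootstrap) through `numpy.random.SeedSequence` stream splitting, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GeneratorConfig, generate_day_records, generate_participants
from .composition import PARTS, geometric_mean_composition
from .groups import compare_groups
from .processing import COVARIATE_COLUMNS, OUTCOME_COLUMNS, build_analysis_table
from .reallocation import all_ordered_pairs, reallocation_grid
from .regression import behaviour_beta, fit_model, interaction_test, build_design, vif_screen

OUTCOMES = ("fpg", "2hplg")
SCOPES = ("overall", "lower", "higher")


class InputSchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "synthetic"  # or "files"
    participant_file: str | None = None
    day_file: str | None = None
    out_dir: str = "results/run"
    seed: int = 0
    n_boot: int = 2000
    hba1c_threshold: float = 39.0
    covariates: tuple = COVARIATE_COLUMNS
    minutes_table: float = 60.0
    grid_step: float = 5.0
    grid_max: float = 60.0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(**raw, generator=gen)
        cfg.generator.hba1c_threshold = cfg.hba1c_threshold
        return cfg


def _read_csv(path, required: set[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise InputSchemaError(
            f"{label} file {path}: missing column(s) {sorted(missing)} "
            f"(header is line 1)"
        )
    return df


def load_inputs(cfg: RunConfig):
    """Load or simulate the day- and participant-level tables."""
    if cfg.mode == "synthetic":
        ss = np.random.SeedSequence(cfg.seed)
        s_part, s_days, _ = ss.spawn(3)
        participants, truth = generate_participants(cfg.generator, s_part)
        days = generate_day_records(cfg.generator, participants, s_days)
        participants = participants.drop(columns=[*PARTS, "risk_group_true"])
        return participants, days, truth
    if cfg.mode != "files":
        raise InputSchemaError(f"unknown mode {cfg.mode!r}")
    days = _read_csv(
        cfg.day_file,
        {"participant_id", "day_index", "sit_min", "stand_min", "step_min",
         "nonwear_min", "diary_sleep_available"},
        "day-level",
    )
    participants = _read_csv(
        cfg.participant_file,
        {"participant_id", "hba1c_mmol_mol", "fpg_mmol_l", "plg2h_mmol_l",
         "known_diabetes", "pregnant"},
        "participant-level",
    )
    return participants, days, None


def table2(analysis: pd.DataFrame, n_boot: int, seed) -> tuple[pd.DataFrame, dict]:
    """Group geometric means, bootstrap percent differences, Hotelling test."""
    lower = analysis.loc[analysis.risk_group == "lower", list(PARTS)].to_numpy()
    higher = analysis.loc[analysis.risk_group == "higher", list(PARTS)].to_numpy()
    cmp = compare_groups(lower, higher, n_boot=n_boot, seed=seed)
    g_lo = geometric_mean_composition(lower)
    g_hi = geometric_mean_composition(higher)
    rows = []
    for i, part in enumerate(PARTS):
        est, lo, hi = cmp.per_part_percent_diff[part]
        rows.append(
            {
                "part": part,
                "gm_lower_min": g_lo[i],
                "gm_lower_pct": 100 * g_lo[i] / g_lo.sum(),
                "gm_higher_min": g_hi[i],
                "gm_higher_pct": 100 * g_hi[i] / g_hi.sum(),
                "percent_diff": est,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    meta = {
        "hotelling_statistic": cmp.hotelling_statistic,
        "hotelling_p": cmp.hotelling_p,
        "n_lower": len(lower),
        "n_higher": len(higher),
        "n_boot": n_boot,
    }
    return pd.DataFrame(rows), meta


def table3(analysis: pd.DataFrame, covariates) -> pd.DataFrame:
    """Per-behaviour associations with each log glucose outcome, unadjusted
    and covariate-adjusted, overall and per risk group, with the pooled
    group x ilr1 interaction p-value."""
    rows = []
    for outcome in OUTCOMES:
        for adjustment, covs in (("unadjusted", ()), ("adjusted", tuple(covariates))):
            for part in PARTS:
                p_int = interaction_test(analysis, outcome, part, covs)
                for scope in SCOPES:
                    fit = fit_model(analysis, outcome, part, covs, scope)
                    beta, lo, hi, p = behaviour_beta(fit)
                    rows.append(
                        {
                            "outcome": outcome,
                            "adjustment": adjustment,
                            "behaviour": part,
                            "scope": scope,
                            "n": fit.n_used,
                            "beta": beta,
                            "ci_low": lo,
                            "ci_high": hi,
                            "p_value": p,
                            "p_interaction": p_int,
                        }
                    )
    return pd.DataFrame(rows)


def table4_and_fig1(
    analysis: pd.DataFrame,
    covariates,
    minutes_table: float = 60.0,
    grid_step: float = 5.0,
    grid_max: float = 60.0,
):
    """Reallocation estimates per risk group and outcome.

    table4: all 12 ordered behaviour pairs at ``minutes_table`` minutes.
    fig1: dense signed grid for the three waking-behaviour pairs.
    """
    t4_rows, fig_rows = [], []
    fig_pairs = [("sit", "stand"), ("sit", "step"), ("stand", "step")]
    grid = np.arange(grid_step, grid_max + 1e-9, grid_step)
    for group in ("lower", "higher"):
        base = geometric_mean_composition(
            analysis.loc[analysis.risk_group == group, list(PARTS)].to_numpy()
        )
        for outcome in OUTCOMES:
            fit = fit_model(analysis, outcome, "sit", covariates, group)
            t4 = reallocation_grid(fit, base, all_ordered_pairs(), [minutes_table])
            t4.insert(0, "outcome", outcome)
            t4.insert(0, "group", group)
            t4_rows.append(t4)
            fg = reallocation_grid(
                fit,
                base,
                fig_pairs + [(b, a) for a, b in fig_pairs],
                grid,
            )
            fg.insert(0, "outcome", outcome)
            fg.insert(0, "group", group)
            fig_rows.append(fg)
    return pd.concat(t4_rows, ignore_index=True), pd.concat(fig_rows, ignore_index=True)


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; write the artifact bundle; return paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants, days, truth = load_inputs(cfg)
    if cfg.mode == "synthetic":
        participants.to_csv(out / "participants.csv", index=False, float_format="%.6f")
        days.to_csv(out / "days.csv", index=False, float_format="%.6f")
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    analysis, ledger = build_analysis_table(
        days, participants, cfg.hba1c_threshold, tuple(cfg.covariates)
    )

    ss = np.random.SeedSequence(cfg.seed)
    _, _, s_boot = ss.spawn(3)
    boot_seed = int(s_boot.generate_state(1)[0] % (2**31))
    t2, t2_meta = table2(analysis, cfg.n_boot, boot_seed)
    t3 = table3(analysis, cfg.covariates)
    t4, fig1 = table4_and_fig1(
        analysis, tuple(cfg.covariates), cfg.minutes_table, cfg.grid_step, cfg.grid_max
    )

    # collinearity audit of the adjusted overall design
    X = build_design(
        analysis.dropna(subset=[OUTCOME_COLUMNS["fpg"]]),
        "sit", tuple(cfg.covariates),
    )
    vifs, vif_flag = vif_screen(X)

    artifacts = {
        "table2": out / "table2.csv",
        "table3": out / "table3.csv",
        "table4": out / "table4.csv",
        "fig1_data": out / "fig1_data.csv",
        "exclusion_ledger": out / "exclusion_ledger.json",
        "run_log": out / "run_log.json",
    }
    t2.to_csv(artifacts["table2"], index=False, float_format="%.6f")
    t3.to_csv(artifacts["table3"], index=False, float_format="%.6f")
    t4.to_csv(artifacts["table4"], index=False, float_format="%.6f")
    fig1.to_csv(artifacts["fig1_data"], index=False, float_format="%.6f")
    artifacts["exclusion_ledger"].write_text(json.dumps(ledger, indent=2, sort_keys=True))
    run_log = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        # path fields are machine-local; everything that affects numbers stays
        "config": {
            k: v
            for k, v in _jsonable(asdict(cfg)).items()
            if k not in ("out_dir", "day_file", "participant_file")
        },
        "seed": cfg.seed,
        "bootstrap_seed": boot_seed,
        "group_comparison": t2_meta,
        "max_vif": max(vifs.values()),
        "vif_flagged": vif_flag,
        "exclusions": ledger,
    }
    artifacts["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return {k: str(v) for k, v in artifacts.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
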