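#!/usr/bin/env python
"""Process day records into the analysis set.

Applies the wear-validity rules (80% of the diary waking window, or 10 h
total wear without a diary), derives sleep by subtraction, averages valid
days into one closed 1440-min composition per participant, and runs the
exclusion cascade. Writes the analysis table and exclusion ledger under
results/processed/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from timeuse_coda.processing import build_analysis_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    days = pd.read_csv(args.results_dir / "data" / "days.csv")
    participants = pd.read_csv(args.results_dir / "data" / "participants.csv")
    analysis, ledger = build_analysis_table(days, participants)

    out = args.results_dir / "processed"
    out.mkdir(parents=True, exist_ok=True)
    analysis.to_csv(out / "analysis_table.csv", index=False, float_format="%.6f")
    (out / "exclusion_ledger.json").write_text(json.dumps(ledger, indent=2, sort_keys=True))

    print(f"{ledger['n_input']} participants in, {ledger['n_analysis']} analysable:")
    for reason in ("insufficient_valid_days", "known_diabetes", "pregnant",
                   "missing_covariates"):
        print(f"  excluded, {reason.replace('_', ' ')}: {ledger[reason]}")
    print(f"  missing FPG (flagged): {ledger['missing_fpg']}; "
          f"missing 2hPLG (flagged): {ledger['missing_2hplg']}")
    print(f"Per-outcome samples: FPG n={ledger['n_fpg']}, 2hPLG n={ledger['n_2hplg']}")


if __name__ == "__main__":
    main()
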