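"""Isotemporal reallocation: move minutes between behaviours and estimate the
percent change in glucose.

Starting from a base composition (typically a risk group's geometric mean),
a fixed number of minutes is moved from one behaviour to another with the
24-h total held constant. The fitted compositional model then gives the
change in expected log glucose as a linear contrast of the ilr coordinates:

    delta_log = (z_new - z_base) @ beta_ilr

Covariate terms cancel in the difference, so no representative covariate
values are needed. The standard error comes from the coefficient covariance
(sqrt(c' Sigma c)); the base composition is treated as fixed. CIs use
t(residual df) and are transformed endpoint-wise to the percent scale with
the exact back-transform 100*(exp(delta) - 1), which keeps the printed
asymmetry of intervals on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import PARTS, ilr_pivot
from .regression import ILR_NAMES, CompositionalFit


class InfeasibleReallocationError(ValueError):
    """A reallocation that would drive some behaviour to zero or below."""


@dataclass
class ReallocationResult:
    from_part: str
    to_part: str
    minutes: float
    delta_log: float
    se_log: float
    delta_percent: float
    ci_low_percent: float
    ci_high_percent: float


def reallocate(base, from_part: str, to_part: str, minutes: float) -> np.ndarray:
    """Move ``minutes`` from ``from_part`` to ``to_part``; total unchanged.

    Negative minutes move time in the opposite direction. The resulting
    composition must stay strictly positive.
    """
    if from_part == to_part:
        raise InfeasibleReallocationError("from_part and to_part must differ")
    for p in (from_part, to_part):
        if p not in PARTS:
            raise InfeasibleReallocationError(f"unknown part {p!r}")
    new = np.asarray(base, dtype=float).copy()
    new[PARTS.index(from_part)] -= minutes
    new[PARTS.index(to_part)] += minutes
    if np.any(new <= 0):
        bad = PARTS[int(np.argmin(new))]
        raise InfeasibleReallocationError(
            f"moving {minutes} min {from_part}->{to_part} leaves "
            f"'{bad}' non-positive"
        )
    return new


def estimate_delta(
    fit: CompositionalFit,
    base,
    new,
    from_part: str = "",
    to_part: str = "",
    minutes: float = np.nan,
    alpha: float = 0.05,
) -> ReallocationResult:
    """Estimated glucose change (percent) between two compositions under a fit.

    delta_log equals the difference of model predictions at ``new`` and
    ``base``; its variance is c' Sigma c with c the ilr-coordinate contrast.
    """
    z_base = ilr_pivot(base, fit.basis)
    z_new = ilr_pivot(new, fit.basis)
    c = z_new - z_base
    beta = fit.ilr_beta
    sigma = fit.cov_params.loc[list(ILR_NAMES), list(ILR_NAMES)].to_numpy()
    delta_log = float(c @ beta)
    se = float(np.sqrt(c @ sigma @ c))
    tq = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    lo, hi = delta_log - tq * se, delta_log + tq * se
    to_pct = lambda d: 100.0 * (np.exp(d) - 1.0)
    return ReallocationResult(
        from_part=from_part,
        to_part=to_part,
        minutes=minutes,
        delta_log=delta_log,
        se_log=se,
        delta_percent=to_pct(delta_log),
        ci_low_percent=to_pct(lo),
        ci_high_percent=to_pct(hi),
    )


def all_ordered_pairs() -> list[tuple[str, str]]:
    return [(a, b) for a in PARTS for b in PARTS if a != b]


def reallocation_grid(
    fit: CompositionalFit,
    base,
    pairs=None,
    minutes_grid=(15.0, 30.0, 45.0, 60.0),
) -> pd.DataFrame:
    """One ReallocationResult per (ordered pair, minutes), as a long table.

    Infeasible grid points (a part driven to zero) are recorded with NaN
    estimates rather than raising, so a dense curve grid can run past a
    small behaviour's feasibility limit.
    """
    if pairs is None:
        pairs = all_ordered_pairs()
    rows = []
    for from_part, to_part in pairs:
        for minutes in minutes_grid:
            try:
                new = reallocate(base, from_part, to_part, float(minutes))
            except InfeasibleReallocationError:
                rows.append(
                    {
                        "from_part": from_part,
                        "to_part": to_part,
                        "minutes": float(minutes),
                        "delta_log": np.nan,
                        "se_log": np.nan,
                        "delta_percent": np.nan,
                        "ci_low_percent": np.nan,
                        "ci_high_percent": np.nan,
                        "feasible": False,
                    }
                )
                continue
            r = estimate_delta(fit, base, new, from_part, to_part, float(minutes))
            rows.append(
                {
                    "from_part": r.from_part,
                    "to_part": r.to_part,
                    "minutes": r.minutes,
                    "delta_log": r.delta_log,
                    "se_log": r.se_log,
                    "delta_percent": r.delta_percent,
                    "ci_low_percent": r.ci_low_percent,
                    "ci_high_percent": r.ci_high_percent,
                    "feasible": True,
                }
            )
    return pd.DataFrame(rows)
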