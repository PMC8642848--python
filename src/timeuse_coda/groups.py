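"""Comparison of two risk groups' 24-h behaviour compositions.

Two complementary views:

* per-behaviour percentage differences between the groups' geometric-mean
  compositions, with percentile-bootstrap confidence intervals (participants
  resampled with replacement within each group); and
* an overall two-sample Hotelling T² test on the ilr coordinates, which is
  invariant to the choice of pivot reference.

The percentage difference for a part is 100*(exp(ln gB - ln gA) - 1) on the
*closed* group geometric means, i.e. the log-ratio of shares converted to
percent; a positive value means group B (by convention the higher-risk
group) spends relatively more of the day in that behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composition import (
    DAY_MINUTES,
    PARTS,
    geometric_mean_composition,
    ilr_pivot,
    pivot_basis,
)


class ConfigurationError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class GroupComparisonResult:
    per_part_percent_diff: dict[str, tuple[float, float, float]]
    hotelling_statistic: float
    hotelling_p: float
    n_boot: int
    seed: int | None


def _percent_diff(group_a: np.ndarray, group_b: np.ndarray, total: float) -> np.ndarray:
    ga = geometric_mean_composition(group_a, total)
    gb = geometric_mean_composition(group_b, total)
    return 100.0 * (np.exp(np.log(gb) - np.log(ga)) - 1.0)


def percent_diff_bootstrap(
    group_a,
    group_b,
    n_boot: int = 2000,
    seed: int | None = None,
    total: float = DAY_MINUTES,
) -> dict[str, tuple[float, float, float]]:
    """Per-part percent difference of geometric means (B vs A) with
    percentile-bootstrap 95% CIs.

    Returns ``{part: (estimate %, CI low %, CI high %)}``.
    """
    if n_boot < 200:
        raise ConfigurationError(f"n_boot must be >= 200, got {n_boot}")
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("both groups must be non-empty")
    est = _percent_diff(a, b, total)

    rng = np.random.default_rng(seed)
    # vectorised bootstrap: log-geometric means are plain means of logs
    la, lb = np.log(a), np.log(b)
    idx_a = rng.integers(0, len(a), size=(n_boot, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_boot, len(b)))
    ma = la[idx_a].mean(axis=1)  # (n_boot, 4) mean log parts
    mb = lb[idx_b].mean(axis=1)
    # closure in log space: subtract log of the exp-sum so shares are compared
    ma -= np.log(np.exp(ma).sum(axis=1, keepdims=True))
    mb -= np.log(np.exp(mb).sum(axis=1, keepdims=True))
    boot = 100.0 * (np.exp(mb - ma) - 1.0)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return {
        part: (float(est[i]), float(lo[i]), float(hi[i]))
        for i, part in enumerate(PARTS)
    }


def hotelling_ilr_test(group_a, group_b, reference_part: str = "sit"):
    """Two-sample Hotelling T² on the 3-d ilr coordinates.

    Pooled-covariance statistic with the exact F reference distribution
    F(p, n1 + n2 - p - 1). The result does not depend on ``reference_part``
    (orthonormal rotation of the coordinates).
    """
    basis = pivot_basis(reference_part)
    za = np.atleast_2d(ilr_pivot(group_a, basis))
    zb = np.atleast_2d(ilr_pivot(group_b, basis))
    n1, n2 = len(za), len(zb)
    p = za.shape[1]
    if min(n1, n2) <= p + 1:
        raise DegenerateDataError(
            f"each group needs more than {p + 1} observations for a {p}-d test"
        )
    diff = za.mean(axis=0) - zb.mean(axis=0)
    s_pooled = (
        (n1 - 1) * np.cov(za, rowvar=False) + (n2 - 1) * np.cov(zb, rowvar=False)
    ) / (n1 + n2 - 2)
    try:
        solve = np.linalg.solve(s_pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular pooled covariance: {exc}") from exc
    if np.linalg.cond(s_pooled) > 1e12:
        raise DegenerateDataError("pooled covariance is numerically singular")
    t2 = float(n1 * n2 / (n1 + n2) * diff @ solve)
    f_stat = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
    p_value = float(stats.f.sf(f_stat, p, n1 + n2 - p - 1))
    return t2, p_value


def compare_groups(
    group_a,
    group_b,
    n_boot: int = 2000,
    seed: int | None = None,
    total: float = DAY_MINUTES,
) -> GroupComparisonResult:
    """Full two-group comparison: bootstrap percent differences + Hotelling."""
    per_part = percent_diff_bootstrap(group_a, group_b, n_boot, seed, total)
    t2, p = hotelling_ilr_test(group_a, group_b)
    return GroupComparisonResult(per_part, t2, p, n_boot, seed)
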