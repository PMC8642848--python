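"""Compositional linear regression of log glucose on pivot ilr coordinates.

The model is ordinary least squares of the natural log of a glucose outcome
(fasting or 2-h post-load, mmol/L) on the three pivot ilr coordinates of the
24-h behaviour composition plus covariates:

    E[ln y | z] = b0 + b1*z1 + b2*z2 + b3*z3 + covariate effects

With the pivot reference set to behaviour P, b1 is interpreted as the
association of relative time in P (against the geometric mean of the other
three behaviours) with log glucose. Rotating the reference part is an
orthonormal change of basis, so fitted values, residuals and covariate
coefficients are identical across the four reference choices; only
(b1, b2, b3) rotate. Inference is Wald with t(residual df) quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .composition import PARTS, PivotBasis, ilr_pivot, pivot_basis
from .processing import OUTCOME_COLUMNS

ILR_NAMES = ("ilr1", "ilr2", "ilr3")

#: Fixed reference levels for categorical covariates (first level = the
#: reference). References are the majority levels, which keeps the treatment
#: dummies well conditioned (a rare reference level inflates dummy VIFs).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "menopausal_status": ("male", "pre", "peri", "post"),
    "education": ("technical", "high_school", "bachelor_plus"),
    "smoking": ("non", "ex", "current"),
    "income": ("high", "none", "low", "mid"),
}


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


@dataclass
class CompositionalFit:
    """OLS fit of log glucose on ilr coordinates (+ covariates)."""

    outcome: str
    group_scope: str
    basis: PivotBasis
    params: pd.Series
    cov_params: pd.DataFrame
    df_resid: float
    n_used: int
    covariates: tuple[str, ...]
    results: object = field(repr=False, default=None)

    @property
    def reference_part(self) -> str:
        return self.basis.reference_part

    @property
    def ilr_beta(self) -> np.ndarray:
        return self.params[list(ILR_NAMES)].to_numpy()

    def predict_log(self, compositions, covariate_row: pd.Series | None = None):
        """Predicted ln(outcome); covariate terms optional (they cancel in
        any difference of predictions over compositions)."""
        z = ilr_pivot(compositions, self.basis)
        pred = self.params["const"] + np.atleast_2d(z) @ self.ilr_beta
        if covariate_row is not None:
            extra = [c for c in self.params.index if c not in ("const", *ILR_NAMES)]
            pred = pred + float(covariate_row[extra] @ self.params[extra])
        return pred if np.asarray(compositions).ndim > 1 else float(pred[0])


def expand_covariates(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Expand covariates into numeric design columns.

    Categorical covariates become treatment-coded dummies against the fixed
    reference levels in :data:`CATEGORICAL_LEVELS`; everything else is cast
    to float (flags such as depression are 0/1).
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            cat = pd.Categorical(df[cov], categories=levels)
            if cat.isna().any() and not pd.isna(df[cov]).any():
                bad = sorted(set(df[cov]) - set(levels))
                raise ValueError(f"unknown {cov} level(s): {bad}")
            # levels absent from this (sub)sample are dropped; the first
            # observed level in the configured order is the reference
            observed = [lvl for lvl in levels if (cat == lvl).any()]
            for lvl in observed[1:]:
                cols[f"{cov}[{lvl}]"] = (cat == lvl).astype(float)
        else:
            cols[cov] = df[cov].astype(float).to_numpy()
    return pd.DataFrame(cols, index=df.index)


def build_design(
    df: pd.DataFrame,
    reference_part: str = "sit",
    covariates=(),
    group_interaction: bool = False,
    group_col: str = "risk_group",
) -> pd.DataFrame:
    """Design matrix: intercept, ilr coordinates, optional group x ilr terms,
    expanded covariates."""
    basis = (
        reference_part
        if isinstance(reference_part, PivotBasis)
        else pivot_basis(reference_part)
    )
    z = ilr_pivot(df[list(PARTS)].to_numpy(), basis)
    X = pd.DataFrame(z, columns=list(ILR_NAMES), index=df.index)
    if group_interaction:
        groups = df[group_col].unique()
        if len(groups) < 2:
            raise ValueError(
                f"group interaction requires both risk groups, found {groups}"
            )
        g = (df[group_col] == "higher").astype(float)
        X["group[higher]"] = g
        for name in ILR_NAMES:
            X[f"group[higher]:{name}"] = g * X[name]
    if covariates:
        X = pd.concat([X, expand_covariates(df, covariates)], axis=1)
    X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(np.asarray(X))
    if rank < X.shape[1]:
        vifs = vif_screen(X.drop(columns="const"), flag_threshold=np.inf)[0]
        dependent = [c for c, v in vifs.items() if not np.isfinite(v)]
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"linearly dependent columns: {dependent or 'intercept-related'}"
        )


def fit_model(
    df: pd.DataFrame,
    outcome: str,
    reference_part: str = "sit",
    covariates=(),
    group_scope: str = "overall",
) -> CompositionalFit:
    """Fit ln(outcome) ~ ilr1 + ilr2 + ilr3 + covariates by OLS.

    ``outcome`` is 'fpg' or '2hplg' (mapped to the schema column) or a raw
    positive column name. ``group_scope`` restricts to one risk group, or
    'overall' for the pooled sample.
    """
    col = OUTCOME_COLUMNS.get(outcome, outcome)
    sub = df if group_scope == "overall" else df.loc[df["risk_group"] == group_scope]
    sub = sub.loc[sub[col].notna()]
    if (sub[col] <= 0).any():
        raise ValueError(f"outcome {outcome!r} must be strictly positive")
    X = build_design(sub, reference_part, covariates)
    _check_rank(X)
    res = sm.OLS(np.log(sub[col].to_numpy()), X).fit()
    basis = (
        reference_part
        if isinstance(reference_part, PivotBasis)
        else pivot_basis(reference_part)
    )
    return CompositionalFit(
        outcome=outcome,
        group_scope=group_scope,
        basis=basis,
        params=res.params,
        cov_params=res.cov_params(),
        df_resid=res.df_resid,
        n_used=int(res.nobs),
        covariates=tuple(covariates),
        results=res,
    )


def behaviour_beta(fit: CompositionalFit, alpha: float = 0.05):
    """(b1, CI low, CI high, p) for the fit's reference behaviour, using
    t(residual df) Wald intervals."""
    beta = float(fit.params["ilr1"])
    se = float(np.sqrt(fit.cov_params.loc["ilr1", "ilr1"]))
    tq = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    p = 2 * stats.t.sf(abs(beta / se), fit.df_resid) if se > 0 else np.nan
    return beta, beta - tq * se, beta + tq * se, p


def fit_behaviour_family(
    df: pd.DataFrame,
    outcome: str,
    covariates=(),
    group_scope: str = "overall",
) -> dict[str, CompositionalFit]:
    """One fit per behaviour as pivot reference (same model, rotated basis)."""
    return {
        part: fit_model(df, outcome, part, covariates, group_scope)
        for part in PARTS
    }


def interaction_test(
    df: pd.DataFrame,
    outcome: str,
    reference_part: str = "sit",
    covariates=(),
    group_col: str = "risk_group",
) -> float:
    """Wald p-value for the risk-group x ilr1 interaction.

    Pooled model with a group main effect and group interactions with all
    three ilr coordinates; only the coefficient on group x ilr1 (the
    reference behaviour's coordinate) is examined.
    """
    col = OUTCOME_COLUMNS.get(outcome, outcome)
    sub = df.loc[df[col].notna()]
    X = build_design(sub, reference_part, covariates, group_interaction=True,
                     group_col=group_col)
    _check_rank(X)
    res = sm.OLS(np.log(sub[col].to_numpy()), X).fit()
    return float(res.pvalues["group[higher]:ilr1"])


def _covariate_pvalue(res, cov: str) -> float:
    """Wald p for one covariate; joint F test across a categorical's dummies."""
    if cov in CATEGORICAL_LEVELS:
        names = [f"{cov}[{lvl}]" for lvl in CATEGORICAL_LEVELS[cov][1:]]
        names = [n for n in names if n in res.params.index]
        r = np.zeros((len(names), len(res.params)))
        for i, n in enumerate(names):
            r[i, list(res.params.index).index(n)] = 1.0
        return float(res.f_test(r).pvalue)
    return float(res.pvalues[cov])


def backward_eliminate(
    df: pd.DataFrame,
    outcome: str,
    candidate_covariates,
    p_threshold: float = 0.2,
    forced_in=("smoking", "menopausal_status"),
    reference_part: str = "sit",
) -> list[str]:
    """Backward covariate elimination at p > ``p_threshold``.

    Repeatedly drops the non-forced covariate with the largest Wald p while
    that p exceeds the threshold; ``forced_in`` covariates are always kept
    (they are re-added to adjusted models regardless of significance).
    """
    candidates = list(candidate_covariates)
    forced = list(forced_in)
    if set(candidates) & set(forced):
        raise ValueError("candidates must be disjoint from forced_in")
    col = OUTCOME_COLUMNS.get(outcome, outcome)
    sub = df.loc[df[col].notna()]
    y = np.log(sub[col].to_numpy())
    while candidates:
        X = build_design(sub, reference_part, forced + candidates)
        res = sm.OLS(y, X).fit()
        pvals = {c: _covariate_pvalue(res, c) for c in candidates}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= p_threshold:
            break
        candidates.remove(worst)
    return forced + candidates


def vif_screen(X: pd.DataFrame, flag_threshold: float = 2.5):
    """Variance inflation factors: VIF_j = 1 / (1 - R²_j) regressing column j
    on the remaining columns (plus an intercept).

    Returns (``{column: VIF}``, flag) where flag is True when any VIF meets
    or exceeds ``flag_threshold``. Perfectly collinear columns report inf.
    """
    cols = [c for c in X.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least two non-constant columns")
    A = X[cols].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        yj = A[:, j]
        others = np.column_stack([np.delete(A, j, axis=1), np.ones(len(A))])
        resid = yj - others @ np.linalg.lstsq(others, yj, rcond=None)[0]
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    flagged = any(v >= flag_threshold for v in out.values())
    return out, flagged
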