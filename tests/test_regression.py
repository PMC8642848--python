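"""Compositional regression: rotation invariance, recovery, interactions,
covariate screening."""

import numpy as np
import pandas as pd
import pytest

from timeuse_coda.cohort import GeneratorConfig, generate_participants
from timeuse_coda.composition import PARTS, ilr_inverse
from timeuse_coda.processing import assign_risk_group
from timeuse_coda.regression import (
    CollinearityError,
    backward_eliminate,
    behaviour_beta,
    build_design,
    fit_behaviour_family,
    fit_model,
    interaction_test,
    vif_screen,
)

ADJUST = ("age", "menopausal_status", "education", "income", "smoking",
          "depression", "diet_quality", "energy_intake", "alcohol", "calcium")


def _null_frame(rng, n=300, beta=(0.0, 0.0, 0.0), group_split=True, noise=0.1,
                group_beta=None):
    """Participant-like frame with compositions and a log-normal outcome whose
    ilr coefficients are known exactly."""
    z = rng.normal(scale=0.3, size=(n, 3))
    comp = ilr_inverse(z, "sit")
    lin = np.log(5.3) + z @ np.asarray(beta, dtype=float)
    group = np.where(np.arange(n) % 2 == 0, "lower", "higher") if group_split \
        else np.array(["lower"] * n)
    if group_beta is not None:
        lin = lin + (group == "higher") * (z @ np.asarray(group_beta, float))
    y = np.exp(lin + rng.normal(scale=noise, size=n))
    df = pd.DataFrame(comp, columns=list(PARTS))
    df["fpg_mmol_l"] = y
    df["plg2h_mmol_l"] = y
    df["risk_group"] = group
    return df


class TestFitModel:
    def test_rotation_invariance_of_fit(self, analysis_df):
        df, _ = analysis_df
        fits = fit_behaviour_family(df, "fpg", covariates=("age",))
        fitted = {p: f.results.fittedvalues for p, f in fits.items()}
        base = fitted["sit"]
        for part in ("stand", "step", "sleep"):
            np.testing.assert_allclose(fitted[part], base, atol=1e-9)
        # covariate coefficient identical across rotations
        ages = [fits[p].params["age"] for p in PARTS]
        np.testing.assert_allclose(ages, ages[0], atol=1e-12)

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(12)
        beta = (0.08, -0.03, 0.05)
        df = _null_frame(rng, n=4000, beta=beta, noise=0.05)
        fit = fit_model(df, "fpg", "sit")
        np.testing.assert_allclose(fit.ilr_beta, beta, atol=0.01)

    def test_sign_flip_negates_beta(self, analysis_df):
        df, _ = analysis_df
        fit = fit_model(df, "fpg", "sit")
        flipped = df.copy()
        flipped["fpg_mmol_l"] = 1.0 / flipped["fpg_mmol_l"]  # ln flips sign
        fit2 = fit_model(flipped, "fpg", "sit")
        assert fit2.params["ilr1"] == pytest.approx(-fit.params["ilr1"], rel=1e-9)

    def test_clr_contrast_identity(self, analysis_df):
        """beta1 for part P is recoverable from any single fit: the clr
        coefficient vector is basis-independent."""
        df, _ = analysis_df
        fits = fit_behaviour_family(df, "2hplg")
        ref = fits["sit"]
        a = ref.basis.contrast @ ref.ilr_beta  # clr coefficients
        for i, part in enumerate(PARTS):
            assert fits[part].params["ilr1"] == pytest.approx(
                np.sqrt(4.0 / 3.0) * a[i], abs=1e-10
            )

    def test_duplicated_column_raises_collinearity(self, analysis_df):
        df, _ = analysis_df
        df = df.copy()
        df["age_copy"] = df["age"]
        with pytest.raises(CollinearityError, match="age"):
            fit_model(df, "fpg", "sit", covariates=("age", "age_copy"))

    def test_residual_df_accounting(self, analysis_df):
        df, _ = analysis_df
        fit = fit_model(df, "fpg", "sit", covariates=("age", "smoking"))
        p = 1 + 3 + 1 + 2  # const, ilr, age, smoking dummies
        assert fit.df_resid == fit.n_used - p

    def test_behaviour_beta_wald_interval(self, analysis_df):
        df, _ = analysis_df
        fit = fit_model(df, "fpg", "step")
        beta, lo, hi, p = behaviour_beta(fit)
        assert lo < beta < hi
        se = np.sqrt(fit.cov_params.loc["ilr1", "ilr1"])
        from scipy import stats
        tq = stats.t.ppf(0.975, fit.df_resid)
        assert hi - beta == pytest.approx(tq * se, rel=1e-12)


class TestInteraction:
    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        df = _null_frame(rng, group_split=False)
        with pytest.raises(ValueError, match="both risk groups"):
            interaction_test(df, "fpg", "sit")

    def test_row_duplication_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(2)
        df = _null_frame(rng, beta=(0.1, 0.0, 0.0),
                         group_beta=(-0.15, 0.0, 0.0))
        import statsmodels.api as sm
        from timeuse_coda.regression import build_design

        def coef(d):
            X = build_design(d, "sit", group_interaction=True)
            res = sm.OLS(np.log(d["fpg_mmol_l"].to_numpy()), X).fit()
            return res.params["group[higher]:ilr1"]

        assert coef(pd.concat([df, df], ignore_index=True)) == \
            pytest.approx(coef(df), rel=1e-9)

    def test_power_for_opposite_sign_effects(self):
        """Opposite-sign standing effects by group (as in the generating
        table: +0.02 vs −0.07) should be detected in most replicates at the
        study's sample size."""
        cfg = GeneratorConfig(
            n_lower=376, n_higher=272,
            p_missing_covariate=0.0, p_missing_fpg=0.0, p_missing_2hplg=0.0,
        )
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            df, _ = generate_participants(cfg, rng)
            df["risk_group"] = assign_risk_group(df["hba1c_mmol_mol"])
            p = interaction_test(df, "fpg", "stand", covariates=("age",))
            rejections += p < 0.05
        assert rejections / n_rep > 0.5


class TestBackwardElimination:
    def test_strong_candidates_all_retained(self):
        rng = np.random.default_rng(3)
        df = _null_frame(rng, n=500, noise=0.05)
        df["x1"] = rng.normal(size=500)
        df["x2"] = rng.normal(size=500)
        df["fpg_mmol_l"] *= np.exp(0.2 * df["x1"] + 0.2 * df["x2"])
        kept = backward_eliminate(df, "fpg", ["x1", "x2"], forced_in=())
        assert set(kept) == {"x1", "x2"}

    def test_noise_candidate_removed_in_most_replicates(self):
        # a pure-noise covariate survives the p > 0.2 rule by chance ~20% of
        # the time, so judge over replicates
        rng = np.random.default_rng(4)
        removed = 0
        for _ in range(25):
            df = _null_frame(rng, n=500, noise=0.05)
            df["signal"] = rng.normal(size=500)
            df["noise"] = rng.normal(size=500)
            df["fpg_mmol_l"] *= np.exp(0.3 * df["signal"])
            kept = backward_eliminate(df, "fpg", ["signal", "noise"], forced_in=())
            assert "signal" in kept
            removed += "noise" not in kept
        assert removed >= 15

    def test_forced_in_noise_retained(self):
        rng = np.random.default_rng(5)
        df = _null_frame(rng, n=400, noise=0.05)
        df["junk"] = rng.normal(size=400)
        kept = backward_eliminate(df, "fpg", [], forced_in=("junk",))
        assert kept == ["junk"]

    def test_candidates_disjoint_from_forced(self):
        rng = np.random.default_rng(6)
        df = _null_frame(rng)
        df["x"] = 1.0
        with pytest.raises(ValueError, match="disjoint"):
            backward_eliminate(df, "fpg", ["x"], forced_in=("x",))


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        # zero-mean mutually orthogonal contrasts
        X = pd.DataFrame(
            {"a": [1, 1, -1, -1], "b": [1, -1, 1, -1], "c": [1, -1, -1, 1]},
            dtype=float,
        )
        vifs, flagged = vif_screen(X)
        assert not flagged
        for v in vifs.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_column_infinite_flagged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        vifs, flagged = vif_screen(X)
        assert flagged and np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_known_correlation_closed_form(self):
        # VIF = 1/(1-ρ²) = 1.5625 at ρ = 0.6 in the population
        rng = np.random.default_rng(8)
        n = 40000
        x = rng.normal(size=n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        vifs, _ = vif_screen(pd.DataFrame({"x": x, "y": y}))
        assert vifs["x"] == pytest.approx(1.5625, abs=0.03)

    def test_matches_statsmodels(self, analysis_df):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        df, _ = analysis_df
        X = build_design(df, "sit", covariates=("age", "alcohol", "calcium"))
        vifs, _ = vif_screen(X)
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            if name == "const":
                continue
            assert vifs[name] == pytest.approx(
                variance_inflation_factor(arr, j), rel=1e-6
            )
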