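"""Time reallocation and the estimated percent change in glucose."""

import numpy as np
import pandas as pd
import pytest

from timeuse_coda.composition import PARTS, close, geometric_mean_composition
from timeuse_coda.reallocation import (
    InfeasibleReallocationError,
    all_ordered_pairs,
    estimate_delta,
    reallocate,
    reallocation_grid,
)
from timeuse_coda.regression import build_design, fit_model
from conftest import random_compositions

LOWER_GM = (526.4, 287.1, 120.6, 505.8)


def _random_fit(rng, n=120):
    from timeuse_coda.composition import ilr_inverse

    z = rng.normal(scale=0.35, size=(n, 3))
    df = pd.DataFrame(ilr_inverse(z, "sit"), columns=list(PARTS))
    beta = rng.normal(scale=0.1, size=3)
    df["fpg_mmol_l"] = np.exp(
        np.log(5.3) + z @ beta + rng.normal(scale=0.1, size=n)
    )
    df["age"] = rng.normal(55, 9, size=n)
    return fit_model(df, "fpg", "sit", covariates=("age",)), df


class TestReallocate:
    def test_sixty_minutes_sit_to_step(self):
        new = reallocate(np.array(LOWER_GM), "sit", "step", 60.0)
        np.testing.assert_allclose(new, (466.4, 287.1, 180.6, 505.8))

    def test_zero_minutes_identity(self):
        base = np.array(LOWER_GM)
        np.testing.assert_allclose(reallocate(base, "sleep", "stand", 0.0), base)

    def test_total_preserved(self):
        base = close(LOWER_GM)
        new = reallocate(base, "stand", "sleep", 45.0)
        assert new.sum() == pytest.approx(base.sum())

    def test_infeasible_raises(self):
        base = np.array([500.0, 300.0, 140.0, 500.0])
        with pytest.raises(InfeasibleReallocationError):
            reallocate(base, "sit", "step", 600.0)
        with pytest.raises(InfeasibleReallocationError):
            reallocate(base, "sit", "sit", 10.0)


class TestEstimateDelta:
    def test_no_change_gives_zero(self):
        rng = np.random.default_rng(0)
        fit, _ = _random_fit(rng)
        base = close(LOWER_GM)
        r = estimate_delta(fit, base, base)
        assert r.delta_percent == 0.0
        assert r.ci_low_percent == pytest.approx(0.0) == r.ci_high_percent

    def test_equals_direct_prediction_difference(self):
        """delta_log must equal the fitted model's own prediction difference
        (covariates cancel), checked over 100 random fits/reallocations."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            fit, df = _random_fit(rng, n=60)
            base = geometric_mean_composition(df[list(PARTS)].to_numpy())
            frm, to = rng.choice(PARTS, size=2, replace=False)
            minutes = float(rng.uniform(5, min(50.0, base[PARTS.index(frm)] - 1)))
            new = reallocate(base, frm, to, minutes)
            r = estimate_delta(fit, base, new, frm, to, minutes)
            # oracle: predict both compositions through the design pathway
            # with an arbitrary fixed covariate row
            row = df.iloc[[0]].copy()
            preds = []
            for comp in (new, base):
                row[list(PARTS)] = comp
                X = build_design(row, "sit", covariates=("age",))
                preds.append((X.to_numpy() @ fit.params.to_numpy())[0])
            assert r.delta_log == pytest.approx(preds[0] - preds[1], abs=1e-10)

    def test_sign_consistency_percent_vs_log(self):
        rng = np.random.default_rng(2)
        fit, df = _random_fit(rng)
        base = geometric_mean_composition(df[list(PARTS)].to_numpy())
        grid = reallocation_grid(fit, base, minutes_grid=[15.0, 60.0])
        ok = grid.feasible
        assert (np.sign(grid.loc[ok, "delta_percent"])
                == np.sign(grid.loc[ok, "delta_log"])).all()


class TestGrid:
    def test_zero_grid_all_zero(self):
        rng = np.random.default_rng(3)
        fit, df = _random_fit(rng)
        base = geometric_mean_composition(df[list(PARTS)].to_numpy())
        grid = reallocation_grid(fit, base, minutes_grid=[0.0])
        assert len(grid) == 12
        np.testing.assert_allclose(grid["delta_percent"], 0.0, atol=1e-12)

    def test_antisymmetric_consistency(self):
        """Moving t minutes A->B then estimating the reverse move from the
        shifted base must exactly undo the delta."""
        rng = np.random.default_rng(4)
        fit, df = _random_fit(rng)
        base = geometric_mean_composition(df[list(PARTS)].to_numpy())
        shifted = reallocate(base, "sit", "step", 30.0)
        fwd = estimate_delta(fit, base, shifted)
        back = estimate_delta(fit, shifted, base)
        assert back.delta_log == pytest.approx(-fwd.delta_log, abs=1e-12)

    def test_compositional_asymmetry_about_zero(self):
        """|delta(A->B, t)| != |delta(B->A, t)| in general: the ilr contrast
        is non-linear in minutes."""
        rng = np.random.default_rng(5)
        fit, df = _random_fit(rng)
        base = geometric_mean_composition(df[list(PARTS)].to_numpy())
        ab = estimate_delta(fit, base, reallocate(base, "sit", "step", 60.0))
        ba = estimate_delta(fit, base, reallocate(base, "step", "sit", 60.0))
        assert abs(ab.delta_log) != pytest.approx(abs(ba.delta_log), rel=1e-6)

    def test_infeasible_point_recorded_not_fatal(self):
        rng = np.random.default_rng(6)
        fit, df = _random_fit(rng)
        base = np.array([700.0, 400.0, 40.0, 300.0])
        grid = reallocation_grid(fit, base, pairs=[("step", "sit")],
                                 minutes_grid=[30.0, 60.0])
        assert grid.feasible.tolist() == [True, False]
        assert grid.delta_percent.isna().tolist() == [False, True]

    def test_full_layout(self):
        rng = np.random.default_rng(7)
        fit, df = _random_fit(rng)
        base = geometric_mean_composition(df[list(PARTS)].to_numpy())
        grid = reallocation_grid(fit, base)
        assert len(grid) == 12 * 4
        assert set(map(tuple, grid[["from_part", "to_part"]].to_numpy())) \
            == set(all_ordered_pairs())

    def test_known_generating_negative_stepping_effect(self):
        """With a strongly negative stepping association, moving sitting
        time into stepping must lower predicted glucose, matching the
        closed-form contrast of the generating coefficients."""
        from timeuse_coda.cohort import GeneratorConfig, generate_participants
        from timeuse_coda.composition import ilr_pivot
        from timeuse_coda.processing import assign_risk_group

        cfg = GeneratorConfig(p_missing_covariate=0.0, p_missing_2hplg=0.0)
        df, truth = generate_participants(cfg, seed=77)
        df["risk_group"] = assign_risk_group(df["hba1c_mmol_mol"])
        fit = fit_model(df, "2hplg", "sit", covariates=("age",),
                        group_scope="lower")
        base = geometric_mean_composition(
            df.loc[df.risk_group == "lower", list(PARTS)].to_numpy()
        )
        new = reallocate(base, "sit", "step", 60.0)
        r = estimate_delta(fit, base, new)
        assert -10.0 < r.delta_percent < 0.0
        # closed form under the generating clr coefficients
        a = np.array(truth["beta"]["2hplg"]["lower"]["clr"])
        basis = fit.basis
        truth_delta = (ilr_pivot(new, basis) - ilr_pivot(base, basis)) \
            @ (basis.contrast.T @ a)
        assert r.delta_log == pytest.approx(truth_delta, abs=0.04)
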