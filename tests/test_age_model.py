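"""Screening, stepwise selection, diagnostics, LOO CV and fixed equations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from itertools import combinations

from ribchron.age_model import (
    VIF_CAP,
    apply_published,
    fit_model,
    load_published_equations,
    loo_cv,
    screen,
    stepwise_aic,
)


def _toy_table(rng, n=60, k=6, signal=(0, 2)):
    """k candidate columns; those in `signal` carry real effects."""
    x = rng.standard_normal((n, k))
    beta = np.zeros(k)
    for j, b in zip(signal, (3.0, -2.0)):
        beta[j] = b
    age = 45 + x @ beta + rng.standard_normal(n) * 2.0
    cols = {f"x{j}": x[:, j] for j in range(k)}
    cols["age"] = age
    cols["sex"] = np.where(rng.random(n) < 0.5, "M", "F")
    return pd.DataFrame(cols)


class TestScreen:
    def test_generated_correlation_recovered(self, cohort_table):
        # the cohort fixture carries the configured porosity-age structure
        big = screen(cohort_table)
        assert big.loc["PoAr_pct", "pearson_r"] > 0.6

    def test_high_n_correlation_close_to_target(self):
        from ribchron.synthetic import (PopulationSpec, build_parameter_table)
        t = build_parameter_table(PopulationSpec(n_specimens=10_000, seed=3), seed=3)
        s = screen(t, parameters=["PoAr_pct"])
        assert s.loc["PoAr_pct", "pearson_r"] == pytest.approx(0.83, abs=0.02)

    def test_sex_identical_column_null_anova(self):
        vals = np.linspace(1.0, 2.0, 20)
        t = pd.DataFrame({
            "age": np.tile(np.linspace(20, 70, 20), 2),
            "flat": np.concatenate([vals, vals]),  # identical distribution per sex
            "sex": ["M"] * 20 + ["F"] * 20,
        })
        s = screen(t, parameters=["flat"])
        assert s.loc["flat", "anova_f"] == pytest.approx(0.0, abs=1e-12)
        assert s.loc["flat", "anova_p"] > 0.99

    def test_pearson_matches_hand_computation(self):
        t = pd.DataFrame({
            "age": [20.0, 30.0, 40.0, 50.0, 60.0],
            "v": [1.0, 1.5, 1.7, 2.6, 2.9],
            "sex": ["M", "M", "F", "F", "M"],
        })
        s = screen(t, parameters=["v"])
        a, v = t["age"].to_numpy(), t["v"].to_numpy()
        r_hand = np.sum((a - a.mean()) * (v - v.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((v - v.mean()) ** 2))
        assert s.loc["v", "pearson_r"] == pytest.approx(r_hand, rel=1e-12)

    def test_constant_column_reported_undefined(self, rng):
        t = _toy_table(rng)
        t["const_col"] = 3.14
        s = screen(t, parameters=["const_col"])
        assert np.isnan(s.loc["const_col", "pearson_r"])
        assert "undefined" in s.loc["const_col", "note"]


class TestStepwise:
    def test_matches_exhaustive_best_subset(self, rng):
        table = _toy_table(rng, n=60, k=6)
        cands = [f"x{j}" for j in range(6)]
        best_aic, best_set = np.inf, ()
        y = table["age"].to_numpy()
        for r in range(7):
            for subset in combinations(cands, r):
                x = sm.add_constant(table[list(subset)].to_numpy()) if subset else \
                    np.ones((len(table), 1))
                aic = sm.OLS(y, x).fit().aic
                if aic < best_aic:
                    best_aic, best_set = aic, subset
        fitted = stepwise_aic(table, cands, dw_permutations=0)
        assert sorted(fitted.predictors) == sorted(best_set)
        assert fitted.aic == pytest.approx(best_aic, abs=1e-8)

    def test_dominant_predictor_selected(self, rng):
        n = 80
        age = rng.uniform(15, 80, n)
        t = pd.DataFrame({
            "age": age,
            "perfect": age + rng.standard_normal(n) * 0.01,
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        })
        fitted = stepwise_aic(t, ["noise1", "perfect", "noise2"], dw_permutations=0)
        assert fitted.predictors == ["perfect"]

    def test_final_aic_beats_empty_and_full(self, rng):
        table = _toy_table(rng, n=70, k=6)
        cands = [f"x{j}" for j in range(6)]
        fitted = stepwise_aic(table, cands, dw_permutations=0)
        y = table["age"].to_numpy()
        aic_empty = sm.OLS(y, np.ones((len(y), 1))).fit().aic
        aic_full = sm.OLS(y, sm.add_constant(table[cands].to_numpy())).fit().aic
        assert fitted.aic <= aic_empty + 1e-9
        assert fitted.aic <= aic_full + 1e-9

    def test_perfect_collinearity_errors(self, rng):
        t = _toy_table(rng)
        t["dup"] = t["x0"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_model(t, ["x0", "dup"], dw_permutations=0)


class TestDiagnostics:
    def test_near_duplicate_vif_capped(self, rng):
        t = _toy_table(rng, n=100)
        t["near"] = t["x0"] + 1e-8 * rng.standard_normal(len(t))
        fitted = fit_model(t, ["x0", "near"], dw_permutations=0)
        assert fitted.vif["x0"] == VIF_CAP

    def test_single_predictor_vif_is_one(self, rng):
        t = _toy_table(rng)
        fitted = fit_model(t, ["x0"], dw_permutations=0)
        assert fitted.vif == {"x0": 1.0}

    def test_durbin_watson_null(self):
        rng = np.random.default_rng(8)
        n = 10_000
        t = pd.DataFrame({"age": rng.standard_normal(n), "x0": rng.standard_normal(n)})
        fitted = fit_model(t, ["x0"], dw_permutations=200, dw_seed=1)
        assert fitted.dw_statistic == pytest.approx(2.0, abs=0.06)
        assert fitted.dw_p > 0.05

    def test_cooks_flags_gross_outlier(self, rng):
        t = _toy_table(rng, n=50)
        t.loc[0, "age"] += 60.0
        fitted = fit_model(t, ["x0", "x2"], dw_permutations=0)
        assert 0 in fitted.cooks_flagged


class TestLooCv:
    def test_noise_free_linear_is_perfect(self, rng):
        n = 30
        x = rng.standard_normal(n)
        t = pd.DataFrame({"age": 40 + 3 * x, "x0": x})
        cv = loo_cv(t, ["x0"])
        assert cv.cv_r2 == pytest.approx(1.0, abs=1e-9)
        assert cv.cv_mae == pytest.approx(0.0, abs=1e-9)

    def test_matches_explicit_refit_loop(self, rng):
        t = _toy_table(rng, n=12, k=2, signal=(0,))
        preds = ["x0", "x1"]
        cv = loo_cv(t, preds)
        outs = []
        for i in range(len(t)):
            train = t.drop(index=i)
            res = sm.OLS(train["age"], sm.add_constant(train[preds])).fit()
            row = sm.add_constant(t[preds], has_constant="add").iloc[[i]]
            outs.append(float(res.predict(row).iloc[0]))
        err = t["age"].to_numpy() - np.array(outs)
        assert cv.cv_rmse == pytest.approx(float(np.sqrt(np.mean(err**2))), rel=1e-9)
        assert cv.cv_mae == pytest.approx(float(np.mean(np.abs(err))), rel=1e-9)

    def test_row_order_invariance(self, rng):
        t = _toy_table(rng, n=25)
        shuffled = t.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = loo_cv(t, ["x0", "x2"])
        b = loo_cv(shuffled, ["x0", "x2"])
        assert a.cv_rmse == pytest.approx(b.cv_rmse, rel=1e-9)

    def test_rmse_bounds_mae(self, rng):
        cv = loo_cv(_toy_table(rng), ["x0", "x1"])
        assert cv.cv_rmse >= cv.cv_mae >= 0

    def test_too_small_sample_rejected(self, rng):
        t = _toy_table(rng, n=4, k=3)
        with pytest.raises(ValueError):
            loo_cv(t, ["x0", "x1", "x2"])


class TestPublishedEquations:
    def test_shipped_compositions(self):
        eqs = load_published_equations()
        assert len(eqs["E1"].predictors) == 10
        assert len(eqs["E2"].predictors) == 6
        assert len(eqs["E3"].predictors) == 5

    def test_constant_at_zero_predictors(self):
        eqs = load_published_equations()
        record = {p: 0.0 for p in eqs["E1"].predictors}
        assert apply_published(record, eqs["E1"]) == pytest.approx(-759.525)

    def test_porosity_slope(self):
        eqs = load_published_equations()
        base = {p: 1.0 for p in eqs["E1"].predictors}
        bumped = dict(base, PoAr_pct=2.0)
        delta = apply_published(bumped, eqs["E1"]) - apply_published(base, eqs["E1"])
        assert delta == pytest.approx(6.001)

    def test_dot_product_oracle(self, rng):
        eqs = load_published_equations()
        for eq in eqs.values():
            record = {p: float(rng.uniform(-2, 2)) for p in eq.predictors}
            expected = eq.constant + sum(eq.coefficients[p] * record[p] for p in eq.predictors)
            with pytest.warns(UserWarning):
                got = apply_published(record, eq)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_predictor_listed(self):
        eqs = load_published_equations()
        with pytest.raises(KeyError, match="PoAr_pct"):
            apply_published({"H_IT": 60.0}, eqs["E1"])


def test_coefficient_recovery_within_two_se():
    """Refitting data generated from a known linear model recovers beta
    within 2 standard errors at approximately the nominal rate."""
    rng = np.random.default_rng(99)
    hits = 0
    reps = 500
    for _ in range(reps):
        n = 40
        x = rng.standard_normal(n)
        t = pd.DataFrame({"x0": x, "age": 5.0 + 1.8 * x + rng.standard_normal(n) * 1.5})
        fitted = fit_model(t, ["x0"], dw_permutations=0)
        if abs(fitted.coefficients["x0"] - 1.8) <= 2 * fitted.coef_se["x0"]:
            hits += 1
    assert hits / reps > 0.92
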