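"""Generator behaviour: cohort structure, correlation targets, determinism."""

import numpy as np
import pandas as pd
import pytest

from ribchron.constants import DERIVED_PARAMETERS, PARAMETER_NAMES
from ribchron.synthetic import (
    GenerationError,
    ParameterSpec,
    PopulationSpec,
    RenderOptions,
    build_parameter_table,
    default_parameter_specs,
    draw_parameters,
    draw_population,
    render_raw,
)


class TestDrawPopulation:
    def test_default_cohort_moments(self):
        # truncation barely shifts the mean; 3 SE of 16.33/sqrt(113)
        means = [draw_population(PopulationSpec(seed=s))["age"].mean() for s in range(5)]
        assert abs(np.mean(means) - 46.64) < 3 * 16.33 / np.sqrt(113)

    def test_truncation_bounds_hold_at_large_n(self):
        ages = draw_population(PopulationSpec(n_specimens=100_000, seed=3))["age"]
        assert ages.min() >= 12.0 and ages.max() <= 84.0

    def test_zero_sd_degenerates_to_mean(self):
        ages = draw_population(PopulationSpec(n_specimens=20, age_sd=0.0, seed=1))["age"]
        assert np.allclose(ages, 46.64)

    def test_sex_fractions(self):
        pop = draw_population(PopulationSpec(n_specimens=113, seed=2))
        assert (pop["sex"] == "M").sum() == 77

    @pytest.mark.parametrize("kwargs", [
        dict(age_min=50.0, age_max=40.0),
        dict(sex_fraction_male=1.5),
        dict(n_specimens=1),
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationSpec(**kwargs)


class TestDrawParameters:
    def setup_method(self):
        self.ages = draw_population(PopulationSpec(n_specimens=10_000, seed=7))["age"].to_numpy()

    def test_target_correlation_recovered(self):
        spec = ParameterSpec("PoAr_pct", 10.5, 3.5, 0.83)
        x = draw_parameters(self.ages, [spec], seed=1)["PoAr_pct"]
        r = np.corrcoef(x, self.ages)[0, 1]
        assert abs(r - 0.83) < 0.02

    def test_zero_correlation_independent(self):
        spec = ParameterSpec("noise", 5.0, 1.0, 0.0)
        x = draw_parameters(self.ages, [spec], seed=2)["noise"]
        assert abs(np.corrcoef(x, self.ages)[0, 1]) < 0.05

    def test_perfect_correlation_is_affine(self):
        spec = ParameterSpec("lin", 5.0, 2.0, 1.0)
        x = draw_parameters(self.ages[:200], [spec], seed=3)["lin"]
        r = np.corrcoef(x, self.ages[:200])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpec("bad", 0.0, 1.0, 1.2)

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            default_parameter_specs({"not_a_parameter": 0.1})


class TestDerivedColumns:
    def test_consistency_identities(self, cohort_table):
        t = cohort_table
        assert np.allclose(t["Ash_pct"], 100 - t["W_pct"] - t["Or_pct"])
        assert np.allclose(t["MM"] * t["CC"], 1.0, atol=1e-12)
        assert np.allclose(t["eta_IT"], (t["On_eta_IT"] + t["It_eta_IT"]) / 2)
        assert np.allclose(t["HV"], (t["On_HV"] + t["It_HV"]) / 2)

    def test_full_column_set(self, cohort_table):
        assert list(cohort_table.columns) == ["specimen_id", "sex", "age", *PARAMETER_NAMES]
        assert len(PARAMETER_NAMES) == 33
        assert cohort_table["specimen_id"].is_unique

    def test_derived_marked(self):
        assert set(DERIVED_PARAMETERS) == {
            "E_IT", "H_IT", "C_IT", "eta_IT", "HV", "Ash_pct", "MM", "CL002", "CL004"
        }


class TestDeterminism:
    def test_parameter_table_byte_identical(self):
        a = build_parameter_table(seed=9).to_csv(index=False)
        b = build_parameter_table(seed=9).to_csv(index=False)
        assert a == b

    def test_bundle_reproducible(self, cohort_table, fast_render_options):
        rec = cohort_table.iloc[0].to_dict()
        b1 = render_raw(rec, seed=4, options=fast_render_options, specimen_index=0)
        b2 = render_raw(rec, seed=4, options=fast_render_options, specimen_index=0)
        assert np.array_equal(b1.thermogram.mass_mg, b2.thermogram.mass_mg)
        assert np.array_equal(b1.diffraction["wide"].intensity,
                              b2.diffraction["wide"].intensity)
        assert np.array_equal(b1.porosity_masks[0].voids, b2.porosity_masks[0].voids)
        assert np.array_equal(b1.indentation_curves[0].depth_nm,
                              b2.indentation_curves[0].depth_nm)

    def test_specimen_index_changes_stream(self, cohort_table, fast_render_options):
        rec = cohort_table.iloc[0].to_dict()
        b1 = render_raw(rec, seed=4, options=fast_render_options, specimen_index=0)
        b2 = render_raw(rec, seed=4, options=fast_render_options, specimen_index=1)
        assert not np.array_equal(b1.thermogram.mass_mg, b2.thermogram.mass_mg)


class TestRenderErrors:
    def test_eta_out_of_range_names_parameter(self, cohort_table):
        rec = cohort_table.iloc[0].to_dict()
        rec["On_eta_IT"] = 140.0
        with pytest.raises(GenerationError, match="eta_IT"):
            render_raw(rec, seed=1, options=RenderOptions(indents_per_site=1))

    def test_invalid_mass_partition(self, cohort_table):
        rec = cohort_table.iloc[0].to_dict()
        rec["W_pct"], rec["Or_pct"] = 60.0, 55.0
        with pytest.raises(GenerationError):
            render_raw(rec, seed=1, options=RenderOptions(indents_per_site=1))


class TestForwardModelLimits:
    def test_fully_elastic_curve_retraces_loading(self):
        from ribchron.synthetic import render_indentation_curve

        c = render_indentation_curve(E_GPa=20.0, H_MPa=600.0, C_pct=0.0, eta_pct=100.0)
        load_mask = c.phase == "loading"
        unload_mask = c.phase == "unloading"
        # same depth at equal load on both branches
        h_up = np.interp(5.0, c.load_mN[load_mask], c.depth_nm[load_mask])
        p_down = c.load_mN[unload_mask][::-1]
        h_down = np.interp(5.0, p_down, c.depth_nm[unload_mask][::-1])
        assert h_up == pytest.approx(h_down, rel=1e-6)

    def test_thermogram_mass_conservation(self, rng):
        from ribchron.synthetic import render_thermogram

        tg = render_thermogram(10.0, 25.0, rng, RenderOptions(tga_noise_rel=0.0))
        assert tg.mass_mg[-1] / tg.mass_mg[0] == pytest.approx(0.65, abs=5e-4)


def test_model_layer_sanity_on_generated_tables():
    """Feeding the generated cohort to the regression stage gives positive R^2
    that strengthens (in cross-validated terms) as the cohort grows."""
    from ribchron.age_model import fit_model, loo_cv
    from ribchron.age_model import load_published_equations

    preds = load_published_equations()["E1"].predictors
    small = build_parameter_table(PopulationSpec(n_specimens=40, seed=21), seed=21)
    large = build_parameter_table(PopulationSpec(n_specimens=400, seed=22), seed=22)
    fit_small = fit_model(small, preds, dw_permutations=0)
    fit_large = fit_model(large, preds, dw_permutations=0)
    assert fit_small.r2 > 0 and fit_large.r2 > 0
    assert loo_cv(large, preds).cv_r2 > loo_cv(small, preds).cv_r2 - 0.05
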