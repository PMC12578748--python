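"""Counterfactual profiles and the IQR-contrast estimands."""

import numpy as np
import pandas as pd
import pytest

from mixsurv.estimands import (
    build_profile,
    choose_t_spec,
    exposure_response_curve,
    interaction_effect,
    mixture_effect,
    single_exposure_effect,
)
from mixsurv.evaluation import fit_oracle
from mixsurv.learners import LearnerSpec, fit
from mixsurv.scenarios import CURVE_GRID, ScenarioConfig, SurvivalDataset, generate_dataset

from conftest import toy_dataset


@pytest.fixture(scope="module")
def cox_model(scenario1_small):
    return fit(LearnerSpec("cox_ph"), scenario1_small)


@pytest.fixture(scope="module")
def cox_int_model(scenario1_small):
    return fit(LearnerSpec("cox_ph_int"), scenario1_small)


class TestBuildProfile:
    def test_quantile_convention(self):
        data = toy_dataset(np.linspace(1, 10, 100), np.ones(100))
        data.exposures["M1"] = np.arange(1.0, 101.0)
        prof = build_profile(data, [0.75, 0.5])
        assert prof.exposures[0] == np.quantile(np.arange(1.0, 101.0), 0.75)

    def test_median_labels(self, scenario1_small):
        prof = build_profile(scenario1_small, 0.5)
        np.testing.assert_allclose(
            prof.exposures, scenario1_small.exposures.median().to_numpy()
        )

    def test_binary_confounder_at_reference_level(self, scenario1_small):
        prof = build_profile(scenario1_small, 0.5)
        assert prof.confounders[0] == 0.0  # two-valued: lower level
        assert prof.confounders[1] == pytest.approx(
            scenario1_small.confounders["C2"].median()
        )

    def test_label_bounds(self, scenario1_small):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            build_profile(scenario1_small, 1.5)

    def test_empty_data_rejected(self):
        empty = SurvivalDataset.__new__(SurvivalDataset)
        empty.time = np.empty(0)
        empty.event = np.empty(0, dtype=int)
        empty.exposures = pd.DataFrame(columns=["M1"])
        empty.confounders = pd.DataFrame(columns=["C1"])
        with pytest.raises(ValueError, match="empty"):
            build_profile(empty, 0.5)


class TestMixtureEffect:
    def test_cox_linear_predictor_identity(self, cox_model, scenario1_small):
        # for a linear Cox fit the mixture HR is exactly
        # exp(sum_j beta_j (q75_j - q25_j))
        hr, spd = mixture_effect(cox_model, scenario1_small, 8.0)
        q75 = scenario1_small.exposures.quantile(0.75).to_numpy()
        q25 = scenario1_small.exposures.quantile(0.25).to_numpy()
        expected = np.exp(cox_model.coef_[:5] @ (q75 - q25))
        assert hr.point == pytest.approx(expected, rel=1e-12)
        assert -1 <= spd.point <= 0  # harmful mixture: survival drops

    def test_null_model_gives_unit_hr_zero_spd(self):
        config = ScenarioConfig(scenario_id=1, n_subjects=300, seed=3, hazard_variant="null")
        data = generate_dataset(config)
        oracle = fit_oracle(config, data)
        hr, spd = mixture_effect(oracle, data, 8.0)
        assert hr.point == 1.0
        assert spd.point == 0.0

    def test_profile_swap_symmetry(self, cox_model, scenario1_small):
        hi = build_profile(scenario1_small, 0.75).values
        lo = build_profile(scenario1_small, 0.25).values
        fwd = cox_model.predict_log_hazard_contrast(hi, lo, 8.0)
        rev = cox_model.predict_log_hazard_contrast(lo, hi, 8.0)
        assert fwd == pytest.approx(-rev, abs=1e-12)
        s_hi = cox_model.predict_survival(hi, 8.0)
        s_lo = cox_model.predict_survival(lo, 8.0)
        assert (s_hi - s_lo) == pytest.approx(-(s_lo - s_hi))

    def test_ph_model_hr_invariant_to_t_spec(self, cox_model, scenario1_small):
        hr1, _ = mixture_effect(cox_model, scenario1_small, 4.0)
        hr2, _ = mixture_effect(cox_model, scenario1_small, 14.0)
        assert hr1.point == pytest.approx(hr2.point, rel=1e-12)

    def test_discrete_model_hr_may_vary_by_bin(self, scenario1_small):
        model = fit(LearnerSpec("bart_dt", {"n_draws": 100, "n_trees": 25}), scenario1_small)
        hr_early, _ = mixture_effect(model, scenario1_small, 2.0)
        hr_late, _ = mixture_effect(model, scenario1_small, 14.0)
        # bin-specific discrete hazards need not be proportional
        assert hr_early.point != hr_late.point


class TestSingleExposure:
    def test_null_exposure_truth(self):
        from mixsurv.scenarios import compute_truth

        truth = compute_truth(ScenarioConfig(scenario_id=1))
        assert truth.hr_single[1] == 1.0
        assert truth.spd_single[1] == 0.0

    def test_additivity_of_log_hrs(self, cox_model, scenario1_small):
        # for an additive linear model, single-exposure log HRs sum to the
        # mixture log HR
        t = 8.0
        total = sum(
            np.log(single_exposure_effect(cox_model, scenario1_small, j, t)[0].point)
            for j in range(5)
        )
        mix = np.log(mixture_effect(cox_model, scenario1_small, t)[0].point)
        assert total == pytest.approx(mix, abs=1e-10)

    def test_out_of_range_index(self, cox_model, scenario1_small):
        with pytest.raises(IndexError):
            single_exposure_effect(cox_model, scenario1_small, 7, 8.0)


class TestInteraction:
    def test_no_interaction_model_gives_exactly_one(self, cox_model, scenario1_small):
        est = interaction_effect(cox_model, scenario1_small, 0, 4, 8.0)
        assert est.point == pytest.approx(1.0, abs=1e-12)

    def test_cox_int_matches_coefficient_algebra(self, cox_int_model, scenario1_small):
        # double contrast of a model with product terms: exp(gamma_jk
        # * delta_j * delta_k) exactly
        j, k = 0, 4
        est = interaction_effect(cox_int_model, scenario1_small, j, k, 8.0)
        # product columns follow the 5 main exposures in the design
        pair_index = {(a, b): i for i, (a, b) in enumerate(
            [(a, b) for a in range(5) for b in range(a + 1, 5)]
        )}
        gamma = cox_int_model.coef_[5 + pair_index[(j, k)]]
        dj = scenario1_small.exposures.iloc[:, j].quantile(0.75) - \
            scenario1_small.exposures.iloc[:, j].quantile(0.25)
        dk = scenario1_small.exposures.iloc[:, k].quantile(0.75) - \
            scenario1_small.exposures.iloc[:, k].quantile(0.25)
        assert est.point == pytest.approx(np.exp(gamma * dj * dk), rel=1e-10)

    def test_symmetry_in_j_k(self, cox_int_model, scenario1_small):
        a = interaction_effect(cox_int_model, scenario1_small, 0, 4, 8.0).point
        b = interaction_effect(cox_int_model, scenario1_small, 4, 0, 8.0).point
        assert a == pytest.approx(b, rel=1e-12)

    def test_same_exposure_rejected(self, cox_model, scenario1_small):
        with pytest.raises(ValueError, match="distinct"):
            interaction_effect(cox_model, scenario1_small, 2, 2, 8.0)


class TestCurve:
    def test_values_in_unit_interval(self, cox_model, scenario1_small):
        est = exposure_response_curve(cox_model, scenario1_small, 2, 8.0)
        assert len(est.point) == 19
        assert np.all((est.point >= 0) & (est.point <= 1))

    def test_null_exposure_flat_for_oracle(self):
        config = ScenarioConfig(scenario_id=1, n_subjects=500, seed=9)
        data = generate_dataset(config)
        oracle = fit_oracle(config, data)
        est = exposure_response_curve(oracle, data, 1, 8.0)
        assert np.ptp(est.point) == 0.0

    def test_curve_endpoints_reproduce_single_spd(self, cox_model, scenario1_small):
        # S(q75) - S(q25) read off the curve grid equals the
        # single-exposure SPD
        t = 8.0
        for j in (0, 3):
            est = exposure_response_curve(cox_model, scenario1_small, j, t)
            i25 = int(np.where(np.isclose(CURVE_GRID, 0.25))[0][0])
            i75 = int(np.where(np.isclose(CURVE_GRID, 0.75))[0][0])
            spd = single_exposure_effect(cox_model, scenario1_small, j, t)[1].point
            assert est.point[i75] - est.point[i25] == pytest.approx(spd, abs=1e-10)


class TestChooseTSpec:
    def test_percentile_rule_is_empirical_quantile(self):
        data = toy_dataset(np.arange(1.0, 11.0), np.ones(10))
        assert choose_t_spec(data, "percentile", 0.8) == np.quantile(np.arange(1.0, 11.0), 0.8)

    def test_fixed_rule_passthrough(self, scenario1_small):
        assert choose_t_spec(scenario1_small, "fixed", 10.0) == 10.0

    def test_percentile_bounds(self, scenario1_small):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            choose_t_spec(scenario1_small, "percentile", 1.0)

    def test_unknown_rule(self, scenario1_small):
        with pytest.raises(ValueError, match="unknown"):
            choose_t_spec(scenario1_small, "midpoint")
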