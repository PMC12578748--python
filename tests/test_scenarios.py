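"""Tests of the scenario simulator: exposure structure, hazard shapes,
event-time sampling, censoring calibration and closed-form ground truth."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import spearmanr

from mixsurv.scenarios import (
    CURVE_GRID,
    T_MAX_NONPH,
    WEIBULL_RATE,
    WEIBULL_SHAPE,
    ScenarioConfig,
    apply_censoring,
    compute_truth,
    generate_dataset,
    generate_exposures,
    log_hazard_function,
    simulate_event_times,
    true_survival,
)
from mixsurv.scenarios import _cumulative_hazard, _reference_marginals, _split_latent, _draw_latent


class TestExposures:
    def test_positive_lognormal_marginals(self):
        m = generate_exposures(ScenarioConfig(scenario_id=1), np.random.default_rng(0))
        assert m.shape == (3000, 5)
        assert np.all(m > 0)

    def test_scenario2_has_ten_components(self):
        m = generate_exposures(ScenarioConfig(scenario_id=2), np.random.default_rng(0))
        assert m.shape == (3000, 10)

    def test_high_correlation_scenario_spearman(self):
        # the Gaussian copula with latent correlations in [0.7, 0.9] must
        # push mean absolute pairwise Spearman correlation above 0.55
        m = generate_exposures(ScenarioConfig(scenario_id=3), np.random.default_rng(1))
        rho = spearmanr(m)[0]
        off = np.abs(rho[np.triu_indices(5, 1)])
        assert off.mean() > 0.55

    def test_low_moderate_correlations_are_lower(self):
        m = generate_exposures(ScenarioConfig(scenario_id=1), np.random.default_rng(1))
        rho = spearmanr(m)[0]
        off = np.abs(rho[np.triu_indices(5, 1)])
        assert off.mean() < 0.45


class TestLogHazard:
    def setup_method(self):
        self.config = ScenarioConfig(scenario_id=1)
        self.m = np.array([1.2, 0.9, 1.1, 1.4, 0.8])
        self.c = np.array([1.0, 0.3])

    def test_null_exposure_has_no_effect(self):
        f_vals = [
            log_hazard_function(
                np.array([1.2, m2, 1.1, 1.4, 0.8]), self.c, 5.0, self.config
            )[0]
            for m2 in (0.2, 1.0, 4.0)
        ]
        assert np.ptp(f_vals) == 0.0

    def test_ph_scenario_time_invariant(self):
        f1 = log_hazard_function(self.m, self.c, 2.0, self.config)
        f2 = log_hazard_function(self.m, self.c, 15.0, self.config)
        assert f1[0] == f2[0]

    def test_non_ph_scenario_time_varying(self):
        config = ScenarioConfig(scenario_id=4)
        other = np.array([2.0, 0.9, 1.1, 1.4, 0.8])
        d2 = (
            log_hazard_function(self.m, self.c, 2.0, config)
            - log_hazard_function(other, self.c, 2.0, config)
        )[0]
        d15 = (
            log_hazard_function(self.m, self.c, 15.0, config)
            - log_hazard_function(other, self.c, 15.0, config)
        )[0]
        assert abs(d2 - d15) > 1e-3

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="5 exposures"):
            log_hazard_function(np.ones(4), self.c, 1.0, self.config)
        with pytest.raises(ValueError, match="2 confounders"):
            log_hazard_function(self.m, np.ones(3), 1.0, self.config)


class TestEventTimes:
    def test_weibull_transform_of_null_hazard_is_exponential(self):
        # with all exposure and confounder effects zeroed, T^kappa is
        # Exponential(rate), so its empirical mean must sit within 3 SE of
        # 1/rate
        config = ScenarioConfig(scenario_id=1, hazard_variant="null")
        n = 10_000
        m = np.ones((n, 5))
        c = np.zeros((n, 2))
        t = simulate_event_times(m, c, config, np.random.default_rng(3))
        y = t**WEIBULL_SHAPE
        se = y.std(ddof=1) / np.sqrt(n)
        assert abs(y.mean() - 1 / WEIBULL_RATE) < 3 * se

    def test_median_matches_closed_form(self):
        config = ScenarioConfig(scenario_id=1, hazard_variant="null")
        n = 40_000
        t = simulate_event_times(
            np.ones((n, 5)), np.zeros((n, 2)), config, np.random.default_rng(4)
        )
        expected = (np.log(2) / WEIBULL_RATE) ** (1 / WEIBULL_SHAPE)
        assert np.median(t) == pytest.approx(expected, rel=0.02)

    def test_proportional_hazards_scaling_of_median(self):
        # doubling exp(f) scales the median by 2^(-1/kappa); f = log(2) is
        # reached through the continuous confounder
        config = ScenarioConfig(scenario_id=1, hazard_variant="null")
        n = 40_000
        m = np.ones((n, 5))
        t0 = simulate_event_times(m, np.zeros((n, 2)), config, np.random.default_rng(5))
        c = np.column_stack([np.zeros(n), np.full(n, np.log(2) / 0.25)])
        t1 = simulate_event_times(m, c, config, np.random.default_rng(5))
        assert np.median(t1) / np.median(t0) == pytest.approx(
            2 ** (-1 / WEIBULL_SHAPE), rel=0.02
        )

    def test_all_times_positive_nonph(self):
        config = ScenarioConfig(scenario_id=4)
        rng = np.random.default_rng(6)
        z = _draw_latent(config, 2000, rng)
        m, c = _split_latent(z, 5)
        t = simulate_event_times(m, c, config, rng)
        assert np.all(t > 0)


class TestCensoring:
    def test_default_scenario1_near_target(self):
        ds = generate_dataset(ScenarioConfig(scenario_id=1, seed=0))
        assert 0.64 <= ds.censored_fraction <= 0.70

    def test_no_censoring_limit(self):
        config = ScenarioConfig(scenario_id=1)
        t, d = apply_censoring(np.array([1.0, 2.0, 3.0]), config,
                               np.random.default_rng(0), c_max=np.inf)
        assert np.all(d == 1)
        assert np.allclose(t, [1, 2, 3])

    def test_full_censoring_limit(self):
        config = ScenarioConfig(scenario_id=1)
        t, d = apply_censoring(np.array([1.0, 2.0, 3.0]), config,
                               np.random.default_rng(0), c_max=1e-12)
        assert np.all(d == 0)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="target_censoring"):
            ScenarioConfig(scenario_id=1, target_censoring=1.2)

    def test_calibration_across_replicates(self):
        # realized censored fraction stays within +/- 3 points of the target
        # across seeded replicates of every scenario structure
        for scenario in (1, 4):
            for seed in range(10):
                ds = generate_dataset(
                    ScenarioConfig(scenario_id=scenario, n_subjects=3000, seed=seed)
                )
                assert abs(ds.censored_fraction - 0.67) < 0.03


class TestGenerateDataset:
    def test_seeded_reproducibility(self):
        a = generate_dataset(ScenarioConfig(scenario_id=1, n_subjects=500, seed=7))
        b = generate_dataset(ScenarioConfig(scenario_id=1, n_subjects=500, seed=7))
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.event, b.event)
        assert a.exposures.equals(b.exposures)

    @pytest.mark.parametrize("scenario,j", [(1, 5), (2, 10), (3, 5), (4, 5)])
    def test_exposure_dimension(self, scenario, j):
        ds = generate_dataset(ScenarioConfig(scenario_id=scenario, n_subjects=200, seed=1))
        assert ds.exposures.shape == (200, j)
        assert ds.confounders.shape == (200, 2)
        assert np.all(ds.time > 0)

    def test_round_trip_frame(self):
        ds = generate_dataset(ScenarioConfig(scenario_id=1, n_subjects=100, seed=3))
        frame = ds.to_frame()
        back = type(ds).from_frame(frame)
        assert np.array_equal(back.time, ds.time)
        assert back.exposures.equals(ds.exposures.reset_index(drop=True))


class TestTruth:
    def test_null_variant_truth_is_null(self):
        truth = compute_truth(ScenarioConfig(scenario_id=1, hazard_variant="null"))
        assert truth.hr_mixture == 1.0
        assert truth.spd_mixture == 0.0

    def test_null_exposure_truth(self):
        truth = compute_truth(ScenarioConfig(scenario_id=1))
        assert truth.hr_single[1] == 1.0
        assert truth.spd_single[1] == 0.0
        # curve of the null exposure is flat across the quantile grid
        assert np.ptp(truth.curves[1]) == 0.0

    def test_interaction_truth_structure(self):
        truth = compute_truth(ScenarioConfig(scenario_id=1))
        # the DGP has one product interaction between exposures 1 and 5
        assert truth.interaction[0, 4] > 1.0
        assert truth.interaction[1, 2] == pytest.approx(1.0)
        assert np.allclose(truth.interaction, truth.interaction.T)

    def test_ph_scenario_hr_time_constant(self):
        truth = compute_truth(ScenarioConfig(scenario_id=1))
        assert truth.hr_mixture_at(2.0) == pytest.approx(
            truth.hr_mixture_at(15.0), rel=1e-8
        )

    def test_nonph_scenario_hr_varies(self):
        truth = compute_truth(ScenarioConfig(scenario_id=4))
        assert abs(truth.hr_mixture_at(2.0) - truth.hr_mixture_at(15.0)) > 0.05

    def test_survival_probabilities_valid(self):
        for scenario in (1, 2, 3, 4):
            truth = compute_truth(ScenarioConfig(scenario_id=scenario))
            assert np.all(truth.curves >= 0) and np.all(truth.curves <= 1)

    def test_true_survival_non_increasing_in_time(self):
        config = ScenarioConfig(scenario_id=4)
        m = np.array([[1.2, 0.9, 1.1, 1.4, 0.8]])
        c = np.array([[1.0, 0.3]])
        ts = np.linspace(0.1, 30, 40)
        s = np.array([true_survival(t, m, c, config)[0] for t in ts])
        assert np.all(np.diff(s) <= 1e-12)

    def test_quadrature_matches_closed_form_cumhaz(self):
        # numerical integration of the hazard reproduces the closed-form
        # cumulative hazard in both the PH and the time-varying case
        m = np.array([[1.2, 0.9, 1.1, 1.4, 0.8]])
        c = np.array([[1.0, 0.3]])
        for scenario in (1, 4):
            config = ScenarioConfig(scenario_id=scenario)

            def hazard(s):
                base = WEIBULL_RATE * WEIBULL_SHAPE * s ** (WEIBULL_SHAPE - 1)
                return base * np.exp(log_hazard_function(m, c, s, config)[0])

            for t in (5.0, 18.0):
                quad, _ = integrate.quad(hazard, 0, t, epsabs=1e-12, limit=200)
                closed = _cumulative_hazard(np.array([t]), m, c, config)[0]
                assert quad == pytest.approx(closed, abs=1e-8)

    def test_kaplan_meier_matches_average_true_survival(self):
        # on a large uncensored sample the Kaplan-Meier curve equals the
        # profile-averaged closed-form survival up to Monte-Carlo error
        from lifelines import KaplanMeierFitter

        config = ScenarioConfig(scenario_id=1)
        rng = np.random.default_rng(11)
        n = 20_000
        z = _draw_latent(config, n, rng)
        m, c = _split_latent(z, 5)
        t = simulate_event_times(m, c, config, rng)
        km = KaplanMeierFitter().fit(t, np.ones(n))
        for t0 in (5.0, 12.0, 20.0):
            expected = np.mean(true_survival(t0, m, c, config))
            observed = float(km.predict(t0))
            assert observed == pytest.approx(expected, abs=0.01)

    def test_reference_percentiles_match_lognormal_theory(self):
        quant, c_ref = _reference_marginals(5, "low_moderate")
        # marginals are exp(0.5 Z): quartiles at exp(+/- 0.5 * 0.6745)
        assert quant.loc[0.75, "M1"] == pytest.approx(np.exp(0.5 * 0.67449), rel=0.01)
        assert quant.loc[0.25, "M1"] == pytest.approx(np.exp(-0.5 * 0.67449), rel=0.01)
        assert c_ref[1] == pytest.approx(0.0, abs=0.01)
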