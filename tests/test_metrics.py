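"""Closed-form per-participant estimators and their algebraic identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coinlab as cl
from conftest import zero_noise_spec


def _toy_trials(mu_L, response, prior_cond="narrow", lik_cond="narrow", coin=None):
    mu_L = np.asarray(mu_L, dtype=float)
    response = np.asarray(response, dtype=float)
    n = len(mu_L)
    return pd.DataFrame(
        {
            "participant_id": "P0001",
            "task": "main",
            "block_index": 1,
            "trial_index": np.arange(1, n + 1),
            "prior_cond": prior_cond,
            "lik_cond": lik_cond,
            "mu_L": mu_L,
            "coin_pos": mu_L if coin is None else np.asarray(coin, dtype=float),
            "response": response,
        }
    )


class TestMeanEstimationError:
    def test_arithmetic(self):
        t = _toy_trials([0.0, 0.0], [0.1, 0.3])
        assert cl.mean_estimation_error(t, reference="centroid") == pytest.approx(0.2)
        assert cl.mean_estimation_error(t, reference="coin") == pytest.approx(0.2)
        exact = _toy_trials([0.2, -0.1], [0.2, -0.1])
        assert cl.mean_estimation_error(exact, reference="centroid") == 0.0

    def test_empty_filter_errors(self):
        t = _toy_trials([0.0], [0.1])
        with pytest.raises(ValueError):
            cl.mean_estimation_error(t, lik_cond="wide")

    def test_wide_condition_noisier_for_simulated_observer(self, design):
        cohort = cl.simulate_cohort(cl.CohortSpec(n_participants=3, seed=8), design)
        lo = cohort.trials_likonly
        wide = cl.mean_estimation_error(lo, reference="centroid", lik_cond="wide")
        narrow = cl.mean_estimation_error(lo, reference="centroid", lik_cond="narrow")
        assert wide > narrow


class TestSensoryWeight:
    def test_exact_line(self):
        x = np.linspace(-0.3, 0.3, 20)
        assert cl.fit_sensory_weight(_toy_trials(x, 0.3 * x)) == pytest.approx(0.3, abs=1e-12)

    def test_pure_prior_observer_has_zero_weight(self):
        x = np.linspace(-0.3, 0.3, 20)
        assert cl.fit_sensory_weight(_toy_trials(x, np.zeros(20))) == pytest.approx(0.0)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            cl.fit_sensory_weight(_toy_trials([0.1, 0.2], [0.0, 0.1]))  # < 3 trials
        with pytest.raises(ValueError):
            cl.fit_sensory_weight(_toy_trials([0.1] * 5, np.arange(5.0)))  # zero variance

    def test_zero_noise_ideal_observer_slope(self, design):
        prior_var, lik_var = 0.0016, design.centroid_var("narrow")
        w = prior_var / (prior_var + lik_var)
        rng = np.random.default_rng(9)
        coin = cl.sample_coin_position(design, "narrow", rng, size=2000)
        _, mu_L = cl.sample_splashes(design, coin, "narrow", rng)
        fitted = cl.fit_sensory_weight(_toy_trials(mu_L, w * mu_L))
        assert fitted == pytest.approx(0.4647, abs=1e-3)
        assert fitted == pytest.approx(w, abs=1e-10)


class TestOptimalBenchmarks:
    def test_condition_values(self, design):
        bench = cl.optimal_benchmarks(design)["sw_opt"]
        assert bench["PnLn"] == pytest.approx(0.4647, abs=5e-4)
        assert bench["PnLw"] == pytest.approx(0.1220, abs=5e-4)
        assert bench["PwLn"] == pytest.approx(0.9094, abs=5e-4)
        assert bench["PwLw"] == pytest.approx(0.6162, abs=5e-4)
        assert bench["PwLn"] > bench["PwLw"] > bench["PnLn"] > bench["PnLw"]

    def test_equal_variances_give_half(self):
        d = cl.make_design(
            prior_sd_narrow=0.1, prior_sd_wide=0.3, splash_sd_narrow=0.1 * math.sqrt(5),
            splash_sd_wide=0.9,
        )
        assert cl.optimal_sensory_weight(d, "narrow", "narrow") == pytest.approx(0.5)

    def test_monotone_in_both_variances(self):
        priors = np.linspace(0.02, 0.3, 8)
        ws = [
            pv**2 / (pv**2 + 0.002)
            for pv in priors
        ]
        assert np.all(np.diff(ws) > 0)
        d = cl.make_design()
        assert cl.optimal_sensory_weight(d, "narrow", "narrow") > cl.optimal_sensory_weight(
            d, "narrow", "wide"
        )

    def test_literal_mode(self, design):
        w = cl.optimal_sensory_weight(design, "narrow", "narrow", variance_mode="literal")
        assert w == pytest.approx(0.0016 / (0.0016 + 0.09625))
        with pytest.raises(ValueError):
            cl.optimal_sensory_weight(
                cl.make_design(splash_sd_narrow=0.1), "narrow", "narrow", variance_mode="literal"
            )


class TestSensitivityToPriorChange:
    @pytest.mark.parametrize(
        "slopes,expected",
        [
            ([0.2, 0.6, 0.2, 0.6], 0.4),
            ([0.5, 0.5, 0.5, 0.5], 0.0),
            ([0.0, 1.0, 0.0, 1.0], 1.0),
        ],
    )
    def test_values(self, slopes, expected):
        assert cl.sensitivity_to_prior_change(slopes) == pytest.approx(expected)

    def test_missing_block_errors(self):
        with pytest.raises(ValueError):
            cl.sensitivity_to_prior_change([0.2, np.nan, 0.3, 0.4])


class TestTrialSensoryWeight:
    def test_closed_form_values(self):
        raw, logistic = cl.trial_sensory_weight(0.2, 0.2)  # response at the centroid
        assert (raw, logistic) == (pytest.approx(1.0), pytest.approx(1 / (1 + math.exp(-1))))
        raw, logistic = cl.trial_sensory_weight(0.0, 0.2)  # response at the prior mean
        assert (raw, logistic) == (pytest.approx(0.0), pytest.approx(0.5))
        raw, logistic = cl.trial_sensory_weight(0.4, 0.2)  # overshoot
        assert (raw, logistic) == (pytest.approx(2.0), pytest.approx(1 / (1 + math.exp(-2))))

    def test_degenerate_trial_is_missing(self):
        raw, logistic = cl.trial_sensory_weight(0.1, 0.0, mu_P=0.0)
        assert math.isnan(raw) and math.isnan(logistic)

    def test_variance_of_half_half_weights(self):
        n = 200
        mu_L = np.full(n, 0.2)
        resp = np.where(np.arange(n) % 2 == 0, 0.2, 0.0)  # raw weights 1 and 0
        t = _toy_trials(mu_L, resp)
        expected = np.var([0.5, 1 / (1 + math.exp(-1))])  # two-point distribution
        assert cl.trial_sw_variance(t) == pytest.approx(expected, rel=0.02)

    def test_constant_weights_have_zero_variance(self):
        t = _toy_trials(np.full(10, 0.2), np.full(10, 0.15))
        assert cl.trial_sw_variance(t) == pytest.approx(0.0, abs=1e-20)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_variance_bounded_by_quarter(self, seed):
        r = np.random.default_rng(seed)
        t = _toy_trials(r.normal(0, 0.2, 50), r.normal(0, 0.5, 50))
        assert 0.0 <= cl.trial_sw_variance(t) <= 0.25


class TestSubjectiveVariances:
    def test_likelihood_variance_arithmetic(self):
        t = _toy_trials([0.0, 0.0], [0.1, -0.1], lik_cond="narrow")
        assert cl.subjective_likelihood_variance(t) == pytest.approx(0.01)

    def test_likelihood_variance_recovers_encoding_noise(self, design):
        s = 0.05
        spec = cl.CohortSpec(
            n_participants=3, seed=10, perceptual_noise_sd=s, motor_noise_sd=0.0, lapse_rate=0.0
        )
        big = cl.make_design(n_likelihood_only_trials=10_000)
        cohort = cl.simulate_cohort(spec, big)
        one = cohort.trials_likonly[cohort.trials_likonly["participant_id"] == "P0001"]
        est = cl.subjective_likelihood_variance(one)
        assert est == pytest.approx(s**2, rel=0.05)

    def test_prior_variance_symmetry_point(self):
        assert cl.subjective_prior_variance(0.004, 0.5) == pytest.approx(0.004)

    @given(
        st.floats(1e-6, 1.0),
        st.floats(1e-6, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inversion_round_trip(self, prior_var, lik_var):
        sw = prior_var / (prior_var + lik_var)
        assert cl.subjective_prior_variance(lik_var, sw) == pytest.approx(
            prior_var, rel=1e-9, abs=1e-12
        )

    def test_imposed_variant_returns_true_prior_variance(self, design):
        for lc in ("narrow", "wide"):
            assert cl.imposed_prior_variance(design, "narrow", lc) == pytest.approx(0.0016)
            assert cl.imposed_prior_variance(design, "wide", lc) == pytest.approx(0.136**2)

    def test_out_of_range_weights(self):
        assert math.isnan(cl.subjective_prior_variance(0.01, 1.0))
        assert math.isnan(cl.subjective_prior_variance(0.01, 1.5))
        with pytest.warns(UserWarning):
            assert cl.subjective_prior_variance(0.01, -0.2) == 0.0


class TestExclusions:
    def test_single_extreme_value_flagged(self):
        base = pd.Series([0.05] * 20 + [0.06] * 20 + [5.0])
        flags = cl.exclude_outliers(base)
        assert flags.sum() == 1 and bool(flags.iloc[-1])

    def test_no_variance_no_flags(self):
        assert cl.exclude_outliers(pd.Series([0.1] * 10)).sum() == 0

    def test_flag_rate_matches_gaussian_expectation(self):
        rng = np.random.default_rng(13)
        flags = sum(
            cl.exclude_outliers(pd.Series(rng.standard_normal(1000))).sum() for _ in range(30)
        )
        n = 30 * 1000
        p = 2 * 0.0013499  # P(|Z| > 3)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(flags / n - p) < 4 * se


class TestComputeAllMetrics:
    def test_zero_noise_closure(self, design):
        spec = zero_noise_spec(n_participants=5, seed=14, sigma_between=0.4)
        cohort = cl.simulate_cohort(spec, design)
        m = cl.compute_all_metrics(cohort.trials_main, cohort.trials_likonly, design)
        m = m.set_index("participant_id")
        for obs in cohort.observers:
            for c, (pc, lc) in {
                "PnLn": ("narrow", "narrow"),
                "PnLw": ("narrow", "wide"),
                "PwLn": ("wide", "narrow"),
                "PwLw": ("wide", "wide"),
            }.items():
                assert abs(
                    m.loc[obs.participant_id, f"sw_{c}"] - obs.generating_weight(pc, lc)
                ) < 1e-8

    def test_idempotent(self, design, default_cohort, default_metrics):
        again = cl.compute_all_metrics(
            default_cohort.trials_main, default_cohort.trials_likonly, design
        )
        pd.testing.assert_frame_equal(default_metrics, again)

    def test_group_mean_weight_ordering(self, default_metrics):
        kept = default_metrics[~default_metrics["excluded"]]
        sw = {c: kept[f"sw_{c}"].mean() for c in cl.CONDITION_LABELS}
        assert (sw["PwLn"] + sw["PwLw"]) / 2 > (sw["PnLn"] + sw["PnLw"]) / 2  # prior effect
        assert (sw["PnLn"] + sw["PwLn"]) / 2 > (sw["PnLw"] + sw["PwLw"]) / 2  # likelihood effect

    def test_missing_task_flagged(self, design):
        cohort = cl.simulate_cohort(cl.CohortSpec(n_participants=4, seed=15), design)
        partial_main = cohort.trials_main[cohort.trials_main["participant_id"] != "P0002"]
        m = cl.compute_all_metrics(partial_main, cohort.trials_likonly, design)
        row = m[m["participant_id"] == "P0002"].iloc[0]
        assert row["excluded"] and row["exclusion_reason"] == "missing_task"
        assert math.isnan(row["sw_global"])
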