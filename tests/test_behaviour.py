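import numpy as np
import pandas as pd
import pytest

from pavo2.agent import AgentParams, simulate_agent
from pavo2.behaviour import (
    BOUNDS,
    FULL_SPEC,
    STANDARD_SPEC,
    FitResult,
    ModelSpec,
    compare_models,
    default_grid,
    fit_model,
    negloglik,
    predict_responses,
    recency_baseline,
    rw_update,
)
from pavo2.task import Counterbalance, Regime, generate_schedule


def make_trace(n_sessions=2, seed=5, **agent_overrides):
    scheds = [
        generate_schedule(i, Counterbalance.CL1_T2, Regime.TRAINING, seed=seed)
        for i in range(1, n_sessions + 1)
    ]
    params = AgentParams(**agent_overrides)
    return simulate_agent(scheds, params, seed=seed), params


class TestRwUpdate:
    @pytest.mark.parametrize(
        "v,r,alpha,expected",
        [(0.0, 1, 0.1, 0.1), (0.5, 0, 0.2, 0.4), (1.0, 1, 0.5, 1.0)],
    )
    def test_arithmetic(self, v, r, alpha, expected):
        assert rw_update(v, r, alpha) == pytest.approx(expected)

    def test_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        v = 0.3
        for _ in range(200):
            v = rw_update(v, int(rng.random() < 0.75), 0.9)
            assert 0.0 <= v <= 1.0

    def test_fixed_point_zero_drift_at_reward_probability(self):
        """At V = p the expected update is zero: p*(1-V) + (1-p)*(0-V) = 0."""
        p, v = 0.75, 0.75
        drift = p * (rw_update(v, 1, 0.1) - v) + (1 - p) * (rw_update(v, 0, 0.1) - v)
        assert drift == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            rw_update(0.5, 1, alpha)


class TestRecencyBaseline:
    def test_gamma_zero_tracks_previous_rate(self):
        rates = np.array([1.0, 4.0, 2.0, 8.0])
        b = recency_baseline(rates, gamma=0.0, b0=9.0)
        np.testing.assert_allclose(b, [9.0, 1.0, 4.0, 2.0])

    def test_gamma_one_frozen_at_b0(self):
        b = recency_baseline(np.arange(10.0), gamma=1.0, b0=3.0)
        np.testing.assert_allclose(b, 3.0)

    @pytest.mark.parametrize("gamma", [0.2, 0.5, 0.9])
    def test_converges_to_constant_rate(self, gamma):
        b = recency_baseline(np.full(500, 2.5), gamma=gamma, b0=0.0)
        assert b[-1] == pytest.approx(2.5, abs=1e-6)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            recency_baseline(np.ones(3), gamma=1.5, b0=0.0)


class TestPredictResponses:
    def test_hand_unrolled_standard_model(self):
        trace = pd.DataFrame(
            {
                "cue": ["CS_High"] * 3,
                "sound": ["tone"] * 3,
                "rewarded": [1, 1, 0],
                "pre_cue_rate": [0.0] * 3,
                "session": [1] * 3,
            }
        )
        params = {"alpha": 0.5, "gain": 1.0}
        pred, lat = predict_responses(trace, params, STANDARD_SPEC)
        np.testing.assert_allclose(pred, [0.0, 0.5, 0.75])
        np.testing.assert_allclose(lat["v_post"], [0.5, 0.75, 0.375])

    def test_cue_specific_k_dominates_when_value_is_negligible(self):
        trace = pd.DataFrame(
            {
                "cue": ["CS_High", "CS_Low"],
                "sound": ["clicker", "tone"],
                "rewarded": [1, 0],
                "pre_cue_rate": [0.0, 0.0],
                "session": [1, 1],
            }
        )
        spec = ModelSpec(k_mode="cue_specific")
        params = {"alpha": 0.1, "gain": 0.0, "k_clicker": 3.0, "k_tone": 1.0}
        pred, _ = predict_responses(trace, params, spec)
        np.testing.assert_allclose(pred, [3.0, 1.0])

    def test_output_shape_matches_schedule(self):
        trace, _ = make_trace(n_sessions=1)
        for spec in default_grid():
            params = {p: 0.5 if p not in ("gain",) else 1.0
                      for p in spec.param_names if p != "sigma"}
            pred, lat = predict_responses(trace, params, spec)
            assert len(pred) == 56
            assert len(lat) == 56

    def test_missing_parameter_raises_named_error(self):
        trace, _ = make_trace(n_sessions=1)
        with pytest.raises(KeyError, match="alpha"):
            predict_responses(trace, {"gain": 1.0}, STANDARD_SPEC)

    def test_value_trajectory_matches_bruteforce_loop(self):
        """V from the vectorised path equals a naive trial loop to 1e-12."""
        trace, _ = make_trace(n_sessions=2)
        spec = FULL_SPEC
        params = {"alpha": 0.17, "beta_clicker": 1.8, "gamma_recency": 0.6,
                  "gain": 2.0, "k_clicker": 1.0, "k_tone": 0.3}
        _, lat = predict_responses(trace, params, spec)
        v = {"CS_High": 0.0, "CS_Low": 0.0}
        for i, row in trace.iterrows():
            assert abs(lat["v_pre"].iloc[i] - v[row["cue"]]) < 1e-12
            beta = params["beta_clicker"] if row["sound"] == "clicker" else 1.0
            a = min(params["alpha"] * beta, 1.0)
            v[row["cue"]] += a * (row["rewarded"] - v[row["cue"]])


class TestNegLogLik:
    def test_zero_residuals_closed_form(self):
        trace = pd.DataFrame(
            {
                "cue": ["CS_High"] * 2,
                "sound": ["tone"] * 2,
                "rewarded": [1, 1],
                "pre_cue_rate": [0.0] * 2,
                "cue_rate": [0.0, 0.5],   # exactly the model prediction
                "session": [1, 1],
            }
        )
        params = {"alpha": 0.5, "gain": 1.0, "sigma": 1.0}
        assert negloglik(trace, params, STANDARD_SPEC) == pytest.approx(
            np.log(2 * np.pi)
        )

    def test_matches_direct_sum_oracle(self):
        """NLL equals an independently coded direct sum on a 10-trial fixture."""
        trace, _ = make_trace(n_sessions=1)
        trace = trace.iloc[:10].reset_index(drop=True)
        params = {"alpha": 0.3, "gain": 2.0, "sigma": 1.7}
        pred, _ = predict_responses(trace, params, STANDARD_SPEC)
        sigma = params["sigma"]
        oracle = -sum(
            -0.5 * np.log(2 * np.pi * sigma**2)
            - (y - mu) ** 2 / (2 * sigma**2)
            for y, mu in zip(trace["cue_rate"], pred)
        )
        assert negloglik(trace, params, STANDARD_SPEC) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_doubling_residuals_at_profiled_sigma(self):
        """Doubling residuals raises the profiled-sigma NLL by n*ln 2."""
        trace, _ = make_trace(n_sessions=1)
        params = {"alpha": 0.3, "gain": 2.0}
        pred, _ = predict_responses(trace, params, STANDARD_SPEC)
        resid = trace["cue_rate"].to_numpy() - pred
        n = len(resid)

        def profiled_nll(r):
            s = np.sqrt(np.mean(r**2))
            return 0.5 * n * np.log(2 * np.pi * s**2) + (r @ r) / (2 * s**2)

        assert profiled_nll(2 * resid) - profiled_nll(resid) == pytest.approx(
            n * np.log(2)
        )

    def test_nonpositive_sigma_rejected(self):
        trace, _ = make_trace(n_sessions=1)
        with pytest.raises(ValueError):
            negloglik(trace, {"alpha": 0.3, "gain": 1.0, "sigma": 0.0},
                      STANDARD_SPEC)


class TestFitModel:
    def test_recovers_alpha_from_noiseless_standard_data(self):
        trace, _ = make_trace(
            n_sessions=2, alpha=0.15, beta_clicker=1.0, k_clicker=0.0,
            k_tone=0.0, response_gain=5.0, noise_sd=0.0,
            baseline_mean=0.0, baseline_sd=0.0, gamma_recency=0.5,
        )
        fit = fit_model(trace, STANDARD_SPEC, n_restarts=10, seed=1)
        assert fit.params["alpha"] == pytest.approx(0.15, abs=0.02)

    def test_bic_identity_exact(self):
        trace, _ = make_trace(n_sessions=1)
        fit = fit_model(trace, STANDARD_SPEC, n_restarts=3, seed=0)
        assert fit.bic - (fit.n_params * np.log(fit.n_obs) + 2 * fit.nll) == 0.0
        assert fit.n_params == 3  # alpha, gain, sigma

    def test_n_params_per_spec(self):
        assert STANDARD_SPEC.n_params == 3
        assert FULL_SPEC.n_params == 7  # alpha, beta, gamma, gain, 2x k, sigma
        assert ModelSpec(split_alpha=True, k_mode="shared").n_params == 5

    def test_nested_model_never_beats_parent(self):
        """Best NLL of a nested spec is >= its parent's (shared restarts)."""
        trace, _ = make_trace(n_sessions=2, seed=8)
        nested = fit_model(trace, STANDARD_SPEC, n_restarts=10, seed=3)
        parent = fit_model(trace, FULL_SPEC, n_restarts=10, seed=3)
        assert parent.nll <= nested.nll + 1e-6

    def test_extra_parameter_raises_bic_at_equal_fit(self):
        """A spec with more parameters pays a higher BIC when NLL ties."""
        trace, _ = make_trace(n_sessions=1, seed=2)
        fit = fit_model(trace, STANDARD_SPEC, n_restarts=5, seed=0)
        richer = ModelSpec(split_alpha=True)
        penalty = (richer.n_params - STANDARD_SPEC.n_params) * np.log(fit.n_obs)
        bic_if_equal_fit = richer.n_params * np.log(fit.n_obs) + 2 * fit.nll
        assert bic_if_equal_fit == pytest.approx(fit.bic + penalty)

    def test_deterministic_given_seed(self):
        trace, _ = make_trace(n_sessions=1)
        a = fit_model(trace, FULL_SPEC, n_restarts=4, seed=11)
        b = fit_model(trace, FULL_SPEC, n_restarts=4, seed=11)
        assert a.nll == b.nll
        assert a.params == b.params

    def test_invalid_restarts_rejected(self):
        trace, _ = make_trace(n_sessions=1)
        with pytest.raises(ValueError):
            fit_model(trace, STANDARD_SPEC, n_restarts=0)


class TestCompareModels:
    def test_single_animal_strictly_better_spec_counted(self):
        trace, _ = make_trace(n_sessions=2, seed=4)
        grid = [STANDARD_SPEC, FULL_SPEC]
        out = compare_models({"a1": trace}, grid, n_restarts=5, seed=0)
        winner = out["best_per_animal"]["a1"]
        assert out["win_counts"][winner.label] == 1
        assert sum(out["win_counts"].values()) == 1

    def test_exact_bic_tie_goes_to_fewer_parameters(self, monkeypatch):
        import pavo2.behaviour as bh

        specs = [ModelSpec(split_alpha=True), STANDARD_SPEC]

        def fake_fit(trace, spec, n_restarts=1, seed=0):
            return FitResult(spec=spec, params={}, nll=10.0, bic=100.0,
                             n_obs=56, n_params=spec.n_params,
                             latents=pd.DataFrame())

        monkeypatch.setattr(bh, "fit_model", fake_fit)
        out = bh.compare_models({"a1": pd.DataFrame()}, specs, n_restarts=1)
        assert out["best_per_animal"]["a1"] == STANDARD_SPEC
        assert out["population_preferred"] == STANDARD_SPEC

    def test_requires_two_specs(self):
        with pytest.raises(ValueError):
            compare_models({"a1": pd.DataFrame()}, [STANDARD_SPEC])
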