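import numpy as np
import pandas as pd
import pytest

from pavo2.glm import (
    GlmResult,
    RankDeficientDesignError,
    build_design,
    fit_glm,
    group_effects,
    rpe_criteria_check,
    value_vs_behaviour_comparison,
)


def latents_frame(n=56, seed=0, all_rewarded=False):
    rng = np.random.default_rng(seed)
    r = np.ones(n, int) if all_rewarded else (rng.random(n) < 0.5).astype(int)
    v = rng.uniform(0.1, 0.9, n)
    return pd.DataFrame({
        "session": 1, "trial": np.arange(1, n + 1),
        "rewarded": r, "v_pre": v, "v_post": v + 0.1 * (r - v),
    })


def auc_frame(latents, y):
    return pd.DataFrame({
        "session": latents["session"], "trial": latents["trial"],
        "cue": "CS_High", "rewarded": latents["rewarded"], "auc": y,
    })


class TestBuildDesign:
    def test_cue_value_design_shape(self):
        lat = latents_frame()
        X, y = build_design(lat, auc_frame(lat, np.arange(56.0)), "cue_value")
        assert X.shape == (56, 2)
        assert list(X.columns) == ["const", "v"]
        assert len(y) == 56

    def test_outcome_rpe_has_reward_and_value_columns(self):
        lat = latents_frame()
        X, _ = build_design(lat, auc_frame(lat, np.arange(56.0)), "outcome_rpe")
        assert list(X.columns) == ["const", "r", "v_prev"]

    def test_constant_reward_column_flagged_rank_deficient(self):
        lat = latents_frame(all_rewarded=True)
        with pytest.raises(RankDeficientDesignError):
            build_design(lat, auc_frame(lat, np.arange(56.0)), "outcome_rpe")

    def test_unsigned_pe_value(self):
        lat = latents_frame(n=8, seed=1)
        lat.loc[0, ["rewarded", "v_pre"]] = [0, 0.75]
        X, _ = build_design(lat, auc_frame(lat, np.arange(8.0)),
                            "outcome_unsigned")
        # z-scoring preserves order; verify via the raw quantity
        raw = (lat["rewarded"] - lat["v_pre"]).abs()
        assert raw.iloc[0] == pytest.approx(0.75)
        assert np.argsort(X["unsigned_pe"].to_numpy()).tolist() == \
            np.argsort(raw.to_numpy()).tolist()

    def test_unknown_kind_rejected(self):
        lat = latents_frame()
        with pytest.raises(ValueError):
            build_design(lat, auc_frame(lat, np.arange(56.0)), "quadratic")


class TestFitGlm:
    def test_noiseless_linear_response_recovered_exactly(self):
        lat = latents_frame(seed=3)
        y = 2.0 * lat["v_pre"] + 1.0
        X, ys = build_design(lat, auc_frame(lat, y), "cue_value")
        res = fit_glm(X, ys)
        assert res.r2 == pytest.approx(1.0)
        assert res.betas["v"] == pytest.approx(1.0)  # standardized slope of exact fit

    def test_permuted_response_gives_null_beta(self):
        lat = latents_frame(seed=4, n=200)
        y = 2.0 * lat["v_pre"]
        rng = np.random.default_rng(0)
        X, ys = build_design(lat, auc_frame(lat, rng.permutation(y.to_numpy())),
                             "cue_value")
        res = fit_glm(X, ys)
        assert abs(res.betas["v"]) < 0.2

    def test_betas_match_normal_equations_oracle(self):
        """OLS solution equals (X'X)^-1 X'y on a random 50x3 fixture."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"const": 1.0, "a": rng.standard_normal(50),
                          "b": rng.standard_normal(50)})
        y = pd.Series(rng.standard_normal(50))
        res = fit_glm(X, y)
        Xm = X.to_numpy()
        oracle = np.linalg.solve(Xm.T @ Xm, Xm.T @ y.to_numpy())
        got = np.array([res.betas[c] for c in X.columns])
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_too_few_trials_rejected(self):
        X = pd.DataFrame({"const": np.ones(4), "a": np.arange(4.0)})
        with pytest.raises(ValueError):
            fit_glm(X, pd.Series(np.arange(4.0)))


def make_result(region, beta, p, coef="v", kind="cue_value", eid="e"):
    return GlmResult(electrode_id=eid, region=region, design_kind=kind,
                     betas={coef: beta}, se={coef: 0.1}, pvalues={coef: p},
                     n_trials=56, r2=0.5)


class TestGroupEffects:
    def test_identical_betas_zero_sem(self):
        res = [make_result("NAc", 0.5, 0.01, eid=f"e{i}") for i in range(4)]
        out = group_effects(res, "v")
        assert out["sem"].iloc[0] == 0.0
        assert out["mean_beta"].iloc[0] == 0.5

    def test_too_few_electrodes_rejected(self):
        res = [make_result("NAc", 0.5, 0.01, eid=f"e{i}") for i in range(2)]
        with pytest.raises(ValueError, match="electrodes"):
            group_effects(res, "v")


class TestRpeCriteria:
    def _glms(self, v_cue, r_out, v_out, spread=0.02):
        cue = [make_result("NAc", v_cue + spread * i, 0.0, coef="v", eid=f"c{i}")
               for i in range(-2, 3)]
        out = []
        for i in range(-2, 3):
            g = make_result("NAc", 0.0, 0.0, coef="r", eid=f"o{i}",
                            kind="outcome_rpe")
            g.betas = {"r": r_out + spread * i, "v_prev": v_out + spread * i}
            g.se = {"r": 0.1, "v_prev": 0.1}
            g.pvalues = {"r": 0.0, "v_prev": 0.0}
            out.append(g)
        return cue, out

    def test_positive_positive_negative_passes_all(self):
        cue, out = self._glms(0.4, 0.5, -0.3)
        assert rpe_criteria_check(cue, out) == {
            "positive_cue_value": True,
            "positive_outcome": True,
            "negative_value_at_outcome": True,
        }

    def test_positive_value_at_outcome_fails_third(self):
        cue, out = self._glms(0.4, 0.5, +0.3)
        crit = rpe_criteria_check(cue, out)
        assert crit["negative_value_at_outcome"] is False
        assert crit["positive_outcome"] is True

    def test_null_betas_fail_everything(self):
        cue, out = self._glms(0.0, 0.0, 0.0, spread=0.05)
        assert set(rpe_criteria_check(cue, out).values()) == {False}

    def test_mixed_regions_rejected(self):
        cue, out = self._glms(0.4, 0.5, -0.3)
        cue[0].region = "OFC"
        with pytest.raises(ValueError):
            rpe_criteria_check(cue, out)


class TestValueVsBehaviour:
    def test_value_generated_response_favours_value(self):
        lat = latents_frame(n=200, seed=5)
        rng = np.random.default_rng(1)
        y = 3.0 * lat["v_pre"] + 0.3 * rng.standard_normal(200)
        he = lat[["session", "trial"]].assign(
            cue_rate=2.0 * lat["v_pre"] + rng.standard_normal(200)
        )
        out = value_vs_behaviour_comparison(auc_frame(lat, y), lat, he)
        assert out["delta_bic"].iloc[0] < 0

    def test_behaviour_generated_response_reverses(self):
        lat = latents_frame(n=200, seed=6)
        rng = np.random.default_rng(2)
        rate = 2.0 * lat["v_pre"] + rng.standard_normal(200)
        he = lat[["session", "trial"]].assign(cue_rate=rate)
        y = 3.0 * rate + 0.3 * rng.standard_normal(200)
        out = value_vs_behaviour_comparison(auc_frame(lat, y), lat, he)
        assert out["delta_bic"].iloc[0] > 0

    def test_identical_regressors_tie(self):
        lat = latents_frame(n=100, seed=7)
        he = lat[["session", "trial"]].assign(cue_rate=lat["v_pre"])
        y = lat["v_pre"] * 1.5 + 0.1
        out = value_vs_behaviour_comparison(auc_frame(lat, y), lat, he)
        assert out["delta_bic"].iloc[0] == pytest.approx(0.0, abs=1e-8)
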