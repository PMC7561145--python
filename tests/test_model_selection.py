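import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from gulldiet import (
    aicc,
    build_profiles,
    build_responses,
    fit_binomial_glm,
    qaicc,
    rank_and_average,
)
from gulldiet.model_selection import (
    CandidateModel,
    DispersionEstimate,
    FitError,
    covariate_frame,
    estimate_c_hat,
    fit_all_subsets,
    select_models,
)

from conftest import pellet, visit


def frame(successes, trials, **covs):
    df = pd.DataFrame({"successes": successes, "trials": trials})
    for k, v in covs.items():
        df[k] = v
    return df


class TestGLM:
    def test_intercept_only_recovers_logit_mean(self):
        data = frame([5] * 10, [10] * 10)
        fit = fit_binomial_glm(data, [])
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)

    def test_binary_predictor_closed_form(self):
        x = [0] * 5 + [1] * 5
        data = frame([2] * 5 + [8] * 5, [10] * 10, x=x)
        fit = fit_binomial_glm(data, ["x"])
        assert fit.params[1] == pytest.approx(logit(0.8) - logit(0.2), abs=1e-6)
        assert fit.params[1] == pytest.approx(2.77, abs=0.01)

    def test_separation_raises(self):
        x = [0] * 5 + [1] * 5
        data = frame([0] * 5 + [10] * 5, [10] * 10, x=x)
        with pytest.raises(FitError):
            fit_binomial_glm(data, ["x"])

    def test_effect_recovery(self):
        """beta=1.5 on a binary covariate is recovered across replicates."""
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(50):
            x = rng.random(30) < 0.5
            p = 1 / (1 + np.exp(-(-0.5 + 1.5 * x)))
            data = frame(rng.binomial(20, p), [20] * 30, x=x.astype(float))
            fit = fit_binomial_glm(data, ["x"])
            errs.append(fit.params[1] - 1.5)
        assert abs(np.mean(errs)) < 3 * np.std(errs) / np.sqrt(len(errs)) + 0.05


class TestDispersion:
    def test_pearson_over_df(self):
        rng = np.random.default_rng(1)
        data = frame(rng.binomial(20, 0.5, 30), [20] * 30)
        fit = fit_binomial_glm(data, [])
        est = estimate_c_hat(fit)
        assert est.c_hat == pytest.approx(float(fit.pearson_chi2) / fit.df_resid)

    def test_floor_at_one(self):
        assert DispersionEstimate(0.7, "global").effective == 1.0
        assert not DispersionEstimate(0.7, "global").estimated
        assert DispersionEstimate(1.5, "global").effective == 1.5

    def test_no_overdispersion_on_clean_binomial(self):
        """Well-specified binomial data has c-hat near 1 on average."""
        rng = np.random.default_rng(2)
        chats = []
        for _ in range(100):
            data = frame(rng.binomial(25, 0.4, 40), [25] * 40)
            chats.append(estimate_c_hat(fit_binomial_glm(data, [])).c_hat)
        assert np.mean(chats) == pytest.approx(1.0, abs=0.1)


class TestInformationCriteria:
    def test_formula_arithmetic(self):
        assert qaicc(-10, 1.0, 3, 20) == pytest.approx(27.5)
        assert qaicc(-10, 2.0, 3, 20) == pytest.approx(17.5)

    def test_reduces_to_aicc(self):
        assert qaicc(-12.3, 1.0, 4, 25) == pytest.approx(aicc(-12.3, 4, 25), abs=1e-12)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            qaicc(-10, 1.0, 5, 6)


class TestRanking:
    @staticmethod
    def candidates(qaiccs, terms):
        return [
            CandidateModel(terms=t, K=1 + len(t), loglik=0.0, qaicc=q)
            for q, t in zip(qaiccs, terms)
        ]

    def test_two_model_weights(self):
        ranked, _ = rank_and_average(
            self.candidates([10.0, 12.0], [("a",), ()])
        )
        assert ranked["weight"].tolist() == pytest.approx([0.731, 0.269], abs=0.001)
        assert ranked["delta"].tolist() == [0.0, 2.0]

    def test_weights_sum_to_one(self):
        ranked, _ = rank_and_average(
            self.candidates([3.0, 3.5, 4.0, 9.0], [("a",), ("a", "b"), (), ("b",)])
        )
        assert ranked["weight"].sum() == pytest.approx(1.0)

    def test_relative_importance_renormalized_in_delta2_set(self):
        # three models inside delta<=2, one far outside
        cands = self.candidates(
            [0.0, 1.0, 1.8, 30.0], [("s",), ("s", "t"), (), ("t",)]
        )
        ranked, ri = rank_and_average(cands)
        w = np.exp(-ranked["delta"] / 2)
        w = w / w.sum()
        in_set = ranked["delta"] <= 2
        set_w = w[in_set].sum()
        expected_s = w[in_set & ranked["terms"].map(lambda t: "s" in t)].sum() / set_w
        ri_s = ri.set_index("predictor").loc["s", "relative_importance"]
        assert ri_s == pytest.approx(float(expected_s))

    def test_full_set_convention(self):
        cands = self.candidates([0.0, 1.0, 30.0], [("s",), (), ("s", "t")])
        _, ri = rank_and_average(cands, renormalize_ri=False)
        by = ri.set_index("predictor")["relative_importance"]
        w = np.exp(-np.array([0.0, 1.0, 30.0]) / 2)
        w /= w.sum()
        assert by["s"] == pytest.approx(w[0] + w[2])

    def test_ranking_invariant_to_loglik_shift(self):
        rng = np.random.default_rng(5)
        lls = rng.normal(-20, 3, size=8)
        terms = [(f"t{i}",) for i in range(8)]
        q1 = [qaicc(ll, 1.0, 2, 30) for ll in lls]
        q2 = [qaicc(ll + 7.0, 1.0, 2, 30) for ll in lls]
        r1, _ = rank_and_average(self.candidates(q1, terms))
        r2, _ = rank_and_average(self.candidates(q2, terms))
        assert r1["model"].tolist() == r2["model"].tolist()
        assert r1["weight"].tolist() == pytest.approx(r2["weight"].tolist())

    def test_delta_zero_unique_tie_broken_by_K(self):
        cands = [
            CandidateModel(terms=("a", "b"), K=3, loglik=0.0, qaicc=5.0),
            CandidateModel(terms=("a",), K=2, loglik=0.0, qaicc=5.0),
        ]
        ranked, _ = rank_and_average(cands)
        assert ranked.loc[0, "model"] == "a"  # fewer parameters wins the tie
        assert ranked.loc[0, "K"] == 2


class TestResponses:
    def test_pellet_mode(self):
        pellets = [pellet(fractions=(0, 0, 0, 0, 1, 0)) for _ in range(4)]
        pellets += [pellet(fractions=(1, 0, 0, 0, 0, 0)) for _ in range(6)]
        profiles = build_profiles(pellets)
        df = build_responses(profiles, [], "pellet")
        assert df.iloc[0].tolist() == ["T01", 4, 10]

    def test_carcass_mode(self):
        visits = [
            visit(date="2009-06-01", counts={"c": 1}),
            visit(date="2009-06-07", counts={}),
            visit(date="2009-06-13", counts={"c": 2}),
        ]
        df = build_responses({}, visits, "carcass")
        assert df.iloc[0].tolist() == ["T01", 2, 3]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            build_responses({}, [], "isotope")

    def test_treatment_group_means_recovered(self):
        """Near-colony pairs show the configured higher bird-pellet share."""
        from gulldiet.simulate import paper_regime, simulate_colony

        shares = {"near": [], "away": []}
        for s in range(12):
            res = simulate_colony(paper_regime("gull_island_2015", seed=s))
            profiles = build_profiles(res.tables["pellets"])
            df = build_responses(profiles, [], "pellet")
            treat = {t.territory_id: t.treatment for t in res.tables["territories"]}
            df["treatment"] = df["territory_id"].map(treat)
            g = df.groupby("treatment").sum(numeric_only=True)
            for grp in shares:
                shares[grp].append(g.loc[grp, "successes"] / g.loc[grp, "trials"])
        assert np.mean(shares["near"]) > np.mean(shares["away"])
        assert np.mean(shares["near"]) == pytest.approx(0.67, abs=0.06)
        assert np.mean(shares["away"]) == pytest.approx(0.51, abs=0.06)


class TestEndToEnd:
    def test_select_models_on_synthetic_colony(self, colony_2009):
        profiles = build_profiles(
            colony_2009.tables["pellets"], colony_2009.tables["carcasses"]
        )
        out = select_models(
            profiles,
            colony_2009.tables["carcasses"],
            colony_2009.tables["territories"],
            "carcass",
            predictors=("shoreline", "size_class", "nearest_neighbor"),
        )
        assert out["ranked"]["weight"].sum() == pytest.approx(1.0)
        assert len(out["ranked"]) == 8  # 2^3 subsets incl. null
        assert out["c_hat"].effective >= 1.0
        assert (out["importance"]["relative_importance"] <= 1 + 1e-9).all()

    def test_size_threshold_override(self, colony_2009):
        covs = covariate_frame(colony_2009.tables["territories"], size_threshold=73.5)
        assert covs.attrs["size_threshold"] == 73.5
        default = covariate_frame(colony_2009.tables["territories"])
        areas = [t.area for t in colony_2009.tables["territories"]]
        assert default.attrs["size_threshold"] == pytest.approx(np.mean(areas))
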