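import numpy as np
import pandas as pd
import pytest

from deltascreen.delta import (auc_roc, build_deq_spec, composite_scores,
                               factor_determinacy, factor_score_weights,
                               fit_delta, validate_vs_severity)
from deltascreen.sem import FittedModel, ModelSpec
from deltascreen.synthetic import INDICATORS


def _fitted_from(spec: ModelSpec, params: dict) -> FittedModel:
    return FittedModel(spec=spec, estimator="ml", params=params, se={},
                       n=1000, chi2=0.0, df=1, p=1.0, converged=True,
                       grad_norm=0.0)


def _one_indicator_fit(lam: float, theta: float) -> FittedModel:
    spec = ModelSpec(observed=["y"], latent=["f"])
    spec.add_variance("f", free=False, value=1.0)
    spec.add_path("f", "y")
    spec.add_variance("y")
    return _fitted_from(spec, {"y~f": lam, "y~~y": theta})


class TestBuildDeqSpec:
    def test_free_parameter_count_and_df(self):
        spec = build_deq_spec(INDICATORS)
        assert spec.n_free == 14
        # 5*6/2 = 15 distinct moments minus 14 free parameters
        assert 15 - spec.n_free == 1

    def test_iadl_loads_delta_only(self):
        spec = build_deq_spec(INDICATORS)
        assert "iadl~gprime" not in spec.free_labels()
        assert "iadl~delta" in spec.free_labels()

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="exactly 5"):
            build_deq_spec(["lm2", "vr1", "cowa", "iadl"])

    def test_missing_iadl_rejected(self):
        with pytest.raises(ValueError, match="IADL"):
            build_deq_spec(["lm2", "vr1", "cowa", "digit_span", "mmse"])

    def test_spec_json_round_trip(self):
        spec = build_deq_spec(INDICATORS)
        clone = ModelSpec.from_json(spec.to_json())
        assert clone.free_labels() == spec.free_labels()
        theta = np.linspace(0.2, 0.9, spec.n_free)
        assert np.array_equal(spec.matrices(theta)[1],
                              clone.matrices(theta)[1])


class TestFactorScoreWeights:
    def test_one_indicator_closed_form(self):
        lam, theta = 0.8, 0.36
        W = factor_score_weights(_one_indicator_fit(lam, theta))
        assert W.loc["y", "f"] == pytest.approx(lam / (lam ** 2 + theta))

    def test_zero_loadings_zero_weights(self):
        W = factor_score_weights(_one_indicator_fit(0.0, 1.0))
        assert W.loc["y", "f"] == 0.0

    def test_iadl_gprime_weight_nonzero_in_general(self):
        # IADL's loading on g' is fixed at 0 but its regression-score
        # weight for g' need not be: Sigma^-1 mixes indicators
        spec = build_deq_spec(INDICATORS)
        params = {}
        lam_d = dict(zip(INDICATORS, [0.25, -0.25, 0.25, -0.25, 0.88]))
        for nm in INDICATORS:
            params[f"{nm}~delta"] = lam_d[nm]
            if nm != "iadl":
                params[f"{nm}~gprime"] = 0.7
            params[f"{nm}~~{nm}"] = 1 - lam_d[nm] ** 2 - (
                0.49 if nm != "iadl" else 0.0)
        W = factor_score_weights(_fitted_from(spec, params))
        A, S = spec.matrices(params)
        lat = [spec.variables.index(v) for v in spec.latent]
        Lam = A[:5, lat]
        Sigma = Lam @ Lam.T + S[:5, :5]
        expect = np.linalg.solve(Sigma, Lam)
        assert np.allclose(W.to_numpy(), expect)
        # delta weight on IADL dominates; its g' weight is small here
        assert abs(W.loc["iadl", "delta"]) > abs(W.loc["iadl", "gprime"])


class TestFactorDeterminacy:
    def test_vanishing_residuals_full_determinacy(self):
        rho = factor_determinacy(_one_indicator_fit(1.0, 1e-10))["f"]
        assert rho == pytest.approx(1.0, abs=1e-6)

    def test_matches_scalar_closed_form(self):
        # one factor, loadings (0.8, 0.8, 0.8), Theta = 0.36 I:
        # rho = sqrt(lam' Sigma^-1 lam)
        spec = ModelSpec(observed=["a", "b", "c"], latent=["f"])
        spec.add_variance("f", free=False, value=1.0)
        params = {}
        for v in "abc":
            spec.add_path("f", v)
            spec.add_variance(v)
            params[f"{v}~f"] = 0.8
            params[f"{v}~~{v}"] = 0.36
        lam = np.full(3, 0.8)
        Sigma = np.outer(lam, lam) + 0.36 * np.eye(3)
        expect = np.sqrt(lam @ np.linalg.solve(Sigma, lam))
        rho = factor_determinacy(_fitted_from(spec, params))["f"]
        assert rho == pytest.approx(expect, abs=1e-10)

    def test_determinacy_equals_empirical_score_truth_correlation(
            self, scored_cohort):
        cfg, cohort, truth, dfit = scored_cohort
        sc = cohort["deq"]
        ok = sc.notna()
        r = np.corrcoef(sc[ok], truth.delta[ok.to_numpy()])[0, 1]
        assert r == pytest.approx(dfit.determinacy["delta"], abs=0.03)


class TestCompositeScores:
    def test_indicators_at_mean_score_zero(self):
        W = pd.DataFrame({"delta": [0.3, 0.2], "gprime": [0.1, 0.4]},
                         index=["a", "b"])
        obs = pd.DataFrame({"a": [5.0], "b": [7.0]})
        means = pd.Series({"a": 5.0, "b": 7.0})
        sds = pd.Series({"a": 2.0, "b": 3.0})
        sc = composite_scores(W, obs, means, sds)
        assert sc.iloc[0].tolist() == [0.0, 0.0]

    def test_rows_with_missing_indicator_scored_missing(self):
        W = pd.DataFrame({"delta": [0.3, 0.2], "gprime": [0.1, 0.4]},
                         index=["a", "b"])
        obs = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 1.0]})
        sc = composite_scores(W, obs, pd.Series({"a": 0, "b": 0}),
                              pd.Series({"a": 1, "b": 1}))
        assert sc.iloc[1].isna().all()
        assert sc.iloc[0].notna().all()

    def test_permuting_subjects_permutes_scores(self):
        rng = np.random.default_rng(0)
        W = pd.DataFrame({"delta": [0.3, 0.2], "gprime": [0.1, 0.4]},
                         index=["a", "b"])
        obs = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        means = pd.Series({"a": 0.0, "b": 0.0})
        sds = pd.Series({"a": 1.0, "b": 1.0})
        sc = composite_scores(W, obs, means, sds)
        perm = rng.permutation(10)
        sc_perm = composite_scores(W, obs.iloc[perm].reset_index(drop=True),
                                   means, sds)
        assert np.allclose(sc_perm.to_numpy(), sc.to_numpy()[perm])

    def test_unknown_columns_rejected(self):
        W = pd.DataFrame({"delta": [0.3]}, index=["a"])
        with pytest.raises(KeyError, match="lacks indicator"):
            composite_scores(W, pd.DataFrame({"z": [1.0]}),
                             pd.Series({"a": 0}), pd.Series({"a": 1}))


class TestAucRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[["AD"] * 20, ["NC"] * 20]
        auc, (lo, hi) = auc_roc(scores, labels)
        assert auc == 1.0 and hi <= 1.0

    def test_chance_level_when_independent(self):
        rng = np.random.default_rng(14)
        scores = rng.standard_normal(2000)
        labels = np.where(rng.random(2000) < 0.5, "AD", "NC")
        auc, _ = auc_roc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_pairwise_count(self):
        rng = np.random.default_rng(15)
        scores = np.round(rng.standard_normal(60), 1)  # induce ties
        labels = np.where(rng.random(60) < 0.4, "AD", "NC")
        auc, _ = auc_roc(scores, labels)
        pos = scores[labels == "AD"]
        neg = scores[labels == "NC"]
        wins = sum((p < n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            auc_roc(np.ones(5), np.array(["AD"] * 5))


class TestValidateVsSeverity:
    def test_exact_linear_transform(self):
        s = np.linspace(-2, 2, 50)
        r, p = validate_vs_severity(s, 3.0 - 2.0 * s)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(16)
        r, _ = validate_vs_severity(rng.standard_normal(5000),
                                    rng.standard_normal(5000))
        assert abs(r) < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            validate_vs_severity([1.0, 2.0], [1.0, 2.0])


class TestFitDeltaOnSyntheticCohort:
    def test_phenotype_pattern(self, scored_cohort):
        cfg, cohort, truth, dfit = scored_cohort
        assert dfit.fitted.converged
        assert dfit.determinacy["delta"] >= 0.80
        ok = cohort["deq"].notna()
        auc_d, _ = auc_roc(cohort.loc[ok, "deq"], cohort.loc[ok, "dx"])
        auc_g, _ = auc_roc(cohort.loc[ok, "gprime"], cohort.loc[ok, "dx"])
        assert auc_d > 0.9
        assert 0.4 < auc_g < 0.6

    def test_severity_validation_strong_negative(self, scored_cohort):
        cfg, cohort, truth, dfit = scored_cohort
        r, p = validate_vs_severity(cohort["deq"], cohort["cdr"])
        assert r < -0.5
        assert p < 1e-10
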