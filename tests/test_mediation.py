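import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltascreen.mediation import (bonferroni_gate, build_base_model,
                                   build_mediation_model, classify_protein,
                                   fit_mediation, mediation_effect,
                                   run_screen, write_class_tables)
from deltascreen.sem import fit_ml
from deltascreen.synthetic import COVARIATES, SynthConfig, generate_cohort
from deltascreen.delta import fit_delta


def _single_mediator_cohort(a, c, b, n=3000, seed=0):
    cfg = SynthConfig(n_subjects=n, n_biomarkers=1, n_true_mediators=1,
                      path_a=a, path_c_vec=np.array([c]),
                      path_b_vec=np.array([b]), seed=seed,
                      skew_flag=np.zeros(1, bool), batch_sd=0.0,
                      missing_rate=0.0, outlier_rate=0.0)
    table, truth = generate_cohort(cfg)
    col = "biomarker_000"
    table[col] = (table[col] - table[col].mean()) / table[col].std(ddof=1)
    dfit = fit_delta(table, seed=0)
    return table.join(dfit.score(table)), truth


class TestMediationEffect:
    def test_zero_indirect(self):
        ind, z, pct, direction = mediation_effect(-0.2, 0.0, 0.5, 0.1, 0.1)
        assert ind == 0.0 and z == 0.0 and pct == 0.0 and direction == ""

    def test_full_mediation_when_direct_zero(self):
        _, _, pct, _ = mediation_effect(0.0, 0.4, -0.3, 0.05, 0.05)
        assert pct == 100.0

    def test_percent_reproduces_published_magnitude(self):
        # direct effect -0.13 with indirect -0.107 (back-solved from a
        # total of about -0.24): percent = 100*0.107/(0.107+0.13) = 45.1,
        # the magnitude class of the strongest mediator in the screen the
        # model family was built for
        _, _, pct, direction = mediation_effect(-0.13, 0.5, -0.214,
                                                0.05, 0.05)
        assert pct == pytest.approx(45.2, abs=0.5)
        assert direction == "attenuating"

    def test_accentuating_direction(self):
        _, _, _, direction = mediation_effect(-0.2, 0.4, 0.3, 0.05, 0.05)
        assert direction == "accentuating"

    def test_undefined_percent_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mediation_effect(0.0, 0.0, 0.5, 0.1, 0.1)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mediation_effect(0.1, 0.2, 0.3, 0.0, 0.1)

    def test_sobel_z_matches_parametric_bootstrap(self):
        # toy configuration: c = 0.3 (se 0.05), b = 0.2 (se 0.04)
        c, se_c, b, se_b = 0.3, 0.05, 0.2, 0.04
        _, z, _, _ = mediation_effect(-0.1, c, b, se_c, se_b)
        rng = np.random.default_rng(20)
        draws = rng.normal(c, se_c, 2000) * rng.normal(b, se_b, 2000)
        z_boot = c * b / draws.std(ddof=1)
        assert z == pytest.approx(z_boot, rel=0.10)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(-0.5, 0.5), c=st.floats(-0.8, 0.8),
           b=st.floats(-0.8, 0.8), k=st.floats(0.1, 10.0))
    def test_percent_invariant_to_age_rescaling(self, a, c, b, k):
        # rescaling age by k > 0 multiplies both the direct effect and the
        # age->biomarker path by k; the percent mediated must not move
        if c * b == 0 and a == 0:
            return
        _, _, pct, _ = mediation_effect(a, c, b, 0.05, 0.05)
        _, _, pct_k, _ = mediation_effect(a * k, c * k, b, 0.05 * k, 0.05)
        assert pct == pytest.approx(pct_k, rel=1e-9, abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(c=st.floats(-0.8, 0.8).filter(lambda x: abs(x) > 1e-6),
           b=st.floats(-0.8, 0.8).filter(lambda x: abs(x) > 1e-6))
    def test_sobel_sign_matches_indirect_sign(self, c, b):
        ind, z, pct, _ = mediation_effect(-0.2, c, b, 0.05, 0.05)
        assert np.sign(z) == np.sign(ind)
        assert 0.0 <= pct <= 100.0


class TestGateAndClassing:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, True), (0.001, False), (0.5, False), (0.0, True)])
    def test_gate_strict_inequality(self, p, expected):
        assert bonferroni_gate(p) is expected

    def test_gate_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni_gate(1.5)

    @pytest.mark.parametrize("p_c,p_b,expected", [
        (1e-5, 1e-4, 1), (1e-5, 0.02, 2), (0.02, 1e-5, 3), (0.02, 0.5, 4)])
    def test_four_class_taxonomy(self, p_c, p_b, expected):
        assert classify_protein(p_c, p_b) == expected


class TestModelSpecs:
    def test_base_model_is_saturated_regression(self):
        spec = build_base_model(COVARIATES)
        p = len(spec.observed)
        assert spec.n_free == p * (p + 1) // 2

    def test_mediation_model_adds_one_observed_and_one_df(self):
        base = build_base_model(COVARIATES)
        med = build_mediation_model("biomarker_000", COVARIATES)
        assert len(med.observed) == len(base.observed) + 1
        p = len(med.observed)
        assert p * (p + 1) // 2 - med.n_free == 1

    def test_mediation_spec_json_includes_biomarker(self):
        med = build_mediation_model("biomarker_007", COVARIATES)
        assert "biomarker_007" in med.to_json()


class TestRecovery:
    def test_base_model_age_effect_recovers_total(self, scored_cohort):
        cfg, cohort, truth, dfit = scored_cohort
        fit = fit_ml(build_base_model(COVARIATES), cohort, seed=0)
        est = fit.params["deq~age"] * cfg.age_sd   # per-SD-of-age scale
        se = fit.se["deq~age"] * cfg.age_sd
        # regressions onto the composite attenuate structural coefficients
        # by (W'Lambda)_dd, the squared score-truth correlation
        expect = truth.total_age_effect * dfit.determinacy["delta"] ** 2
        assert est < 0
        assert abs(est - expect) < 3 * se

    def test_null_biomarker_paths_near_zero(self):
        table, truth = _single_mediator_cohort(a=-0.25, c=0.0, b=0.0,
                                               seed=3)
        res = fit_mediation(table, "biomarker_000", covariate_names=[])
        assert res.failure == ""
        assert abs(res.path_b) < 3 * res.se_b
        assert abs(res.path_c) < 3 * res.se_c
        assert res.protein_class == 4

    def test_true_mediator_paths_recovered(self):
        table, truth = _single_mediator_cohort(a=-0.25, c=0.4, b=-0.3,
                                               seed=4)
        res = fit_mediation(table, "biomarker_000", covariate_names=[])
        rho = np.corrcoef(
            table["deq"][table["deq"].notna()],
            truth.delta[table["deq"].notna().to_numpy()])[0, 1]
        # age in years: structural paths scale with sd(age); regressions
        # onto the composite attenuate outcome-side paths by the squared
        # score-truth correlation
        assert res.path_c * 9.5 == pytest.approx(0.4, abs=3 * res.se_c * 9.5)
        assert res.path_b == pytest.approx(-0.3 * rho ** 2,
                                           abs=3 * res.se_b)
        assert res.path_a * 9.5 == pytest.approx(
            -0.25 * rho ** 2, abs=3 * res.se_a * 9.5)
        assert res.protein_class == 1


class TestRunScreen:
    def test_empty_biomarker_list(self, scored_cohort):
        _, cohort, _, _ = scored_cohort
        out = run_screen(cohort, [])
        assert out.empty

    def test_class1_percent_in_open_interval(self, scored_cohort):
        cfg, cohort, truth, _ = scored_cohort
        biom = [f"biomarker_{m:03d}" for m in range(20)]
        out = run_screen(cohort, biom, seed=0)
        c1 = out[out["protein_class"] == 1]
        assert len(c1) > 0
        assert ((c1["percent_mediated"] > 0)
                & (c1["percent_mediated"] < 100)).all()
        # non-mediators carry no percent (finite only for class 1)
        assert out.loc[out["protein_class"] != 1,
                       "percent_mediated"].isna().all()

    def test_screen_deterministic_and_tables_written(self, scored_cohort,
                                                     tmp_path):
        _, cohort, _, _ = scored_cohort
        biom = [f"biomarker_{m:03d}" for m in range(6)]
        out1 = run_screen(cohort, biom, seed=0)
        out2 = run_screen(cohort, biom, seed=0)
        pd.testing.assert_frame_equal(out1, out2)
        write_class_tables(out1, tmp_path)
        assert (tmp_path / "mediation_effects.csv").exists()
        for cls in (1, 2, 3, 4):
            assert (tmp_path / f"class{cls}_proteins.csv").exists()

    def test_consistency_identity_direct_plus_indirect_is_total(
            self, scored_cohort):
        cfg, cohort, truth, _ = scored_cohort
        base = fit_ml(build_base_model(COVARIATES), cohort, seed=0)
        total = base.params["deq~age"]
        res = fit_mediation(cohort, "biomarker_000")
        decomposed = res.path_a + res.path_c * res.path_b
        joint_se = np.hypot(base.se["deq~age"], res.se_a)
        assert decomposed == pytest.approx(total, abs=2 * joint_se)
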