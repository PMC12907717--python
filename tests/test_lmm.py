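"""Mixed models: estimation oracles, contrasts, effect sizes, recovery."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from patsy import build_design_matrices, dmatrix

from mgtlab import (CohortDesign, EffectSpec, ModelSpec, contrast_analysis,
                    fit_lmm, fit_repetition_model, icc_from_components,
                    partial_eta_to_f, cohens_f_to_eta, recovery_experiment,
                    simulate_lmm_dataset, standardized_coefficients,
                    table2_family)


@pytest.fixture(scope="module")
def fitted(small_lmm_table):
    table, truth = small_lmm_table
    return fit_lmm(table, "risk"), table, truth


class TestEstimation:
    def test_ols_oracle_without_random_effects(self, rng):
        """With the random structure removed, fixed effects equal the
        closed-form least-squares solution on the same design matrix."""
        n = 200
        df = pd.DataFrame({
            "session": rng.choice([1, 2], n),
            "group": rng.choice(["placebo", "probiotics"], n),
            "stimulation": rng.choice(["sham", "SPL", "VMPFC"], n),
        })
        df["risk"] = 20 + 2 * (df["session"] == 2) + rng.normal(0, 3, n)
        spec = ModelSpec("ols", "risk", "session * group * stimulation",
                         random="none")
        fit = fit_lmm(df, spec)
        X = np.asarray(build_design_matrices(
            [fit.design_info],
            df.assign(**{c: pd.Categorical(df[c], fit.factors[c])
                         for c in fit.factors}))[0])
        beta, *_ = np.linalg.lstsq(X, df["risk"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_recovers_generative_parameters(self, fitted):
        fit, _, truth = fitted
        assert fit.converged
        est = fit.params
        assert abs(est["Intercept"] - truth["intercept"]) < \
            3 * fit.coefficients.loc["Intercept", "se"]
        tt = "session2:probiotics"
        assert abs(est[tt] - truth["coefficients"][tt]) < \
            3 * fit.coefficients.loc[tt, "se"]
        vc = fit.variance_components
        assert vc["trialtype:participant"] == pytest.approx(
            truth["tau_trialtype_participant"], rel=0.25)
        assert vc["residual"] == pytest.approx(truth["sigma2_residual"],
                                               rel=0.10)

    def test_agrees_with_lme4(self, tmp_path):
        """Independent oracle: the same ML optimum from R's lme4."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        design = CohortDesign(n_placebo=6, n_probiotics=6,
                              n_dropped_runs=0, n_trial_types=10)
        table, _ = simulate_lmm_dataset(EffectSpec(), design, seed=42)
        fit = fit_lmm(table, "risk")
        csv = tmp_path / "t.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$session <- factor(d$session)
            d$group <- factor(d$group, levels=c("placebo","probiotics"))
            d$stimulation <- factor(d$stimulation,
                                    levels=c("sham","SPL","VMPFC"))
            m <- lmer(risk ~ session*group*stimulation + (1|participant)
                      + (1|participant:trial_code), data=d, REML=FALSE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            write.csv(data.frame(term=names(fe), estimate=unname(fe)),
                      "{tmp_path}/fe.csv", row.names=FALSE)
            write.csv(vc[,c("grp","vcov")], "{tmp_path}/vc.csv",
                      row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        fe = pd.read_csv(tmp_path / "fe.csv")
        fe["term"] = (fe["term"].str.replace("(Intercept)", "Intercept",
                                             regex=False)
                      .str.replace("groupprobiotics", "probiotics")
                      .str.replace("stimulation", ""))
        for _, row in fe.iterrows():
            assert fit.params[row["term"]] == pytest.approx(
                row["estimate"], abs=1e-5)
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        ours = fit.variance_components
        assert ours["residual"] == pytest.approx(vc["Residual"], rel=0.01)
        assert ours["trialtype:participant"] == pytest.approx(
            vc["participant:trial_code"], rel=0.01)
        assert ours["participant"] == pytest.approx(
            vc["participant"], abs=0.05)

    def test_zero_random_variance_data(self):
        rng = np.random.default_rng(1)
        design = CohortDesign(n_placebo=5, n_probiotics=5,
                              n_dropped_runs=0, n_trial_types=8)
        spec = EffectSpec(coefficients={}, tau_participant=0.0,
                          tau_trialtype_participant=0.0,
                          sigma2_residual=4.0)
        table, _ = simulate_lmm_dataset(spec, design, seed=2)
        fit = fit_lmm(table, "risk")
        vc = fit.variance_components
        assert vc["participant"] < 0.5
        assert vc["trialtype:participant"] < 0.5
        assert fit.icc < 0.15

    def test_invariant_to_row_order_and_group_relabeling(self, fitted):
        fit, table, _ = fitted
        shuffled = table.sample(frac=1.0, random_state=0)
        relabeled = shuffled.assign(
            participant="X" + shuffled["participant"].astype(str))
        fit2 = fit_lmm(relabeled, "risk")
        np.testing.assert_allclose(fit2.params.to_numpy(),
                                   fit.params.to_numpy(), atol=1e-6)
        assert fit2.icc == pytest.approx(fit.icc, abs=1e-6)

    def test_missing_factor_column_rejected(self, fitted):
        _, table, _ = fitted
        with pytest.raises(ValueError):
            fit_lmm(table.drop(columns=["group"]), "risk")

    def test_unknown_factor_level_rejected(self, fitted):
        _, table, _ = fitted
        bad = table.copy()
        bad.loc[bad.index[0], "stimulation"] = "DLPFC"
        with pytest.raises(ValueError):
            fit_lmm(bad, "risk")


class TestReportIdentities:
    def test_icc_matches_component_ratio(self, fitted):
        fit, _, _ = fitted
        vc = fit.variance_components
        tau = vc["participant"] + vc["trialtype:participant"]
        assert fit.icc == pytest.approx(tau / (tau + vc["residual"]),
                                        abs=1e-12)

    def test_r2_decomposition_bounds(self, fitted):
        fit, _, _ = fitted
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
        # almost all variance is random-intercept structure here
        assert fit.r2_conditional > 0.85

    def test_ci_brackets_estimate(self, fitted):
        fit, _, _ = fitted
        c = fit.coefficients
        assert (c["ci_low"] <= c["estimate"]).all()
        assert (c["estimate"] <= c["ci_high"]).all()

    def test_counts_match_input(self, fitted):
        fit, table, _ = fitted
        assert fit.n_obs == len(table)
        assert fit.n_groups["participant"] == table["participant"].nunique()


class TestContrasts:
    def test_session_contrast_is_coefficient_sum(self, fitted):
        """EMM(session2) - EMM(session1) in the (probiotics, sham) cell
        equals beta_session2 + beta_session2:probiotics exactly."""
        fit, _, _ = fitted
        cr = contrast_analysis(fit, [{
            "label": "SESSION2 - SESSION1",
            "cell_a": {"session": 2, "group": "probiotics",
                       "stimulation": "sham"},
            "cell_b": {"session": 1, "group": "probiotics",
                       "stimulation": "sham"}}])
        expected = (fit.params["session2"]
                    + fit.params["session2:probiotics"])
        assert cr.table["estimate"].iloc[0] == pytest.approx(expected,
                                                             abs=1e-10)

    def test_self_contrast_is_null(self, fitted):
        fit, _, _ = fitted
        cell = {"session": 1, "group": "placebo", "stimulation": "sham"}
        cr = contrast_analysis(fit, [{"label": "X - X", "cell_a": cell,
                                      "cell_b": cell}])
        row = cr.table.iloc[0]
        assert row["estimate"] == 0.0
        assert row["p_adj"] == 1.0

    def test_table2_family_shape(self, fitted):
        fit, _, _ = fitted
        cr = contrast_analysis(fit, table2_family())
        assert cr.family_size == 20
        assert len(cr.table) == 20
        assert (cr.table["p_adj"] >= cr.table["p_raw"] - 1e-15).all()
        assert cr.table["p_adj"].between(0, 1).all()

    def test_absent_level_rejected(self, fitted):
        fit, _, _ = fitted
        with pytest.raises(ValueError):
            contrast_analysis(fit, [{
                "label": "bad",
                "cell_a": {"session": 1, "group": "placebo",
                           "stimulation": "DLPFC"},
                "cell_b": {"session": 1, "group": "placebo",
                           "stimulation": "sham"}}])

    @given(p=st.floats(1e-12, 1.0), m=st.integers(1, 60))
    @settings(max_examples=100, deadline=None)
    def test_bonferroni_monotone_in_family_size(self, p, m):
        adj = min(1.0, m * p)
        adj_bigger = min(1.0, (m + 1) * p)
        assert adj >= p
        assert adj_bigger >= adj
        assert 0.0 <= adj <= 1.0


class TestRepetitionModel:
    def test_injected_repetition_effect_recovered(self, small_lmm_table):
        table, _ = small_lmm_table
        bumped = table.copy()
        bumped.loc[bumped["repetition"] == "B", "risk"] += 2.0
        fit = fit_repetition_model(bumped)
        est = fit.coefficients.loc["repetitionB"]
        assert abs(est["estimate"] - 2.0) < 3 * est["se"]

    def test_single_level_repetition_rejected(self, small_lmm_table):
        table, _ = small_lmm_table
        collapsed = table.assign(repetition="A")
        with pytest.raises(ValueError):
            fit_repetition_model(collapsed)


class TestEffectSizes:
    @pytest.mark.parametrize("eta2,f", [(0.691, 1.4954), (0.0, 0.0),
                                        (0.5, 1.0)])
    def test_eta_to_f_conversion(self, eta2, f):
        assert partial_eta_to_f(eta2) == pytest.approx(f, abs=5e-5)

    @pytest.mark.parametrize("eta2", [-0.1, 1.0, 1.5])
    def test_eta_domain_enforced(self, eta2):
        with pytest.raises(ValueError):
            partial_eta_to_f(eta2)

    @given(st.floats(0.0, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_conversion_round_trips(self, eta2):
        assert cohens_f_to_eta(partial_eta_to_f(eta2)) == pytest.approx(
            eta2, abs=1e-9)

    def test_icc_from_components(self):
        assert icc_from_components(16.88, 192.99, 1.56) == pytest.approx(
            0.92, abs=0.005)
        assert icc_from_components(1.0) == 0.0
        with pytest.raises(ValueError):
            icc_from_components(-1.0, 2.0)

    def test_standardized_beta_scale_invariant(self, fitted):
        fit, table, _ = fitted
        std1 = standardized_coefficients(fit, table)
        scaled = table.assign(risk=table["risk"] * 7.0)
        fit2 = fit_lmm(scaled, "risk")
        std2 = standardized_coefficients(fit2, scaled)
        np.testing.assert_allclose(std1["estimate"], std2["estimate"],
                                   atol=1e-4)
        assert std1.attrs["method"] == "response-sd-division"

    def test_standardized_beta_magnitude(self, fitted):
        """A raw interaction near 0.27 against response SD ~14.5 lands at
        standardized beta ~0.02."""
        fit, table, _ = fitted
        std = standardized_coefficients(fit, table)
        sd = std.attrs["response_sd"]
        assert 12 < sd < 17
        raw = fit.params["session2:probiotics"]
        assert std.loc["session2:probiotics", "estimate"] == pytest.approx(
            raw / sd, abs=1e-12)

    def test_zero_variance_response_rejected(self, fitted):
        fit, table, _ = fitted
        flat = table.assign(risk=1.0)
        with pytest.raises(ValueError):
            standardized_coefficients(fit, flat)


class TestRecoveryHarness:
    def test_single_replicate_report(self, reduced_design):
        rep = recovery_experiment(design=reduced_design, n_reps=1, seed=5)
        assert rep.n_reps == 1
        assert np.isnan(rep.summary.loc["session2:probiotics", "mc_se"])
        assert rep.summary.loc["session2:probiotics", "n_reps"] == 1

    def test_small_recovery_is_unbiased(self):
        design = CohortDesign(n_placebo=8, n_probiotics=8,
                              n_dropped_runs=0, n_trial_types=10)
        rep = recovery_experiment(design=design, n_reps=12, seed=17,
                                  terms=["Intercept",
                                         "session2:probiotics"])
        row = rep.summary.loc["session2:probiotics"]
        assert row["truth"] == 0.27
        assert abs(row["bias"]) < 3 * row["mc_se"]
        assert rep.n_failed == 0

    def test_nonpositive_reps_rejected(self, reduced_design):
        with pytest.raises(ValueError):
            recovery_experiment(design=reduced_design, n_reps=0)
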