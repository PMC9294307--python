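import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from cibalance.stats import (ModelSpec, anova_table, estimated_marginal_means,
                             fit_lmm, fit_predictor_model, pairwise_contrasts)

BINS = ["weeks_1_2", "months_1_2", "months_3_4", "months_6_14"]


def simulate_lmm_data(n_participants=13, beta_hemi=0.5, sd_intercept=0.3,
                      sd_resid=0.4, seed=0, session_slope=-0.1):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        b = rng.normal(0, sd_intercept)
        age = rng.uniform(1, 5)
        delay = rng.uniform(7, 14)
        for s, tb in enumerate(BINS):
            for hemi in ("left", "right"):
                y = (1.0 + b + session_slope * s
                     + (beta_hemi if hemi == "left" else 0.0)
                     + 0.02 * age - 0.01 * delay
                     + rng.normal(0, sd_resid))
                rows.append(dict(participant_id=f"P{i:02d}", time_bin=tb,
                                 hemisphere=hemi, age_ci1=age,
                                 inter_implant_delay=delay, pz=y))
    return pd.DataFrame(rows)


SPEC = ModelSpec(response="pz",
                 fixed=["time_bin", "hemisphere", "time_bin:hemisphere"])


class TestFitLmm:
    def test_reml_fit_reports_variance_components(self):
        fit = fit_lmm(simulate_lmm_data(), SPEC)
        assert fit.converged
        assert fit.var_intercept > 0 and fit.var_residual > 0

    def test_zero_between_participant_variance_estimates_near_zero(self):
        data = simulate_lmm_data(sd_intercept=0.0, seed=3)
        fit = fit_lmm(data, SPEC)
        assert fit.var_intercept < 0.05 * fit.var_residual

    def test_duplicating_rows_keeps_fixed_effects(self):
        data = simulate_lmm_data(seed=5)
        fit1 = fit_lmm(data, SPEC)
        fit2 = fit_lmm(pd.concat([data, data], ignore_index=True), SPEC)
        assert np.allclose(fit1.fe_params, fit2.fe_params, atol=1e-4)

    def test_row_order_invariance(self):
        data = simulate_lmm_data(seed=6)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit1, fit2 = fit_lmm(data, SPEC), fit_lmm(shuffled, SPEC)
        assert np.allclose(fit1.fe_params, fit2.fe_params, atol=1e-6)

    def test_participant_relabelling_invariance(self):
        data = simulate_lmm_data(seed=6)
        relabeled = data.copy()
        relabeled["participant_id"] = relabeled["participant_id"].map(
            lambda s: "Z" + s[::-1])
        fit1, fit2 = fit_lmm(data, SPEC), fit_lmm(relabeled, SPEC)
        assert np.allclose(fit1.fe_params, fit2.fe_params, atol=1e-6)

    def test_too_few_participants_rejected(self):
        data = simulate_lmm_data(n_participants=1)
        with pytest.raises(ValueError):
            fit_lmm(data, SPEC)

    def test_missing_rows_dropped_and_counted(self):
        data = simulate_lmm_data(seed=7)
        data.loc[:4, "pz"] = np.nan
        fit = fit_lmm(data, SPEC)
        assert fit.n_dropped == 5

    def test_coverage_of_planted_effect(self):
        # 95% Wald CI for the hemisphere effect covers the planted value in
        # at least 90 of 100 replicates
        beta = 0.5
        hits = 0
        for seed in range(100):
            data = simulate_lmm_data(beta_hemi=beta, seed=seed)
            fit = fit_lmm(data, ModelSpec(response="pz", fixed=["hemisphere"]))
            names = list(fit.result.fe_params.index)
            (idx,) = [i for i, n in enumerate(names) if "hemisphere" in n]
            # sum coding: the hemisphere coefficient is half the group difference
            est = 2 * fit.fe_params[idx]
            se = 2 * np.sqrt(fit.fe_cov[idx, idx])
            hits += bool(abs(est - beta) <= 1.96 * se)
        assert hits >= 90


class TestAnova:
    def test_planted_effect_detected_and_null_not(self):
        data = simulate_lmm_data(beta_hemi=0.8, seed=2)
        table = anova_table(fit_lmm(data, SPEC))
        rows = table.set_index("term")
        assert rows.loc["hemisphere", "p"] < 1e-4
        assert rows.loc["time_bin:hemisphere", "p"] > 0.01

    def test_null_term_type_I_rate_calibrated(self):
        # interaction is never planted; its rejection rate stays near alpha
        rejections = 0
        n = 120
        for seed in range(n):
            data = simulate_lmm_data(beta_hemi=0.0, seed=1000 + seed,
                                     n_participants=10)
            table = anova_table(fit_lmm(data, SPEC)).set_index("term")
            rejections += bool(table.loc["time_bin:hemisphere", "p"] < 0.05)
        assert rejections / n <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n)

    def test_df_method_recorded(self):
        table = anova_table(fit_lmm(simulate_lmm_data(), SPEC))
        assert (table["df_method"] == "between-within").all()


class TestEmms:
    def test_balanced_one_factor_emms_equal_cell_means(self):
        data = simulate_lmm_data(seed=4)
        spec = ModelSpec(response="pz", fixed=["hemisphere"], covariates=())
        emms = estimated_marginal_means(fit_lmm(data, spec), ["hemisphere"])
        cell = data.groupby("hemisphere")["pz"].mean()
        for _, row in emms.table.iterrows():
            assert row["emm"] == pytest.approx(cell[row["hemisphere"]],
                                               abs=1e-6)

    def test_translation_equivariance(self):
        data = simulate_lmm_data(seed=8)
        fit1 = fit_lmm(data, SPEC)
        shifted = data.assign(pz=data["pz"] + 5.0)
        fit2 = fit_lmm(shifted, SPEC)
        e1 = estimated_marginal_means(fit1, ["time_bin"]).table
        e2 = estimated_marginal_means(fit2, ["time_bin"]).table
        assert np.allclose(e2["emm"] - e1["emm"], 5.0, atol=1e-3)

    def test_planted_ordering_recovered(self):
        data = simulate_lmm_data(seed=9, session_slope=-0.3)
        emms = estimated_marginal_means(fit_lmm(data, SPEC), ["time_bin"])
        ordered = emms.table.set_index("time_bin").loc[BINS, "emm"].to_numpy()
        assert (np.diff(ordered) < 0).all()

    def test_covariate_level_request_rejected(self):
        fit = fit_lmm(simulate_lmm_data(), SPEC)
        with pytest.raises(ValueError):
            estimated_marginal_means(fit, ["age_ci1"])


class TestContrasts:
    def test_two_level_family_tukey_equals_unadjusted(self):
        data = simulate_lmm_data(seed=10, beta_hemi=0.2)
        emms = estimated_marginal_means(fit_lmm(data, SPEC), ["hemisphere"])
        row = pairwise_contrasts(emms).iloc[0]
        assert row["p_tukey"] == pytest.approx(row["p_unadjusted"], rel=1e-3)

    def test_adjusted_p_never_below_unadjusted(self):
        data = simulate_lmm_data(seed=11)
        emms = estimated_marginal_means(fit_lmm(data, SPEC), ["time_bin"])
        table = pairwise_contrasts(emms)
        assert len(table) == 6
        assert (table["p_tukey"] >= table["p_unadjusted"] - 1e-12).all()

    def test_single_level_gives_empty_list(self):
        data = simulate_lmm_data(seed=12)
        data = data[data["hemisphere"] == "left"]
        spec = ModelSpec(response="pz", fixed=["time_bin"])
        emms = estimated_marginal_means(fit_lmm(data, spec), ["time_bin"])
        emms.table = emms.table.iloc[:1]
        emms.L = emms.L[:1]
        assert pairwise_contrasts(emms).empty

    def test_equal_means_familywise_error_controlled(self):
        # three equal-mean bins: family-wise rejection rate stays near alpha
        fw = 0
        n = 100
        for seed in range(n):
            rng = np.random.default_rng(20_000 + seed)
            rows = []
            for i in range(12):
                b = rng.normal(0, 0.3)
                for tb in BINS[:3]:
                    rows.append(dict(participant_id=f"P{i}", time_bin=tb,
                                     pz=1.0 + b + rng.normal(0, 0.4)))
            data = pd.DataFrame(rows)
            spec = ModelSpec(response="pz", fixed=["time_bin"], covariates=())
            emms = estimated_marginal_means(fit_lmm(data, spec), ["time_bin"])
            fw += bool((pairwise_contrasts(emms)["p_tukey"] < 0.05).any())
        assert fw / n <= 0.05 + 0.05


class TestPredictorModel:
    def test_identity_fit_r2_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(dict(
            y=rng.normal(size=20), age_ci1=rng.uniform(1, 5, 20),
            inter_implant_delay=rng.uniform(7, 14, 20)))
        df["x"] = df["y"]
        res, _ = fit_predictor_model(df, "y", ["x"])
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_planted_negative_slope_recovered(self):
        rng = np.random.default_rng(1)
        recovered = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            delay = rng.uniform(7, 14, 13)
            age = rng.uniform(1, 5, 13)
            y = -9.0 * delay + 2.0 * age + rng.normal(0, 10, 13)
            df = pd.DataFrame(dict(y=y, inter_implant_delay=delay,
                                   age_ci1=age))
            res, _ = fit_predictor_model(df, "y", ["inter_implant_delay"],
                                         covariates=("age_ci1",))
            recovered += bool(res.params["inter_implant_delay"] < 0)
        assert recovered >= 39

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(dict(
            y=rng.normal(size=15), age_ci1=rng.uniform(1, 5, 15),
            inter_implant_delay=rng.uniform(7, 14, 15)))
        df["dup"] = 2.0 * df["age_ci1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_predictor_model(df, "y", ["dup"])


class TestAgainstLme4:
    """Cross-check the mixed-model fit against lme4/lmerTest via Rscript."""

    R_CODE = """
suppressMessages({library(lme4); library(jsonlite)})
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
m <- lmer(pz ~ hemisphere + time_bin + age_ci1 + inter_implant_delay +
          (1|participant_id), data=d, REML=TRUE)
out <- list(fixef=as.list(fixef(m)),
            var_intercept=as.numeric(VarCorr(m)$participant_id[1]),
            var_residual=sigma(m)^2)
cat(toJSON(out, auto_unbox=TRUE, digits=12))
"""

    def test_fixed_effects_and_variances_match(self, tmp_path):
        data = simulate_lmm_data(seed=21)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(self.R_CODE)
        out = subprocess.run(["Rscript", str(script), str(csv)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)

        spec = ModelSpec(response="pz", fixed=["hemisphere", "time_bin"])
        fit = fit_lmm(data, spec)
        # compare on predictions over the observed design rather than on
        # coefficients (R uses treatment coding, this package uses sum coding)
        import patsy
        (X,) = patsy.build_design_matrices([fit.design_info], data)
        pred_py = np.asarray(X) @ fit.fe_params

        rb = ref["fixef"]
        pred_r = np.full(len(data), rb["(Intercept)"])
        pred_r += np.where(data["hemisphere"] == "right",
                           rb.get("hemisphereright", 0.0), 0.0)
        for tb in BINS:   # R's baseline level is alphabetically first
            pred_r += np.where(data["time_bin"] == tb,
                               rb.get(f"time_bin{tb}", 0.0), 0.0)
        pred_r += rb["age_ci1"] * data["age_ci1"].to_numpy()
        pred_r += (rb["inter_implant_delay"]
                   * data["inter_implant_delay"].to_numpy())

        assert np.allclose(pred_py, pred_r, atol=1e-4)
        assert fit.var_intercept == pytest.approx(ref["var_intercept"],
                                                  rel=2e-2)
        assert fit.var_residual == pytest.approx(ref["var_residual"],
                                                 rel=2e-2)
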