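import subprocess

import numpy as np
import pandas as pd
import pytest

import mrrake as m
from mrrake.model import _aggregate, _AgqProblem


def _manual_fit(beta, eta, mu, sigma, x_names, z_names, spec):
    return m.GlmmFit(
        spec=spec,
        beta=np.asarray(beta, float),
        eta=np.asarray(eta, float),
        sigma_mu=sigma,
        mu=mu,
        loglik=0.0,
        converged=True,
        n_iter=0,
        x_names=x_names,
        z_names=z_names,
    )


class TestPredictClosedForm:
    def test_all_zero_coefficients_give_half(self, scheme_2x2):
        spec = m.ModelSpec(fixed=scheme_2x2.factor_names)
        fit = _manual_fit(
            [0, 0, 0], [], {"a1": 0.0}, 0.0,
            ["(Intercept)", "row[b]", "col[y]"], [], spec,
        )
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1"]}))
        preds = m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a1"])
        np.testing.assert_allclose(preds.probs["a1"], 0.5)

    def test_inverse_logit_closed_form(self, scheme_2x2):
        # logit p = 0 + 1*0.3 + 0.2 = 0.5 -> p = 1/(1+e^-0.5)
        spec = m.ModelSpec(fixed=[], area_covariates=["z"])
        fit = _manual_fit([0.0], [1.0], {"a1": 0.2}, 0.3, ["(Intercept)"], ["z"], spec)
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1"], "z": [0.3]}))
        preds = m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a1"], "conditional_blup")
        np.testing.assert_allclose(preds.probs["a1"], 0.6224593, atol=1e-6)

    def test_sigma_zero_marginal_equals_conditional_zero(self, scheme_2x2):
        spec = m.ModelSpec(fixed=scheme_2x2.factor_names, area_covariates=["z"])
        fit = _manual_fit(
            [0.3, -0.4, 0.2], [0.5], {"a1": 0.1}, 0.0,
            ["(Intercept)", "row[b]", "col[y]"], ["z"], spec,
        )
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1", "a9"], "z": [0.3, -1.0]}))
        p_marg = m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a9"], "marginal")
        p_zero = m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a9"], "conditional_zero")
        np.testing.assert_allclose(p_marg.probs["a9"], p_zero.probs["a9"], atol=1e-12)

    def test_marginal_differs_from_zero_plugin_when_sigma_positive(self, scheme_2x2):
        spec = m.ModelSpec(fixed=scheme_2x2.factor_names)
        fit = _manual_fit(
            [1.0, 0.0, 0.0], [], {"a1": 0.0}, 0.8,
            ["(Intercept)", "row[b]", "col[y]"], [], spec,
        )
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1", "a9"]}))
        p_marg = m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a9"], "marginal")
        p_zero = m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a9"], "conditional_zero")
        # population-averaging a convex-then-concave link shifts toward 1/2
        assert (p_marg.probs["a9"] < p_zero.probs["a9"]).all()

    def test_missing_covariates_for_target_area(self, scheme_2x2):
        spec = m.ModelSpec(fixed=[], area_covariates=["z"])
        fit = _manual_fit([0.0], [1.0], {}, 0.3, ["(Intercept)"], ["z"], spec)
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1"], "z": [0.3]}))
        with pytest.raises(m.InputError, match="a9"):
            m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a9"])

    def test_unknown_policy(self, scheme_2x2):
        spec = m.ModelSpec(fixed=[])
        fit = _manual_fit([0.0], [], {}, 0.3, ["(Intercept)"], [], spec)
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1"]}))
        with pytest.raises(m.InputError, match="re_policy"):
            m.predict_cell_probabilities(fit, scheme_2x2, cov, ["a1"], "bogus")


class TestFit:
    def test_sigma_zero_data_matches_plain_logistic(self):
        """With no between-area variation the GLMM collapses to ordinary
        logistic regression (independent oracle: statsmodels GLM)."""
        import statsmodels.api as sm

        cfg = m.tiny_config(sigma_mu=0.0, design_tilt_sd=0.0, seed=5)
        pop, _, survey = m.generate_dataset(cfg)
        spec = m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"])
        fit = m.fit_multilevel_logistic(survey, pop.covariates, spec)
        assert fit.sigma_mu < 1e-3

        areas, row_area, X, s, n, _, _ = _aggregate(survey, pop.covariates, spec, pop.scheme)
        oracle = sm.GLM(np.column_stack([s, n - s]), X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(np.r_[fit.beta, fit.eta], oracle.params, atol=1e-3)

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4 glmer with nAGQ=25 on the same data."""
        cfg = m.tiny_config(
            seed=9, n_areas=12, n_sampled=8, sigma_mu=0.5,
            sample_sizes=(300, 250, 220, 200, 180, 160, 150, 140),
        )
        pop, _, survey = m.generate_dataset(cfg)
        spec = m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"])
        fit = m.fit_multilevel_logistic(survey, pop.covariates, spec, quadrature_points=25)

        df = survey.data.copy()
        df["pct_poverty"] = pop.covariates.data["pct_poverty"].reindex(df["area_id"]).to_numpy()
        csv = tmp_path / "d.csv"
        out = tmp_path / "fit.csv"
        df.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        d$age <- relevel(factor(d$age), '18-44'); d$sex <- relevel(factor(d$sex), 'M')
        d$education <- relevel(factor(d$education), 'hs_or_less')
        f <- glmer(y ~ age + sex + education + pct_poverty + (1|area_id),
                   data=d, family=binomial, nAGQ=25)
        res <- c(fixef(f), sigma=sqrt(unlist(VarCorr(f))), ll=as.numeric(logLik(f)))
        write.csv(data.frame(value=res), '{out}')
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(out)["value"].to_numpy()
        np.testing.assert_allclose(np.r_[fit.beta, fit.eta], ref[:-2], atol=2e-4)
        assert fit.sigma_mu == pytest.approx(ref[-2], abs=2e-4)
        assert fit.loglik == pytest.approx(ref[-1], abs=1e-3)

    def test_parameter_recovery_at_known_truth(self):
        """100 replicate simulations at beta=(-0.5, 0.8), eta=0.3,
        sigma=0.4, 50 areas x 400 respondents: mean estimates within
        3 Monte-Carlo SEs of truth and mean bias < 0.02 per component."""
        scheme = m.StratificationScheme([("x", ["lo", "hi"])])
        cfg = m.GeneratorConfig(
            scheme=scheme, n_areas=50, n_sampled=50,
            pop_log_mean=7.0, pop_log_sd=0.2,
            beta_intercept=-0.5, beta={"x": (0.0, 0.8)},
            eta=(0.3,), sigma_mu=0.4,
            sample_sizes=(400,) * 50, design_tilt_sd=0.0,
            dependence_strength=0.0,
        )
        spec = m.ModelSpec(fixed=["x"], area_covariates=["pct_poverty"])
        ests = []
        for r in range(100):
            pop, _, survey = m.generate_dataset(cfg, seed=30_000 + r)
            fit = m.fit_multilevel_logistic(survey, pop.covariates, spec, compute_se=False)
            ests.append(np.r_[fit.beta, fit.eta, fit.sigma_mu])
        ests = np.asarray(ests)
        truth = np.array([-0.5, 0.8, 0.3, 0.4])
        mean = ests.mean(axis=0)
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert (np.abs(mean[:3] - truth[:3]) < 3 * mc_se[:3]).all(), (mean, mc_se)
        assert (np.abs(mean[:2] - truth[:2]) < 0.02).all()
        # ML variance components carry a small O(1/n_areas) downward bias
        # (no REML analogue here), so sigma gets an absolute band instead
        assert abs(mean[3] - truth[3]) < 0.05

    def test_loglik_at_fit_beats_truth(self, tiny_bundle, tiny_fit):
        """Optimizer sanity: marginal likelihood at the MLE is at least the
        likelihood at the true generating parameters."""
        _, pop, _, survey = tiny_bundle
        spec, fit = tiny_fit
        areas, row_area, X, s, n, _, _ = _aggregate(survey, pop.covariates, spec, pop.scheme)
        prob = _AgqProblem(row_area, X, s, n, len(areas), 15)
        theta_true = np.r_[pop.beta_full, pop.eta, np.log(pop.sigma_mu)]
        ll_true, _ = prob.loglik_grad(theta_true, want_grad=False)
        assert fit.loglik >= ll_true - 1e-8

    def test_quadrature_stability(self, tiny_bundle):
        _, pop, _, survey = tiny_bundle
        spec = m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"])
        f7 = m.fit_multilevel_logistic(survey, pop.covariates, spec, quadrature_points=7)
        f25 = m.fit_multilevel_logistic(survey, pop.covariates, spec, quadrature_points=25)
        assert np.abs(f7.beta - f25.beta).max() < 1e-4

    def test_complete_separation_raises(self, scheme_2x2):
        # 'row' separates the outcome perfectly
        n = 40
        df = pd.DataFrame(
            {
                "area_id": ["a1"] * n,
                "y": [1] * (n // 2) + [0] * (n // 2),
                "row": ["a"] * (n // 2) + ["b"] * (n // 2),
                "col": ["x", "y"] * (n // 2),
            }
        )
        survey = m.SurveyDataset(scheme_2x2, df)
        cov = m.AreaCovariates(pd.DataFrame({"area_id": ["a1"]}))
        spec = m.ModelSpec(fixed=scheme_2x2.factor_names)
        with pytest.raises(m.FittingError):
            m.fit_multilevel_logistic(survey, cov, spec)

    def test_constant_outcome_is_rejected_before_fitting(self, scheme_2x2):
        df = pd.DataFrame(
            {"area_id": ["a1"] * 4, "y": [1] * 4, "row": list("abab"), "col": list("xxyy")}
        )
        with pytest.raises(m.InputError, match="constant"):
            m.SurveyDataset(scheme_2x2, df)

    def test_weights_ignored_with_warning(self, tiny_bundle, tiny_fit):
        _, pop, _, survey = tiny_bundle
        spec, fit = tiny_fit
        weighted = m.SurveyDataset(
            pop.scheme, survey.data.assign(weight=np.linspace(0.2, 5.0, survey.n))
        )
        with pytest.warns(UserWarning, match="unweighted"):
            fit_w = m.fit_multilevel_logistic(weighted, pop.covariates, spec)
        np.testing.assert_allclose(fit_w.beta, fit.beta, atol=1e-8)

    def test_unknown_model_terms_rejected(self, tiny_bundle):
        _, pop, _, survey = tiny_bundle
        with pytest.raises(m.InputError, match="bogus"):
            m.fit_multilevel_logistic(
                survey, pop.covariates, m.ModelSpec(fixed=["bogus"])
            )
        with pytest.raises(m.InputError, match="nope"):
            m.fit_multilevel_logistic(
                survey, pop.covariates,
                m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["nope"]),
            )

    def test_se_available_on_default_fit(self, tiny_fit):
        _, fit = tiny_fit
        assert fit.se is not None
        assert all(np.isfinite(v) and v > 0 for v in fit.se.values())


class TestFixedEffectVariant:
    def test_agrees_with_near_zero_sigma_fit(self):
        """Area-dummy fixed-effect fit vs random-intercept fit on data with
        no between-area variation: sampled-area predictions within 0.01."""
        # large per-area samples so free area dummies are not noise-dominated
        cfg = m.tiny_config(
            sigma_mu=0.0, seed=21, pop_log_mean=10.5,
            sample_sizes=(4000, 3000, 2500),
        )
        pop, _, survey = m.generate_dataset(cfg)
        spec_re = m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"])
        spec_fe = m.ModelSpec(
            fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"],
            random_intercept=False,
        )
        fit_re = m.fit_multilevel_logistic(survey, pop.covariates, spec_re)
        fit_fe = m.fit_multilevel_logistic(survey, pop.covariates, spec_fe)
        assert fit_fe.sigma_mu == 0.0
        sampled = survey.area_ids
        p_re = m.predict_cell_probabilities(fit_re, pop.scheme, pop.covariates, sampled)
        p_fe = m.predict_cell_probabilities(fit_fe, pop.scheme, pop.covariates, sampled)
        for a in sampled:
            assert np.abs(p_re.probs[a] - p_fe.probs[a]).max() < 0.01


class TestCompareModels:
    def test_identical_specs_identical_estimates(self, tiny_bundle, tiny_raked):
        _, pop, margins, survey = tiny_bundle
        spec = m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"])
        ests = {}
        fits = []
        for name in ("m1", "m2"):
            fit = m.fit_multilevel_logistic(survey, pop.covariates, spec, compute_se=False)
            preds = m.predict_cell_probabilities(fit, pop.scheme, pop.covariates, pop.area_ids)
            ests[name] = m.poststratify(preds, tiny_raked)
            fits.append((name, fit))
        report = m.compare_models(fits, ests)
        assert (report["table"]["m1"] == report["table"]["m2"]).all()

    def test_range_string_shape(self, tiny_bundle, tiny_fit, tiny_raked):
        import re

        _, pop, margins, survey = tiny_bundle
        spec, fit = tiny_fit
        preds = m.predict_cell_probabilities(fit, pop.scheme, pop.covariates, pop.area_ids)
        est = m.poststratify(preds, tiny_raked)
        report = m.compare_models([("m1", fit), ("m2", fit)], {"m1": est, "m2": est})
        assert re.fullmatch(r"\d+\.\d–\d+\.\d%", report["range"]["m1"])

    def test_different_surveys_rejected(self, tiny_bundle, tiny_fit):
        cfg, pop, margins, survey = tiny_bundle
        spec, fit1 = tiny_fit
        pop2, _, survey2 = m.generate_dataset(m.tiny_config(seed=777))
        fit2 = m.fit_multilevel_logistic(survey2, pop2.covariates, spec, compute_se=False)
        with pytest.raises(m.InputError, match="different surveys"):
            m.compare_models([("m1", fit1), ("m2", fit2)], {"m1": [], "m2": []})
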