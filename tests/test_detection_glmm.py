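"""Mixed-model fitting, candidate enumeration, AICc selection, bootstrap."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from incidentalg.detection_glmm import (
    GLMMSpec,
    build_design,
    enumerate_candidates,
    fit_binomial_glmm,
    full_factorial_frame,
    marginal_loglik_at,
    predict_bootstrap,
    records_to_frame,
    select_models,
)
from incidentalg.synthetic import generate_trials, study_like_scenario
from incidentalg.trial_data import default_calendars, filter_available


@pytest.fixture(scope="module")
def model_frame():
    config = study_like_scenario(seed=2)
    records, _ = filter_available(generate_trials(config))
    return records_to_frame(records, default_calendars())


@pytest.fixture(scope="module")
def full_fit(model_frame):
    spec = GLMMSpec(fixed_terms=("density_quartile", "season:viewshed_class"))
    return fit_binomial_glmm(model_frame, spec)


class TestEnumerateCandidates:
    def test_eighteen_distinct_models(self):
        assert len(enumerate_candidates()) == 18

    def test_intercept_only_present(self):
        labels = [s.label for s in enumerate_candidates()]
        assert "1" in labels

    def test_retained_specs_have_distinct_column_spaces(self):
        template = full_factorial_frame()
        mats = [build_design(template, s)[0] for s in enumerate_candidates()]
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                a, b = mats[i], mats[j]
                ra = np.linalg.matrix_rank(a)
                rb = np.linalg.matrix_rank(b)
                rab = np.linalg.matrix_rank(np.hstack([a, b]))
                assert not (ra == rb == rab), (i, j)

    def test_interaction_spans_main_effects(self):
        template = full_factorial_frame()
        inter, _ = build_design(
            template, GLMMSpec(fixed_terms=("season:viewshed_class",)))
        mains, _ = build_design(
            template, GLMMSpec(fixed_terms=("season", "viewshed_class")))
        assert np.linalg.matrix_rank(np.hstack([inter, mains])) == \
            np.linalg.matrix_rank(inter)


class TestFitBinomialGlmm:
    def test_single_site_intercept_only_is_logit_phat(self, rng):
        y = rng.uniform(size=400) < 0.35
        df = pd.DataFrame({
            "found": y.astype(int), "site": "only",
            "season": "spring", "viewshed_class": "low",
            "density_quartile": "near",
        })
        fit = fit_binomial_glmm(df, GLMMSpec(fixed_terms=()))
        p_hat = df["found"].mean()
        assert fit.random_intercept_sd == 0.0
        assert fit.coefficients["(Intercept)"] == pytest.approx(
            np.log(p_hat / (1 - p_hat)), abs=1e-3)

    def test_fixed_effects_deviance_matches_irls_oracle(self, model_frame):
        # independent oracle: statsmodels GLM (IRLS) on the same design
        import statsmodels.api as sm

        spec = GLMMSpec(fixed_terms=("season", "density_quartile"))
        fit = fit_binomial_glmm(model_frame, spec, force_zero_sd=True)
        X, _ = build_design(model_frame, spec)
        glm = sm.GLM(model_frame["found"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert fit.log_likelihood == pytest.approx(glm.llf, abs=1e-6)

    def test_matches_lme4_reference(self, tmp_path):
        """Cross-check marginal ML against R lme4 glmer with nAGQ=15."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        config = study_like_scenario(seed=7)
        config.months = 4
        records, _ = filter_available(generate_trials(config))
        df = records_to_frame(records, default_calendars())
        data_path = tmp_path / "glmm.csv"
        df.to_csv(data_path, index=False)
        spec = GLMMSpec(fixed_terms=("density_quartile",))
        fit = fit_binomial_glmm(df, spec, ridge=0.0)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{data_path}")
            d$density_quartile <- factor(d$density_quartile,
                levels=c("near","near_mid","far_mid","far"))
            m <- glmer(found ~ density_quartile + (1|site), data=d,
                       family=binomial, nAGQ=15)
            cat(as.numeric(logLik(m)), sqrt(unlist(VarCorr(m))), fixef(m))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        values = [float(v) for v in out.stdout.split()]
        r_ll, r_sd, r_fixef = values[0], values[1], values[2:]
        assert fit.log_likelihood == pytest.approx(r_ll, abs=1e-3)
        assert fit.random_intercept_sd == pytest.approx(r_sd, abs=1e-3)
        assert fit.coefficients.to_numpy() == pytest.approx(r_fixef, abs=1e-3)

    def test_quadrature_loglik_nondecreasing_in_nodes(self, full_fit):
        lls = [marginal_loglik_at(full_fit, n) for n in (1, 3, 5, 9, 15, 21)]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-4
        # and 15 nodes is effectively converged
        assert abs(lls[-1] - lls[-2]) < 1e-6

    def test_aicc_exceeds_aic_and_converges_to_it(self, full_fit):
        assert full_fit.aicc > full_fit.aic
        k, ll = full_fit.n_params, full_fit.log_likelihood
        n_large = 10**6
        aicc_large = -2 * ll + 2 * k + 2 * k * (k + 1) / (n_large - k - 1)
        assert aicc_large == pytest.approx(-2 * ll + 2 * k, abs=1e-3)

    def test_separated_stratum_stays_finite(self):
        # one stratum fully detected: ridge keeps the estimate finite
        df = pd.DataFrame({
            "found": [1] * 20 + [0] * 10 + [1] * 10,
            "site": ["A"] * 20 + ["B"] * 20,
            "season": ["spring"] * 20 + ["summer"] * 20,
            "viewshed_class": "low",
            "density_quartile": "near",
        })
        fit = fit_binomial_glmm(df, GLMMSpec(fixed_terms=("season",)))
        assert np.all(np.isfinite(fit.coefficients.to_numpy()))
        assert np.isfinite(fit.log_likelihood)


class TestSelectModels:
    def test_ranking_and_best_set(self, model_frame):
        specs = [GLMMSpec(()), GLMMSpec(("density_quartile",)),
                 GLMMSpec(("density_quartile", "season:viewshed_class"))]
        fits = [fit_binomial_glmm(model_frame, s) for s in specs]
        table = select_models(fits)
        assert list(table["aicc"]) == sorted(table["aicc"])
        assert table.loc[0, "best_supported"]
        assert (table.loc[table["delta_aicc"] > 2, "best_supported"] == False).all()

    def test_duplicate_models_collapse(self, model_frame):
        fit = fit_binomial_glmm(model_frame, GLMMSpec(("density_quartile",)))
        table = select_models([fit, fit])
        assert len(table) == 1

    def test_permutation_invariant(self, model_frame):
        specs = [GLMMSpec(()), GLMMSpec(("season",)),
                 GLMMSpec(("viewshed_class",))]
        fits = [fit_binomial_glmm(model_frame, s) for s in specs]
        t1 = select_models(fits)
        t2 = select_models(fits[::-1])
        pd.testing.assert_frame_equal(t1, t2)

    def test_true_structure_wins_on_generated_data(self, model_frame):
        # data were generated with quartile + season x viewshed effects
        fits = [fit_binomial_glmm(model_frame, s)
                for s in enumerate_candidates()]
        table = select_models(fits)
        best = set(table.loc[table["best_supported"], "model"])
        assert any("density_quartile" in m and "season:viewshed_class" in m
                   for m in best)


class TestPredictBootstrap:
    def test_deterministic_given_seed(self, full_fit):
        newdata = full_factorial_frame().iloc[:6]
        a = predict_bootstrap(full_fit, newdata, n_boot=200, seed=42)
        b = predict_bootstrap(full_fit, newdata, n_boot=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_detection_decreases_with_distance(self, full_fit):
        newdata = pd.DataFrame({
            "season": "fall", "viewshed_class": "low",
            "density_quartile": ["near", "near_mid", "far_mid", "far"],
        })
        out = predict_bootstrap(full_fit, newdata, n_boot=200, seed=0)
        preds = out["predicted"].to_numpy()
        assert np.all(np.diff(preds) < 0)

    def test_intervals_bracket_point_predictions(self, full_fit):
        newdata = full_factorial_frame()
        out = predict_bootstrap(full_fit, newdata, n_boot=500, seed=1,
                                include_random=False)
        assert (out["lower"] <= out["predicted"] + 1e-9).all()
        assert (out["upper"] >= out["predicted"] - 1e-9).all()

    def test_zero_variance_fit_interval_shrinks_to_delta_method(self, rng):
        # a single-site fit has no random-effect spread: the bootstrap
        # interval should approach the delta-method (Wald) width
        n = 2000
        y = (rng.uniform(size=n) < 0.4).astype(int)
        df = pd.DataFrame({"found": y, "site": "only", "season": "spring",
                           "viewshed_class": "low", "density_quartile": "near"})
        fit = fit_binomial_glmm(df, GLMMSpec(()))
        newdata = df.iloc[:1][["season", "viewshed_class", "density_quartile"]]
        out = predict_bootstrap(fit, newdata, n_boot=4000, seed=3, level=0.90)
        p_hat = y.mean()
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        delta_width = 2 * 1.6449 * se
        width = out.loc[0, "upper"] - out.loc[0, "lower"]
        assert width == pytest.approx(delta_width, rel=0.10)


def test_viewshed_effect_ordering_recovered(model_frame, full_fit):
    """Marginal predictions keep the low > moderate > high detection order."""
    newdata = pd.DataFrame({
        "season": "fall", "viewshed_class": ["low", "moderate", "high"],
        "density_quartile": "near_mid",
    })
    out = predict_bootstrap(full_fit, newdata, n_boot=100, seed=0)
    preds = out["predicted"].to_numpy()
    assert preds[0] > preds[1] > preds[2]
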