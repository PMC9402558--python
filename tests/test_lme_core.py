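"""REML engine correctness: design construction, closed-form oracles,
cross-checks against an independent implementation, model comparison."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from longlme.lme_core import (
    ComparisonError,
    DesignError,
    ModelSpec,
    build_design,
    compare_models,
    fit_lme,
)
from longlme.synthetic_data import GenerativeConfig, generate_cohort

from conftest import make_balanced_oneway


class TestDesign:
    def test_five_group_model2_shape(self, cohort_small):
        d = build_design(cohort_small, ModelSpec())
        # intercept + time + 4 group + 4 group:time + age + sex + apoe
        # + apoe:time + icv
        assert d.p == 15
        assert d.q == 2
        assert d.x_labels[:2] == ["Intercept", "time"]
        assert d.x_labels[2:6] == [
            "group[cHC]", "group[sMCI]", "group[cMCI]", "group[AD]"
        ]
        assert d.x_labels[10:] == ["baseline_age", "sex", "apoe", "apoe:time", "icv"]

    def test_two_group_design_loses_six_columns(self, cohort_small):
        mci = cohort_small.filter_subjects(
            cohort_small.data.loc[
                cohort_small.data["group"].isin(["sMCI", "cMCI"]), "subject_id"
            ]
        )
        d = build_design(mci, ModelSpec(reference_group="sMCI"))
        assert d.p == 15 - 6
        assert "group[cMCI]" in d.x_labels and "group[sMCI]" not in d.x_labels

    def test_single_visit_subject_z_block(self, cohort_small):
        first = cohort_small.data.groupby("subject_id", sort=False).head(1)
        keep_one = cohort_small.subject_ids[0]
        df = pd.concat(
            [
                cohort_small.data[cohort_small.data.subject_id != keep_one],
                first[first.subject_id == keep_one],
            ]
        )
        ds = replace_data(cohort_small, df)
        d = build_design(ds, ModelSpec())
        code = list(d.subject_ids).index(keep_one)
        block = d.z_block(code)
        assert block.shape == (1, 2)
        assert block[0, 0] == 1.0

    def test_constant_column_raises_design_error(self, cohort_small):
        df = cohort_small.data.copy()
        df["apoe"] = 0
        with pytest.raises(DesignError, match="apoe"):
            build_design(replace_data(cohort_small, df), ModelSpec())

    def test_missing_reference_group_errors(self, cohort_small):
        df = cohort_small.data[cohort_small.data.group != "sHC"]
        with pytest.raises(DesignError, match="sHC"):
            build_design(replace_data(cohort_small, df), ModelSpec())


def replace_data(ds, df):
    from longlme.synthetic_data import LongitudinalDataset

    return LongitudinalDataset(df.copy(), ds.standardized, ds.standardization)


class TestReml:
    def test_balanced_oneway_matches_anova_moments(self):
        # classical result: on balanced one-way data, REML equals the
        # ANOVA moment estimators (MSW and (MSB - MSW) / m)
        n, m = 40, 4
        ds = make_balanced_oneway(n, m, mu=1.0, sd_subject=0.8, sd_resid=0.4,
                                  seed=10)
        y = ds.data["hv"].to_numpy().reshape(n, m)
        subj_means = y.mean(axis=1)
        grand = y.mean()
        msb = m * np.sum((subj_means - grand) ** 2) / (n - 1)
        msw = np.sum((y - subj_means[:, None]) ** 2) / (n * (m - 1))
        spec = ModelSpec(fixed_terms=(), random_structure="intercept_only")
        fit = fit_lme(build_design(ds, spec))
        assert abs(fit.beta[0] - grand) < 1e-6
        assert abs(fit.sigma2 - msw) < 1e-6
        assert abs(fit.G[0, 0] - (msb - msw) / m) < 1e-6

    def test_zero_random_variance_reduces_to_ols(self):
        ds = make_balanced_oneway(30, 3, mu=0.5, sd_subject=0.0, sd_resid=0.3,
                                  seed=11)
        spec = ModelSpec(fixed_terms=("time",), random_structure="intercept_only")
        d = build_design(ds, spec)
        fit = fit_lme(d)
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        assert fit.singular  # boundary fit is returned, not raised
        assert np.allclose(fit.beta, ols, atol=1e-5)

    def test_generating_cmci_slope_recovered(self, fit_small):
        est = fit_small.coef("group[cMCI]:time")
        se = fit_small.se("group[cMCI]:time")
        assert abs(est - (-0.08)) < 3 * se

    def test_reml_criterion_is_local_optimum(self, fit_small):
        eng = fit_small._engine
        th = fit_small.theta[:-1]
        f0 = eng.profiled_crit(th, True)
        for delta in np.eye(len(th)):
            for s in (-0.05, 0.05):
                assert eng.profiled_crit(th + s * delta, True) >= f0 - 1e-7

    def test_fit_invariant_to_record_order(self, cohort_small):
        shuffled = replace_data(
            cohort_small,
            cohort_small.data.sample(frac=1.0, random_state=1),
        )
        f1 = fit_lme(build_design(cohort_small, ModelSpec()))
        f2 = fit_lme(build_design(shuffled, ModelSpec()))
        assert abs(f1.loglik_reml - f2.loglik_reml) < 1e-7
        assert np.allclose(f1.beta, f2.beta, atol=1e-7)

    def test_ml_and_reml_betas_agree_on_balanced_intercept_model(self):
        ds = make_balanced_oneway(25, 3, mu=2.0, sd_subject=0.7, sd_resid=0.5,
                                  seed=12)
        spec = ModelSpec(fixed_terms=(), random_structure="intercept_only")
        d = build_design(ds, spec)
        f_ml = fit_lme(d, "ml")
        f_reml = fit_lme(d, "reml")
        assert abs(f_ml.beta[0] - f_reml.beta[0]) < 1e-8

    def test_statsmodels_crosscheck(self, cohort_small):
        sm = pytest.importorskip("statsmodels.formula.api")
        df = cohort_small.data.copy()
        df["time"] = df["visit_time"]
        md = sm.mixedlm("hv ~ time + C(group, Treatment('sHC'))",
                        df, groups=df["subject_id"], re_formula="~time")
        ref = md.fit(reml=True, method=["lbfgs", "cg"])
        spec = ModelSpec(fixed_terms=("time", "group"))
        fit = fit_lme(build_design(cohort_small, spec))
        assert fit.loglik_reml >= ref.llf - 1e-4  # at least as good an optimum
        if abs(fit.loglik_reml - ref.llf) < 1e-4:  # same optimum -> same params
            assert abs(fit.coef("time") - ref.params["time"]) < 1e-4
            assert abs(fit.sigma2 - ref.scale) < 1e-4


class TestModelComparison:
    def test_self_comparison_is_null(self, fit_small):
        out = compare_models(fit_small, fit_small)
        assert out["lrt_stat"] == 0.0
        assert out["p_value"] == 1.0

    def test_mismatched_data_errors(self, cohort_small, fit_small):
        sub = cohort_small.filter_subjects(cohort_small.subject_ids[:100])
        other = fit_lme(build_design(sub, ModelSpec()))
        with pytest.raises(ComparisonError):
            compare_models(fit_small, other)

    def test_slope_model_preferred_when_slopes_vary(self):
        # at the full cohort size the slope variance is well identified and
        # the intercept+slope model wins on AIC essentially always
        prefer = 0
        n_sim = 10
        for s in range(n_sim):
            ds = generate_cohort(GenerativeConfig(), seed=100 + s)
            f1 = fit_lme(build_design(ds, ModelSpec(random_structure="intercept_only")))
            f2 = fit_lme(build_design(ds, ModelSpec()))
            out = compare_models(f1, f2)
            prefer += out["preferred"] == "big"
            assert out["df"] == 2
        assert prefer >= round(0.95 * n_sim)

    def test_lrt_conservative_under_null_slope_variance(self):
        # boundary case: generating slope variance is zero, so the plain
        # chi2(2) reference over-covers and rejects at most ~alpha
        rejections = 0
        n_sim = 150
        base = GenerativeConfig().scaled(0.12)
        null_cfg = replace(base, random_slope_sd=0.0, random_corr=0.0)
        for s in range(n_sim):
            ds = generate_cohort(null_cfg, seed=2000 + s)
            f1 = fit_lme(build_design(ds, ModelSpec(random_structure="intercept_only")))
            f2 = fit_lme(build_design(ds, ModelSpec()))
            rejections += compare_models(f1, f2)["p_value"] < 0.05
        assert rejections / n_sim <= 0.06
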