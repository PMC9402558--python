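"""Gibbs sampler validation: closed-form conjugate check, agreement with
REML under diffuse priors, CrI decision rules, diagnostics, sparse data."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longlme.blme_core import (
    BlmePosterior,
    McmcConfig,
    PosteriorError,
    PriorConfig,
    _ess,
    _split_rhat,
    cri_decision_pairwise,
    cri_decision_vs_reference,
    fit_blme,
)
from longlme.lme_core import ModelSpec, build_design, fit_lme
from longlme.synthetic_data import (
    GenerativeConfig,
    LongitudinalDataset,
    generate_cohort,
)

from conftest import make_balanced_oneway


@pytest.fixture(scope="module")
def posterior_small(cohort_small):
    design = build_design(cohort_small, ModelSpec())
    return fit_blme(
        design,
        mcmc=McmcConfig(n_chains=4, n_iter=1200, n_warmup=400, seed=21),
    )


class TestSamplerCorrectness:
    def test_matches_conjugate_regression_posterior(self):
        # with b frozen at zero and sigma2 known, beta's posterior is the
        # textbook Gaussian conjugate posterior; compare marginals by KS
        rng = np.random.default_rng(0)
        n, sigma2, tau = 120, 0.25, 10.0
        ds = make_balanced_oneway(n // 2, 2, mu=0.0, sd_subject=0.0,
                                  sd_resid=np.sqrt(sigma2), seed=0)
        spec = ModelSpec(fixed_terms=("time",), random_structure="intercept_only")
        design = build_design(ds, spec)
        X, y = design.X, design.y
        prec = X.T @ X / sigma2 + np.eye(2) / tau**2
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ y / sigma2)

        post = fit_blme(
            design,
            priors=PriorConfig(beta_prior_sd=tau),
            mcmc=McmcConfig(n_chains=2, n_iter=6000, n_warmup=1000, seed=1),
            fix_sigma2=sigma2,
            fix_b_zero=True,
        )
        for j, lbl in enumerate(design.x_labels):
            draws = post.draws_for(lbl)
            ks = stats.kstest(
                draws, "norm", args=(mean[j], np.sqrt(cov[j, j]))
            ).statistic
            assert ks < 0.05

    def test_diffuse_prior_matches_reml(self, cohort_small):
        design = build_design(cohort_small, ModelSpec())
        reml = fit_lme(design)
        post = fit_blme(
            design,
            priors=PriorConfig(beta_prior_sd=1e6),
            mcmc=McmcConfig(n_chains=2, n_iter=1500, n_warmup=500, seed=3),
        )
        for lbl in post.group_time_labels():
            diff = abs(post.posterior_mean(lbl) - reml.coef(lbl))
            assert diff < 2 * post.posterior_sd(lbl)

    def test_deterministic_given_seed(self, cohort_small):
        design = build_design(cohort_small, ModelSpec())
        mcmc = McmcConfig(n_chains=2, n_iter=400, n_warmup=200, seed=5)
        a = fit_blme(design, mcmc=mcmc)
        b = fit_blme(design, mcmc=mcmc)
        assert np.array_equal(a.draws, b.draws)

    def test_different_seeds_agree_within_mc_error(self, cohort_small):
        design = build_design(cohort_small, ModelSpec())
        a = fit_blme(design, mcmc=McmcConfig(2, 1200, 400, 1, seed=11))
        b = fit_blme(design, mcmc=McmcConfig(2, 1200, 400, 1, seed=12))
        lbl = "group[cMCI]:time"
        mc_se = a.posterior_sd(lbl) * np.sqrt(1 / a.ess[lbl] + 1 / b.ess[lbl])
        assert abs(a.posterior_mean(lbl) - b.posterior_mean(lbl)) < 3 * mc_se

    def test_cri_width_shrinks_like_sqrt_n(self):
        widths = []
        for size, seed in ((100, 1), (400, 2), (1600, 3)):
            cfg = GenerativeConfig().scaled(size / 670)
            ds = generate_cohort(cfg, seed=seed)
            post = fit_blme(
                build_design(ds, ModelSpec()),
                mcmc=McmcConfig(n_chains=2, n_iter=900, n_warmup=300, seed=seed),
            )
            lo, _, hi = post.cri["group[cMCI]:time"]
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)

    def test_prior_dominated_smoke_two_subjects(self):
        rows = [
            dict(subject_id="A", group="sHC", visit_time=0.0, hv=0.1, icv=0.0,
                 baseline_age=70.0, sex=0, apoe=0),
            dict(subject_id="B", group="sHC", visit_time=0.0, hv=-0.2, icv=0.0,
                 baseline_age=72.0, sex=1, apoe=0),
        ]
        ds = LongitudinalDataset(pd.DataFrame(rows), standardized=True)
        design = build_design(ds, ModelSpec(fixed_terms=()))
        post = fit_blme(
            design, mcmc=McmcConfig(n_chains=2, n_iter=400, n_warmup=200, seed=0)
        )
        assert np.all(np.isfinite(post.draws))

    def test_runs_in_frequentist_inestimable_regime(self, cohort_small):
        # keep only the baseline visit for most subjects: n_obs < 2 N
        df = cohort_small.data.groupby("subject_id", sort=False).head(1)
        # keep a few fully-observed subjects in every group so each
        # group-by-time column stays identified
        keep_full = set(
            cohort_small.data.groupby("group", sort=False)["subject_id"]
            .unique()
            .apply(lambda ids: list(ids[:4]))
            .explode()
        )
        df = pd.concat(
            [
                cohort_small.data[cohort_small.data.subject_id.isin(keep_full)],
                df[~df.subject_id.isin(keep_full)],
            ]
        )
        ds = LongitudinalDataset(df.copy(), standardized=True)
        assert ds.n_obs < 2 * ds.n_subjects
        post = fit_blme(
            build_design(ds, ModelSpec()),
            mcmc=McmcConfig(n_chains=2, n_iter=1200, n_warmup=600, seed=2),
        )
        assert np.all(np.isfinite(post.draws))
        assert all(np.isfinite(v) for v in post.rhat.values())


class TestDecisionRules:
    def test_contains_zero_rule(self, posterior_small):
        lbl = "group[AD]:time"  # strong atrophy: CrI below zero
        d = cri_decision_vs_reference(posterior_small, lbl)
        assert d["significant"]
        assert d["cri"][1] < 0

    def test_published_interval_pattern_is_disjoint(self):
        # AD-like CrI (-0.13, -0.08) vs sMCI-like CrI (-0.04, 0.01):
        # disjoint intervals fire the overlap rule
        assert -0.08 < -0.04  # disjoint
        post = _synthetic_posterior(
            {"group[AD]:time": (-0.105, 0.0125), "group[sMCI]:time": (-0.015, 0.0125)}
        )
        d = cri_decision_pairwise(post, "group[AD]:time", "group[sMCI]:time")
        assert d["significant"]
        assert d["difference_excludes_zero"]

    def test_identical_parameters_overlap(self, posterior_small):
        d = cri_decision_pairwise(
            posterior_small, "group[cMCI]:time", "group[cMCI]:time"
        )
        assert not d["significant"]

    def test_unknown_label_errors(self, posterior_small):
        with pytest.raises(PosteriorError):
            cri_decision_vs_reference(posterior_small, "group[XX]:time")

    def test_overlap_rule_stricter_than_difference_rule(self):
        # whenever the overlap rule fires on independent posteriors, the
        # difference CrI excludes zero as well
        rng = np.random.default_rng(7)
        fired = 0
        for _ in range(200):
            mu = rng.normal(0, 0.1, size=2)
            sd = rng.uniform(0.01, 0.05, size=2)
            post = _synthetic_posterior(
                {"group[AD]:time": (mu[0], sd[0]), "group[sMCI]:time": (mu[1], sd[1])},
                rng=rng,
            )
            d = cri_decision_pairwise(post, "group[AD]:time", "group[sMCI]:time")
            if d["significant"]:
                fired += 1
                assert d["difference_excludes_zero"]
        assert fired > 10  # the property was actually exercised


def _synthetic_posterior(params: dict, rng=None, n=4000) -> BlmePosterior:
    """A stand-in posterior assembled from independent normal draws, for
    exercising interval decision rules in isolation (synthetic; not MCMC)."""
    rng = rng or np.random.default_rng(0)
    labels = list(params)
    draws = np.stack(
        [rng.normal(mu, sd, size=n) for mu, sd in params.values()], axis=1
    )[None]
    cri = {
        lbl: tuple(np.percentile(draws[0, :, j], [2.5, 50, 97.5]))
        for j, lbl in enumerate(labels)
    }
    return BlmePosterior(
        draws=draws, labels=labels,
        rhat={l: 1.0 for l in labels}, ess={l: float(n) for l in labels},
        cri=cri, n_chains=1, n_warmup=0, n_kept=n, thin=1, seed=0,
        converged=True, max_rhat=1.0,
    )


class TestDiagnostics:
    def test_rhat_and_ess_against_arviz(self, posterior_small):
        az = pytest.importorskip("arviz")
        j = posterior_small.labels.index("group[cMCI]:time")
        x = posterior_small.draws[:, :, j]
        ref_rhat = float(az.rhat(az.convert_to_dataset(x)).x)
        ref_ess = float(az.ess(az.convert_to_dataset(x)).x)
        assert _split_rhat(x) == pytest.approx(ref_rhat, abs=0.01)
        assert _ess(x) == pytest.approx(ref_ess, rel=0.25)

    def test_rhat_detects_disagreeing_chains(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 500))
        x[1] += 5.0
        assert _split_rhat(x) > 1.5

    def test_posterior_converged_flag(self, posterior_small):
        assert posterior_small.max_rhat <= 1.05
        assert posterior_small.converged
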