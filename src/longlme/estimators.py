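"""Scikit-learn style estimators wrapping the frequentist and Bayesian fits.

``FrequentistLME`` and ``BayesianLME`` follow the sklearn estimator
protocol — construction holds only hyperparameters, :meth:`fit` validates
the input and stores results in trailing-underscore attributes, and
``get_params``/``set_params``/``clone`` work for pipeline and
model-selection composition.  Both accept a long-format
:class:`~longlme.synthetic_data.LongitudinalDataset` or an equivalent
pandas DataFrame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .blme_core import McmcConfig, PriorConfig, fit_blme
from .flme_inference import run_contrast_battery
from .lme_core import FIXED_TERMS_FULL, ModelSpec, build_design, fit_lme
from .synthetic_data import LongitudinalDataset


def _as_dataset(data) -> LongitudinalDataset:
    if isinstance(data, LongitudinalDataset):
        return data
    if isinstance(data, pd.DataFrame):
        return LongitudinalDataset(data.copy(), standardized=True)
    raise TypeError(
        "expected a LongitudinalDataset or long-format DataFrame, "
        f"got {type(data).__name__}"
    )


class FrequentistLME(BaseEstimator):
    """Linear mixed-effects regression fitted by REML (or ML).

    Parameters
    ----------
    random_structure : {'intercept_and_slope', 'intercept_only'}
        Per-subject random effects.
    method : {'reml', 'ml'}
        Estimation criterion.
    reference_group : str or None
        Baseline clinical group for treatment coding; None picks the first
        group present in label order.
    fixed_terms : tuple of str or None
        Ordered fixed-effect terms; None uses the full roster.
    outcome : str
        Outcome column.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray — fixed-effect estimates.
    coef_names_ : list of str — labels aligned with ``coef_``.
    cov_re_ : ndarray — random-effect covariance G.
    sigma2_ : float — residual variance.
    beta_cov_ : ndarray — asymptotic covariance of ``coef_``.
    loglik_ : float — maximized criterion log-likelihood.
    aic_ : float — AIC (criterion-matched dialect).
    converged_, singular_ : bool.
    result_ : :class:`~longlme.lme_core.FlmeFit` — the full fit object.
    """

    def __init__(
        self,
        random_structure: str = "intercept_and_slope",
        method: str = "reml",
        reference_group: str | None = None,
        fixed_terms: tuple | None = None,
        outcome: str = "hv",
    ):
        self.random_structure = random_structure
        self.method = method
        self.reference_group = reference_group
        self.fixed_terms = fixed_terms
        self.outcome = outcome

    def _model_spec(self, dataset: LongitudinalDataset) -> ModelSpec:
        ref = self.reference_group or dataset.groups_present()[0]
        terms = tuple(self.fixed_terms) if self.fixed_terms else FIXED_TERMS_FULL
        return ModelSpec(
            outcome=self.outcome,
            fixed_terms=terms,
            random_structure=self.random_structure,
            reference_group=ref,
        )

    def fit(self, X, y=None):
        dataset = _as_dataset(X)
        spec = self._model_spec(dataset)
        design = build_design(dataset, spec)
        result = fit_lme(design, self.method)
        self.result_ = result
        self.design_ = design
        self.model_spec_ = spec
        self.coef_ = result.beta
        self.coef_names_ = list(result.beta_labels)
        self.cov_re_ = result.G
        self.sigma2_ = result.sigma2
        self.beta_cov_ = result.beta_cov
        self.loglik_ = result.loglik_reml if self.method == "reml" else result.loglik_ml
        self.aic_ = result.aic
        self.converged_ = result.converged
        self.singular_ = result.singular
        self.n_features_in_ = design.p
        return self

    def predict(self, X):
        """Population-level (fixed-effects) prediction for new records."""
        dataset = _as_dataset(X)
        design = build_design(dataset, self.model_spec_)
        if design.x_labels != self.coef_names_:
            raise ValueError(
                "new data realizes a different design than the fitted one "
                f"({design.x_labels} vs {self.coef_names_})"
            )
        return design.X @ self.coef_

    def score(self, X, y=None):
        """Mean log-likelihood per observation under the fitted parameters
        is not defined for new grouping structures; returns the fitted
        criterion log-likelihood when called on the training data shape."""
        return self.loglik_

    def contrast_battery(self, dataset_kind: str = "five_group", **kwargs):
        return run_contrast_battery(self.result_, dataset_kind, **kwargs)


class BayesianLME(BaseEstimator):
    """Bayesian linear mixed-effects regression via blocked Gibbs sampling.

    Parameters mirror :class:`FrequentistLME` plus prior and MCMC settings.

    Attributes (after fit)
    ----------------------
    posterior_ : :class:`~longlme.blme_core.BlmePosterior`
    coef_ : ndarray — posterior medians of the fixed effects.
    coef_names_ : list of str.
    cri_ : dict — (2.5%, median, 97.5%) per parameter.
    max_rhat_, converged_ : convergence diagnostics.
    """

    def __init__(
        self,
        random_structure: str = "intercept_and_slope",
        reference_group: str | None = None,
        fixed_terms: tuple | None = None,
        outcome: str = "hv",
        beta_prior_sd: float = 10.0,
        sigma2_shape: float = 2.0,
        sigma2_scale: float = 0.5,
        g_df: float = 4.0,
        g_scale_diag: float = 0.1,
        n_chains: int = 4,
        n_iter: int = 2000,
        n_warmup: int = 1000,
        thin: int = 1,
        random_state: int = 0,
    ):
        self.random_structure = random_structure
        self.reference_group = reference_group
        self.fixed_terms = fixed_terms
        self.outcome = outcome
        self.beta_prior_sd = beta_prior_sd
        self.sigma2_shape = sigma2_shape
        self.sigma2_scale = sigma2_scale
        self.g_df = g_df
        self.g_scale_diag = g_scale_diag
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_warmup = n_warmup
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y=None):
        dataset = _as_dataset(X)
        ref = self.reference_group or dataset.groups_present()[0]
        terms = tuple(self.fixed_terms) if self.fixed_terms else FIXED_TERMS_FULL
        spec = ModelSpec(
            outcome=self.outcome,
            fixed_terms=terms,
            random_structure=self.random_structure,
            reference_group=ref,
        )
        design = build_design(dataset, spec)
        priors = PriorConfig(
            beta_prior_sd=self.beta_prior_sd,
            sigma2_shape=self.sigma2_shape,
            sigma2_scale=self.sigma2_scale,
            g_df=self.g_df,
            g_scale_diag=self.g_scale_diag,
        )
        mcmc = McmcConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_warmup=self.n_warmup,
            thin=self.thin,
            seed=self.random_state,
        )
        post = fit_blme(design, priors=priors, mcmc=mcmc)
        self.posterior_ = post
        self.design_ = design
        self.model_spec_ = spec
        self.coef_names_ = list(design.x_labels)
        self.coef_ = np.array([post.cri[lbl][1] for lbl in self.coef_names_])
        self.cri_ = dict(post.cri)
        self.max_rhat_ = post.max_rhat
        self.converged_ = post.converged
        self.n_features_in_ = design.p
        return self

    def predict(self, X):
        dataset = _as_dataset(X)
        design = build_design(dataset, self.model_spec_)
        if design.x_labels != self.coef_names_:
            raise ValueError("new data realizes a different design than fitted")
        return design.X @ self.coef_
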