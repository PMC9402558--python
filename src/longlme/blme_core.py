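"""Bayesian fit of the longitudinal mixed model by blocked Gibbs sampling.

The Gaussian linear mixed model is conditionally conjugate, so every full
conditional is available in closed form:

    beta | b, sigma2   ~ multivariate normal (normal prior on beta),
    b_i  | beta, G, sigma2 ~ bivariate (or univariate) normal,
    sigma2 | beta, b   ~ inverse-gamma,
    G    | b           ~ inverse-Wishart.

(beta, b) are drawn as one block: beta from its conditional with the
random effects integrated out (a multivariate normal whose moments come
from the same per-subject Woodbury identities the REML engine uses), then
b | beta.  The naive beta | b update mixes pathologically slowly in this
model because per-subject effects can absorb group-level fixed effects;
the collapsed block draw is exact and removes that random walk.

Chains start from overdispersed perturbations of the OLS solution;
post-warmup draws are thinned and pooled.  Convergence is summarised by
split-R-hat and an autocorrelation-based effective sample size per
parameter (Geyer's initial-positive-sequence truncation).

Inference follows credible-interval rules: a coefficient differs from the
reference when its central 95% CrI (2.5th-97.5th percentiles) excludes
zero; two non-reference groups differ when their CrIs do not overlap (the
posterior CrI of the difference is reported alongside as a less
conservative alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lme_core import DesignMatrices, _REMLEngine


def _sample_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from an inverse-Wishart via the Bartlett decomposition.

    If W ~ Wishart(df, scale^{-1}) then W^{-1} ~ IW(df, scale).  Direct
    construction avoids per-iteration scipy frozen-distribution overhead.
    """
    q = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((q, q))
    for i in range(q):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    T = L @ A  # W = T T'
    Tinv = np.linalg.inv(T)
    return Tinv.T @ Tinv


class PosteriorError(ValueError):
    pass


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors on the standardized-HV scale.

    ``beta_prior_sd``: sd of independent zero-mean normal priors on all
    fixed effects.  ``sigma2_shape``/``sigma2_scale``: inverse-gamma prior
    on the residual variance.  ``g_df``/``g_scale_diag``: inverse-Wishart
    prior on the random-effect covariance (scale matrix
    ``g_scale_diag * I``).
    """

    beta_prior_sd: float = 10.0
    sigma2_shape: float = 2.0
    sigma2_scale: float = 0.5
    g_df: float = 4.0
    g_scale_diag: float = 0.1

    def validate(self, q: int) -> None:
        if self.beta_prior_sd <= 0:
            raise ValueError("beta_prior_sd must be > 0")
        if self.sigma2_shape <= 0 or self.sigma2_scale <= 0:
            raise ValueError("inverse-gamma shape/scale must be > 0")
        if self.g_df <= q + 1:
            raise ValueError(f"inverse-Wishart df must exceed q+1={q + 1}")
        if self.g_scale_diag <= 0:
            raise ValueError("g_scale_diag must be > 0")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_chains < 1 or self.n_iter <= self.n_warmup or self.thin < 1:
            raise ValueError("invalid MCMC configuration")


@dataclass
class BlmePosterior:
    """Pooled posterior draws with per-parameter diagnostics.

    ``draws`` has shape (n_chains, n_kept, n_params); ``labels`` names the
    columns (beta labels, then G entries, then sigma2).  ``cri`` maps each
    label to (2.5th percentile, median, 97.5th percentile).
    """

    draws: np.ndarray
    labels: list[str]
    rhat: dict[str, float]
    ess: dict[str, float]
    cri: dict[str, tuple[float, float, float]]
    n_chains: int
    n_warmup: int
    n_kept: int
    thin: int
    seed: int
    converged: bool
    max_rhat: float

    def draws_for(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise PosteriorError(f"unknown parameter {label!r}; have {self.labels}")
        return self.draws[:, :, self.labels.index(label)].reshape(-1)

    def posterior_mean(self, label: str) -> float:
        return float(np.mean(self.draws_for(label)))

    def posterior_sd(self, label: str) -> float:
        return float(np.std(self.draws_for(label), ddof=1))

    def group_time_labels(self) -> list[str]:
        return [
            lbl for lbl in self.labels
            if lbl.startswith("group[") and lbl.endswith(":time")
        ]

    def draws_frame(self) -> pd.DataFrame:
        """Pooled draws as a DataFrame (chain and iteration as columns),
        suitable for CSV persistence."""
        m, k, _ = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(m * k, -1), columns=self.labels
        )
        frame.insert(0, "chain", np.repeat(np.arange(m), k))
        frame.insert(1, "iteration", np.tile(np.arange(k), m))
        return frame

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in self.labels:
            lo, med, hi = self.cri[lbl]
            rows.append(
                {
                    "parameter": lbl,
                    "estimate": med,
                    "cri_2.5%": lo,
                    "cri_97.5%": hi,
                    "rhat": self.rhat[lbl],
                    "ess": self.ess[lbl],
                }
            )
        return pd.DataFrame(rows)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of draws shaped (n_chains, n_iter)."""
    m, n = x.shape
    half = n // 2
    if half < 2:
        return np.nan
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def _ess(x: np.ndarray) -> float:
    """Effective sample size of draws shaped (n_chains, n_iter), using
    chain-averaged autocorrelations with Geyer initial-positive truncation."""
    m, n = x.shape
    half = n // 2
    if half < 4:
        return np.nan
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m2, n2 = chains.shape
    centered = chains - chains.mean(axis=1, keepdims=True)
    # per-chain autocovariance via FFT
    size = 2 * n2
    f = np.fft.rfft(centered, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n2].real / n2
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    means = chains.mean(axis=1)
    B_over_n = means.var(ddof=1)
    var_hat = (n2 - 1) / n2 * W + B_over_n
    if var_hat <= 0:
        return float(m2 * n2)
    rho = 1.0 - (W - acov.mean(axis=0)) / var_hat
    # Geyer: sum consecutive pairs while positive
    tau = 1.0
    t = 1
    while t + 1 < n2:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(m2 * n2 / max(tau, 1e-12), m2 * n2))


def fit_blme(
    design: DesignMatrices,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    fix_sigma2: float | None = None,
    fix_b_zero: bool = False,
) -> BlmePosterior:
    """Run the blocked Gibbs sampler on a realized design.

    ``fix_sigma2`` and ``fix_b_zero`` freeze the residual variance or the
    random effects at zero; they exist to validate the sampler against the
    closed-form conjugate linear-regression posterior and are not used in
    analyses.  Deterministic given ``mcmc.seed``.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    q = design.q
    priors.validate(q)
    mcmc.validate()

    y, X, Z, codes = design.y, design.X, design.Z, design.subject_codes
    n, p, N = design.n_obs, design.p, design.n_subjects
    engine = _REMLEngine(design)
    XtX, Xty = engine.XtX, engine.Xty
    prior_prec_beta = np.eye(p) / priors.beta_prior_sd**2
    S0 = priors.g_scale_diag * np.eye(q)

    # per-subject cross-products for the b updates
    starts = np.searchsorted(codes, np.arange(N))
    bounds = np.append(starts, n)
    ZZ = np.add.reduceat(Z[:, :, None] * Z[:, None, :], bounds[:-1], axis=0)

    n_kept = (mcmc.n_iter - mcmc.n_warmup) // mcmc.thin
    labels = list(design.x_labels)
    g_labels = (
        ["G[0,0]"] if q == 1 else ["G[0,0]", "G[1,0]", "G[1,1]"]
    )
    labels = labels + g_labels + ["sigma2"]
    n_params = len(labels)
    all_draws = np.empty((mcmc.n_chains, n_kept, n_params))

    beta_ols = np.linalg.solve(XtX + 1e-8 * np.eye(p), X.T @ y)
    resid_var = max(float(np.var(y - X @ beta_ols)), 1e-6)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        # overdispersed start
        beta = beta_ols + rng.standard_normal(p) * 0.5 * (1.0 + 0.5 * c)
        sigma2 = fix_sigma2 if fix_sigma2 is not None else resid_var * np.exp(
            rng.normal(0, 0.5)
        )
        G = S0 / max(priors.g_df - q - 1, 1.0) * np.exp(rng.normal(0, 0.5))
        b = np.zeros((N, q))
        keep = 0
        for it in range(mcmc.n_iter):
            # --- beta | G, sigma2 (random effects integrated out) ---
            if not fix_b_zero:
                psi = G / sigma2
                XtVX, XtVy = engine.gls_moments(psi)
            else:
                XtVX, XtVy = XtX, Xty
            prec_b = XtVX / sigma2 + prior_prec_beta
            cF = np.linalg.cholesky(prec_b)
            mean_b = np.linalg.solve(cF.T, np.linalg.solve(cF, XtVy / sigma2))
            beta = mean_b + np.linalg.solve(cF.T, rng.standard_normal(p))
            # --- b | beta, G, sigma2 ---
            if not fix_b_zero:
                G_inv = np.linalg.inv(G)
                prec = ZZ / sigma2 + G_inv  # (N, q, q)
                resid = y - X @ beta
                rhs = np.add.reduceat(Z * resid[:, None], bounds[:-1], axis=0) / sigma2
                if q == 1:
                    var = 1.0 / prec[:, 0, 0]
                    mean = var * rhs[:, 0]
                    b[:, 0] = mean + np.sqrt(var) * rng.standard_normal(N)
                else:
                    # closed-form 2x2 inverse + Cholesky
                    a11, a12, a22 = prec[:, 0, 0], prec[:, 0, 1], prec[:, 1, 1]
                    det = a11 * a22 - a12**2
                    c11, c12, c22 = a22 / det, -a12 / det, a11 / det
                    mean0 = c11 * rhs[:, 0] + c12 * rhs[:, 1]
                    mean1 = c12 * rhs[:, 0] + c22 * rhs[:, 1]
                    l11 = np.sqrt(c11)
                    l21 = c12 / l11
                    l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
                    zdraw = rng.standard_normal((N, 2))
                    b[:, 0] = mean0 + l11 * zdraw[:, 0]
                    b[:, 1] = mean1 + l21 * zdraw[:, 0] + l22 * zdraw[:, 1]
                zb = np.sum(Z * b[codes], axis=1)
            else:
                zb = np.zeros(n)
            # --- sigma2 | rest ---
            if fix_sigma2 is None:
                resid = y - X @ beta - zb
                shape = priors.sigma2_shape + 0.5 * n
                scale = priors.sigma2_scale + 0.5 * float(resid @ resid)
                sigma2 = scale / rng.gamma(shape)
            # --- G | b ---
            if not fix_b_zero:
                scale_G = S0 + b.T @ b
                G = _sample_invwishart(rng, priors.g_df + N, scale_G)
            if it >= mcmc.n_warmup and (it - mcmc.n_warmup) % mcmc.thin == 0:
                row = np.concatenate(
                    [
                        beta,
                        [G[0, 0]] if q == 1 else [G[0, 0], G[1, 0], G[1, 1]],
                        [sigma2],
                    ]
                )
                all_draws[c, keep] = row
                keep += 1

    rhat, ess, cri = {}, {}, {}
    pooled = all_draws.reshape(-1, n_params)
    for j, lbl in enumerate(labels):
        x = all_draws[:, :, j]
        rhat[lbl] = _split_rhat(x) if mcmc.n_chains > 1 or n_kept >= 4 else np.nan
        ess[lbl] = _ess(x)
        lo, med, hi = np.percentile(pooled[:, j], [2.5, 50.0, 97.5])
        cri[lbl] = (float(lo), float(med), float(hi))
    finite_rhat = [v for v in rhat.values() if np.isfinite(v)]
    max_rhat = float(max(finite_rhat)) if finite_rhat else np.nan
    return BlmePosterior(
        draws=all_draws,
        labels=labels,
        rhat=rhat,
        ess=ess,
        cri=cri,
        n_chains=mcmc.n_chains,
        n_warmup=mcmc.n_warmup,
        n_kept=n_kept,
        thin=mcmc.thin,
        seed=mcmc.seed,
        converged=bool(np.isfinite(max_rhat) and max_rhat <= 1.05),
        max_rhat=max_rhat,
    )


def cri_decision_vs_reference(posterior: BlmePosterior, param_label: str) -> dict:
    """Significant iff the central 95% CrI excludes zero."""
    lo, med, hi = posterior.cri[
        _checked_label(posterior, param_label)
    ]
    return {"significant": bool(lo > 0.0 or hi < 0.0), "cri": (lo, hi), "median": med}


def cri_decision_pairwise(
    posterior: BlmePosterior, label_a: str, label_b: str
) -> dict:
    """Significant iff the two 95% CrIs are disjoint (overlap rule).

    The CrI of the posterior difference a - b is reported as supplementary
    output; excluding zero under the difference rule is a strictly weaker
    requirement than disjoint marginal intervals.
    """
    a = _checked_label(posterior, label_a)
    b = _checked_label(posterior, label_b)
    lo_a, _, hi_a = posterior.cri[a]
    lo_b, _, hi_b = posterior.cri[b]
    disjoint = hi_a < lo_b or hi_b < lo_a
    diff = posterior.draws_for(a) - posterior.draws_for(b)
    d_lo, d_hi = np.percentile(diff, [2.5, 97.5])
    return {
        "significant": bool(disjoint),
        "cri_a": (lo_a, hi_a),
        "cri_b": (lo_b, hi_b),
        "difference_cri": (float(d_lo), float(d_hi)),
        "difference_excludes_zero": bool(d_lo > 0.0 or d_hi < 0.0),
    }


def _checked_label(posterior: BlmePosterior, label: str) -> str:
    if label not in posterior.labels:
        raise PosteriorError(f"unknown parameter {label!r}")
    return label
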