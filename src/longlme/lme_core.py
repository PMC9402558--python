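"""Design construction and (restricted) maximum-likelihood fitting of the
longitudinal linear mixed-effects model.

The model for subject i with visit times t_ij is

    y_ij = x_ij' beta + z_ij' b_i + eps_ij,
    b_i ~ N(0, G),   eps_ij ~ N(0, sigma2),

with z_ij = (1,) for a random-intercept model or (1, t_ij) for random
intercept and slope.  Fitting maximizes the profiled (restricted)
log-likelihood over a log-Cholesky parameterization of the scaled
random-effect covariance Psi = G / sigma2; beta and sigma2 have closed
forms at each Psi.  Per-subject Woodbury/Sylvester identities reduce every
criterion evaluation to batched q x q solves, which keeps refitting cheap
enough for the sequential-removal simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .synthetic_data import GROUP_LABELS, LongitudinalDataset

_LOG2PI = np.log(2.0 * np.pi)

FIXED_TERMS_FULL = (
    "time",
    "group",
    "group:time",
    "baseline_age",
    "sex",
    "apoe",
    "apoe:time",
    "icv",
)


class DesignError(ValueError):
    """Invalid or rank-deficient design."""


class FitError(RuntimeError):
    """The optimizer failed to produce a usable fit."""


class ComparisonError(ValueError):
    """Model comparison requested on non-nested or mismatched fits."""


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic definition of the mixed model.

    ``fixed_terms`` is an ordered subset of :data:`FIXED_TERMS_FULL`
    (an intercept is always included); ``random_structure`` selects the
    random-intercept or random-intercept-and-slope model; group terms use
    treatment (dummy) coding against ``reference_group``.
    """

    outcome: str = "hv"
    fixed_terms: tuple[str, ...] = FIXED_TERMS_FULL
    random_structure: str = "intercept_and_slope"
    reference_group: str = "sHC"

    def __post_init__(self):
        unknown = [t for t in self.fixed_terms if t not in FIXED_TERMS_FULL]
        if unknown:
            raise DesignError(f"unknown fixed terms: {unknown}")
        if "group:time" in self.fixed_terms and not (
            "group" in self.fixed_terms and "time" in self.fixed_terms
        ):
            raise DesignError("group:time requires both group and time terms")
        if self.random_structure not in ("intercept_only", "intercept_and_slope"):
            raise DesignError(
                "random_structure must be 'intercept_only' or 'intercept_and_slope'"
            )

    @property
    def q(self) -> int:
        return 2 if self.random_structure == "intercept_and_slope" else 1


@dataclass
class DesignMatrices:
    """Realized fixed/random design with per-subject grouping.

    Records are sorted so each subject's rows are contiguous; ``subject_codes``
    maps each row to 0..n_subjects-1 in ``subject_ids`` order.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    subject_codes: np.ndarray
    subject_ids: np.ndarray
    x_labels: list[str]
    q: int

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def z_block(self, code: int) -> np.ndarray:
        return self.Z[self.subject_codes == code]


def build_design(dataset: LongitudinalDataset, spec: ModelSpec) -> DesignMatrices:
    """Realize the model formula as y, X and per-subject Z blocks.

    Column order is fixed: intercept, time, group dummies (label order
    cHC, sMCI, cMCI, AD restricted to groups present), group-by-time
    dummies, baseline_age, sex, apoe, apoe:time, icv.  Raises
    :class:`DesignError` on rank deficiency, naming the collinear columns.
    """
    df = dataset.data
    if len(df) == 0:
        raise DesignError("empty dataset")
    present = dataset.groups_present()
    needs_groups = "group" in spec.fixed_terms
    if needs_groups and spec.reference_group not in present:
        raise DesignError(
            f"reference group {spec.reference_group!r} absent from data "
            f"(present: {present})"
        )

    t = df["visit_time"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels: list[str] = ["Intercept"]
    dummy_order = [
        g for g in GROUP_LABELS if g in present and g != spec.reference_group
    ]
    for term in spec.fixed_terms:
        if term == "time":
            cols.append(t)
            labels.append("time")
        elif term == "group":
            for g in dummy_order:
                cols.append((df["group"] == g).to_numpy(dtype=float))
                labels.append(f"group[{g}]")
        elif term == "group:time":
            for g in dummy_order:
                cols.append((df["group"] == g).to_numpy(dtype=float) * t)
                labels.append(f"group[{g}]:time")
        elif term == "apoe:time":
            cols.append(df["apoe"].to_numpy(dtype=float) * t)
            labels.append("apoe:time")
        else:
            cols.append(df[term].to_numpy(dtype=float))
            labels.append(term)
    X = np.column_stack(cols)

    # rank check via pivoted QR
    r_diag = np.abs(np.diag(linalg.qr(X, mode="r", pivoting=True)[0]))
    tol = max(X.shape) * np.finfo(float).eps * (r_diag[0] if r_diag[0] > 0 else 1.0)
    if np.sum(r_diag > tol) < X.shape[1]:
        piv = linalg.qr(X, mode="r", pivoting=True)[1]
        bad = [labels[piv[i]] for i in range(len(r_diag)) if r_diag[i] <= tol]
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")

    codes, ids = pd.factorize(df["subject_id"], sort=False)
    order = np.argsort(codes, kind="stable")
    q = spec.q
    Z = np.ones((len(df), q))
    if q == 2:
        Z[:, 1] = t
    return DesignMatrices(
        y=df[spec.outcome].to_numpy(dtype=float)[order],
        X=X[order],
        Z=Z[order],
        subject_codes=codes[order],
        subject_ids=np.asarray(ids),
        x_labels=labels,
        q=q,
    )


# ---------------------------------------------------------------------------
# REML engine


def _psi_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Scaled covariance Psi = L L' from its log-Cholesky parameters.

    Log-diagonals are clipped at +-40 so stray optimizer excursions cannot
    overflow; the criterion is flat far outside the bounds anyway."""
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = np.exp(min(max(theta[0], -40.0), 40.0))
    else:
        L[0, 0] = np.exp(min(max(theta[0], -40.0), 40.0))
        L[1, 0] = min(max(theta[1], -1e6), 1e6)
        L[1, 1] = np.exp(min(max(theta[2], -40.0), 40.0))
    return L @ L.T


def _theta_from_psi(psi: np.ndarray, q: int) -> np.ndarray:
    L = np.linalg.cholesky(psi + 1e-12 * np.eye(q))
    if q == 1:
        return np.array([np.log(L[0, 0])])
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


class _REMLEngine:
    """Sufficient statistics and likelihood evaluations for one design.

    All heavy per-record work is done once in the constructor; each
    criterion evaluation after that is O(n_subjects) batched linear algebra
    on q x q blocks.
    """

    def __init__(self, design: DesignMatrices):
        self.design = design
        y, X, Z, codes = design.y, design.X, design.Z, design.subject_codes
        self.n, self.p, self.q = design.n_obs, design.p, design.q
        self.N = design.n_subjects
        # per-subject aggregates (records are subject-contiguous)
        starts = np.searchsorted(codes, np.arange(self.N))
        bounds = np.append(starts, self.n)
        ZX = Z[:, :, None] * X[:, None, :]
        ZZ = Z[:, :, None] * Z[:, None, :]
        Zy = Z * y[:, None]
        self.S = np.add.reduceat(ZZ, bounds[:-1], axis=0)
        self.U = np.add.reduceat(ZX, bounds[:-1], axis=0)
        self.v = np.add.reduceat(Zy, bounds[:-1], axis=0)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self._Iq = np.eye(self.q)
        self._Uf = np.ascontiguousarray(self.U.reshape(-1, self.p))
        self._s00 = np.ascontiguousarray(self.S[:, 0, 0])
        if self.q == 2:
            self._s01 = np.ascontiguousarray(self.S[:, 0, 1])
            self._s11 = np.ascontiguousarray(self.S[:, 1, 1])
            self._U0 = np.ascontiguousarray(self.U[:, 0, :])
            self._U1 = np.ascontiguousarray(self.U[:, 1, :])

    def _gls_parts(self, psi: np.ndarray, moments_only: bool = False):
        # B_n = Psi (I + S_n Psi)^{-1} (symmetric); explicit scalar algebra
        # on the q<=2 blocks avoids batched-matmul dispatch overhead
        if self.q == 1:
            a = 1.0 + self._s00 * psi[0, 0]
            if not (a.min() > 0):  # also catches NaN
                return None
            logdetA = float(np.sum(np.log(a)))
            b00 = psi[0, 0] / a
            BU = self.U * b00[:, None, None]
            Bv = self.v * b00[:, None]
        else:
            p00, p01, p11 = psi[0, 0], psi[0, 1], psi[1, 1]
            s00, s01, s11 = self._s00, self._s01, self._s11
            # A = I + S Psi
            a00 = 1.0 + s00 * p00 + s01 * p01
            a01 = s00 * p01 + s01 * p11
            a10 = s01 * p00 + s11 * p01
            a11 = 1.0 + s01 * p01 + s11 * p11
            det = a00 * a11 - a01 * a10
            if not (det.min() > 0):  # also catches NaN
                return None
            logdetA = float(np.sum(np.log(det)))
            # B = Psi A^{-1} (symmetric)
            i00, i01, i10, i11 = a11 / det, -a01 / det, -a10 / det, a00 / det
            b00 = p00 * i00 + p01 * i10
            b01 = p00 * i01 + p01 * i11
            b11 = p01 * i01 + p11 * i11
            U0, U1 = self._U0, self._U1  # (N, p) each
            BU = np.empty_like(self.U)
            BU[:, 0, :] = b00[:, None] * U0 + b01[:, None] * U1
            BU[:, 1, :] = b01[:, None] * U0 + b11[:, None] * U1
            v0, v1 = self.v[:, 0], self.v[:, 1]
            Bv = np.empty_like(self.v)
            Bv[:, 0] = b00 * v0 + b01 * v1
            Bv[:, 1] = b01 * v0 + b11 * v1
        Uf = self._Uf
        XtVX = self.XtX - Uf.T @ BU.reshape(-1, self.p)
        XtVy = self.Xty - Bv.reshape(-1) @ Uf
        yVy = self.yty - float(np.sum(self.v * Bv))
        XtVX = 0.5 * (XtVX + XtVX.T)
        if moments_only:
            return XtVX, XtVy
        try:
            c, low = linalg.cho_factor(XtVX)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve((c, low), XtVy)
        quad = yVy - float(XtVy @ beta)
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(c))))
        return float(np.sum(logdetA)), logdet_XtVX, beta, quad, (c, low)

    def gls_moments(self, psi: np.ndarray):
        """(X'V^-1 X, X'V^-1 y) for the scaled marginal covariance
        V = I + Z Psi Z'; used by the collapsed Gibbs block for beta."""
        parts = self._gls_parts(psi, moments_only=True)
        if parts is None:
            raise FitError("marginal covariance not positive definite")
        return parts

    # -- criteria --------------------------------------------------------
    def profiled_crit(self, theta: np.ndarray, reml: bool) -> float:
        """-2 log-likelihood profiled over beta and sigma2."""
        psi = _psi_from_theta(np.asarray(theta, dtype=float), self.q)
        parts = self._gls_parts(psi)
        if parts is None:
            return 1e12
        logdetA, logdet_XtVX, _, quad, _ = parts
        dof = self.n - self.p if reml else self.n
        if quad <= 0 or not np.isfinite(quad):
            return 1e12
        crit = logdetA + dof * (np.log(quad / dof) + 1.0 + _LOG2PI)
        if reml:
            crit += logdet_XtVX
        return float(crit) if np.isfinite(crit) else 1e12

    def full_crit(self, phi: np.ndarray, reml: bool) -> float:
        """-2 log-likelihood at phi = (theta, log sigma2), beta profiled."""
        theta, log_s2 = phi[:-1], phi[-1]
        psi = _psi_from_theta(np.asarray(theta, dtype=float), self.q)
        parts = self._gls_parts(psi)
        if parts is None:
            return 1e12
        logdetA, logdet_XtVX, _, quad, _ = parts
        s2 = np.exp(log_s2)
        if reml:
            crit = (
                logdetA
                + logdet_XtVX
                + (self.n - self.p) * (log_s2 + _LOG2PI)
                + quad / s2
            )
        else:
            crit = logdetA + self.n * (log_s2 + _LOG2PI) + quad / s2
        return float(crit) if np.isfinite(crit) else 1e12

    def beta_cov_at(self, phi: np.ndarray) -> np.ndarray:
        """Asymptotic covariance of beta at phi = (theta, log sigma2)."""
        psi = _psi_from_theta(np.asarray(phi[:-1], dtype=float), self.q)
        parts = self._gls_parts(psi)
        if parts is None:
            raise FitError("beta covariance undefined at given parameters")
        _, _, _, _, chol = parts
        return np.exp(phi[-1]) * linalg.cho_solve(chol, np.eye(self.p))

    def solution_at(self, theta: np.ndarray, reml: bool):
        psi = _psi_from_theta(np.asarray(theta, dtype=float), self.q)
        parts = self._gls_parts(psi)
        if parts is None:
            raise FitError("likelihood undefined at given parameters")
        logdetA, logdet_XtVX, beta, quad, chol = parts
        dof = self.n - self.p if reml else self.n
        sigma2 = quad / dof
        beta_cov = sigma2 * linalg.cho_solve(chol, np.eye(self.p))
        return psi, beta, sigma2, beta_cov

    # -- initialisation --------------------------------------------------
    def initial_theta(self) -> np.ndarray:
        """Moment-style start: split OLS residual variance into between-
        and within-subject parts."""
        XtX = self.XtX + 1e-10 * np.eye(self.p)
        beta = np.linalg.solve(XtX, self.Xty)
        y, X, codes = self.design.y, self.design.X, self.design.subject_codes
        r = y - X @ beta
        total = float(np.var(r)) or 1.0
        means = np.bincount(codes, weights=r, minlength=self.N) / np.bincount(
            codes, minlength=self.N
        )
        between = float(np.var(means))
        within = max(total - between, 0.05 * total)
        l0 = np.sqrt(max(between / within, 1e-2))
        if self.q == 1:
            return np.array([np.log(l0)])
        return np.array([np.log(l0), 0.0, np.log(max(0.1 * l0, 1e-2))])


@dataclass
class FlmeFit:
    """REML/ML estimates of the mixed model.

    ``theta`` is the unconstrained parameterization (log-Cholesky of
    G/sigma2 followed by log sigma2); ``theta_cov`` (lazy, via
    :meth:`theta_covariance`) is the inverse observed information of the
    chosen criterion at the optimum, used by the Satterthwaite machinery.
    """

    beta: np.ndarray
    beta_labels: list[str]
    G: np.ndarray
    sigma2: float
    theta: np.ndarray
    loglik_reml: float
    loglik_ml: float
    aic: float
    aic_ml: float
    beta_cov: np.ndarray
    method: str
    converged: bool
    singular: bool
    n_obs: int
    n_subjects: int
    q: int
    _engine: _REMLEngine = field(repr=False)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def n_variance_params(self) -> int:
        return len(self.theta)  # includes log sigma2

    @property
    def phi(self) -> np.ndarray:
        return self.theta

    def coef(self, label: str) -> float:
        return float(self.beta[self.beta_labels.index(label)])

    def se(self, label: str) -> float:
        i = self.beta_labels.index(label)
        return float(np.sqrt(self.beta_cov[i, i]))

    def theta_covariance(self) -> np.ndarray:
        """Inverse observed information of the REML/ML criterion at the
        optimum (central finite differences), cached."""
        if self._theta_cov is None:
            reml = self.method == "reml"
            H = _numeric_hessian(
                lambda ph: 0.5 * self._engine.full_crit(ph, reml), self.theta
            )
            self._theta_cov = _robust_inverse(H)
        return self._theta_cov

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.beta_cov))
        return pd.DataFrame(
            {"estimate": self.beta, "se": se}, index=self.beta_labels
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficients": dict(zip(self.beta_labels, map(float, self.beta))),
            "se": dict(
                zip(self.beta_labels, map(float, np.sqrt(np.diag(self.beta_cov))))
            ),
            "G": self.G.tolist(),
            "sigma2": self.sigma2,
            "loglik_reml": self.loglik_reml,
            "loglik_ml": self.loglik_ml,
            "aic": self.aic,
            "aic_ml": self.aic_ml,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "q": self.q,
        }


def _numeric_hessian(f, x0: np.ndarray, h: float = 5e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x0."""
    k = len(x0)
    H = np.empty((k, k))
    f0 = f(x0)
    steps = h * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        H[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / steps[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def _robust_inverse(H: np.ndarray) -> np.ndarray:
    """Inverse of an information matrix, falling back to an eigenvalue-
    clipped pseudo-inverse near the variance boundary."""
    try:
        cov = np.linalg.inv(H)
        if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
            return cov
    except np.linalg.LinAlgError:
        pass
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.maximum(w, 1e-8 * max(np.max(np.abs(w)), 1.0))
    return (V / w) @ V.T


def fit_lme(
    design: DesignMatrices,
    method: str = "reml",
    theta0: np.ndarray | None = None,
) -> FlmeFit:
    """Fit the mixed model by REML (default) or ML.

    Optimizes the profiled criterion over the log-Cholesky parameters with
    a derivative-free simplex search followed by a quasi-Newton polish;
    ``theta0`` (log-Cholesky of Psi, without the log sigma2 entry) warm-starts
    the search.  Singular (boundary) fits are returned with ``singular=True``
    rather than raised.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    if design.n_obs <= design.p:
        raise FitError(
            f"n_obs={design.n_obs} must exceed the {design.p} fixed-effect columns"
        )
    engine = _REMLEngine(design)
    reml = method == "reml"
    fun = lambda th: engine.profiled_crit(th, reml)  # noqa: E731
    q = design.q
    n_theta = 1 if q == 1 else 3
    bounds = [(-10.0, 10.0), (-30.0, 30.0), (-10.0, 10.0)][:n_theta]
    if q == 1:
        bounds = [(-10.0, 10.0)]

    starts = []
    if theta0 is not None:
        starts.append(np.asarray(theta0, dtype=float))
    starts.append(engine.initial_theta())

    best = None
    warm_ok = False
    for k, th0 in enumerate(starts):
        if k == 0 and theta0 is not None:
            # warm start: safeguarded Newton from the supplied optimum,
            # falling back to a tight simplex search if it misbehaves
            res = _newton_refine(fun, th0)
            if res is None:
                res = optimize.minimize(fun, th0, method="Nelder-Mead",
                                        options={"xatol": 3e-5, "fatol": 1e-8,
                                                 "maxiter": 150 * n_theta,
                                                 "initial_simplex": _small_simplex(th0, 0.01)})
            if res.fun < 1e11:
                best = res
                warm_ok = True
                break
        else:
            res = optimize.minimize(
                fun, th0, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400 * n_theta},
            )
            if best is None or res.fun < best.fun:
                best = res
    if not warm_ok:
        # derivative-free polish for cold starts
        polish = optimize.minimize(fun, best.x, method="Powell",
                                   options={"xtol": 1e-9, "ftol": 1e-11,
                                            "maxiter": 2000})
        if polish.fun <= best.fun:
            best = polish
    if best.fun >= 1e11:
        raise FitError("REML criterion undefined everywhere searched; no fit")

    theta_opt = np.asarray(best.x, dtype=float)
    psi, beta, sigma2, beta_cov = engine.solution_at(theta_opt, reml)
    G = sigma2 * psi
    ll_reml = -0.5 * engine.profiled_crit(theta_opt, True)
    ll_ml = -0.5 * engine.profiled_crit(theta_opt, False)
    n_var = n_theta + 1  # variance parameters incl. sigma2
    aic_reml = -2.0 * ll_reml + 2.0 * (design.p + n_var)
    aic_ml = -2.0 * ll_ml + 2.0 * (design.p + n_var)
    eigvals = np.linalg.eigvalsh(psi)
    singular = bool(eigvals.min() < 1e-6 * max(eigvals.max(), 1.0))
    phi = np.append(theta_opt, np.log(sigma2))
    return FlmeFit(
        beta=beta,
        beta_labels=list(design.x_labels),
        G=G,
        sigma2=float(sigma2),
        theta=phi,
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        aic=float(aic_reml if reml else aic_ml),
        aic_ml=float(aic_ml),
        beta_cov=beta_cov,
        method=method,
        converged=bool(np.isfinite(best.fun)),
        singular=singular,
        n_obs=design.n_obs,
        n_subjects=design.n_subjects,
        q=q,
        _engine=engine,
    )


def _central_grad(f, x0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.empty(len(x0))
    for i in range(len(x0)):
        e = np.zeros(len(x0))
        e[i] = h * max(1.0, abs(x0[i]))
        g[i] = (f(x0 + e) - f(x0 - e)) / (2.0 * e[i])
    return g


def _newton_refine(fun, th0: np.ndarray, max_iter: int = 8):
    """Safeguarded Newton polish from a warm start.

    Uses a finite-difference Hessian computed once and central-difference
    gradients per iteration; returns None (caller falls back to the simplex
    search) on non-descent, indefinite curvature, or slow progress.
    """
    th = np.asarray(th0, dtype=float).copy()
    f0 = fun(th)
    if not np.isfinite(f0) or f0 >= 1e11:
        return None
    H = _numeric_hessian(fun, th, h=1e-4)
    try:
        c = np.linalg.cholesky(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        return None
    moved = np.inf
    for it in range(max_iter):
        g = _central_grad(fun, th)
        step = -np.linalg.solve(c.T, np.linalg.solve(c, g))
        if not np.all(np.isfinite(step)):
            return None
        # trust region: a near-flat direction can propose a huge jump
        norm = float(np.max(np.abs(step)))
        if norm > 1.0:
            step = step / norm
        # backtracking line search; 1e-9 is the criterion's noise floor
        t = 1.0
        accepted = False
        for _ in range(6):
            f1 = fun(th + t * step)
            if f1 <= f0 + 1e-9:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            # cannot descend further: at the noise floor if we moved already
            if it > 0:
                return optimize.OptimizeResult(x=th, fun=f0, success=True)
            return None
        moved = t * float(np.max(np.abs(step)))
        improved = f0 - f1
        th = th + t * step
        f0 = f1
        if abs(improved) < 1e-8 and moved < 3e-5:
            return optimize.OptimizeResult(x=th, fun=f0, success=True)
    return (
        optimize.OptimizeResult(x=th, fun=f0, success=True)
        if moved < 1e-4
        else None
    )


def _small_simplex(x0: np.ndarray, scale: float = 0.02) -> np.ndarray:
    k = len(x0)
    simplex = np.tile(x0, (k + 1, 1))
    for i in range(k):
        simplex[i + 1, i] += scale * max(1.0, abs(x0[i]))
    return simplex


def compare_models(fit_small: FlmeFit, fit_big: FlmeFit) -> dict:
    """Likelihood-ratio test and AIC comparison of nested random structures.

    The small fit must be the random-intercept model, the big one the
    random-intercept-and-slope model, on identical data with the same
    estimation method.  The chi-square reference uses df = 2 (slope variance
    plus covariance) without boundary correction, which is conservative.
    """
    if fit_small.q > fit_big.q:
        raise ComparisonError("fits are not nested (need q_small <= q_big)")
    if fit_small.n_obs != fit_big.n_obs or fit_small.p != fit_big.p:
        raise ComparisonError("fits are on different data or fixed-effect designs")
    if fit_small.method != fit_big.method:
        raise ComparisonError("fits use different estimation methods")
    if fit_small.method == "reml":
        ll_small, ll_big = fit_small.loglik_reml, fit_big.loglik_reml
    else:
        ll_small, ll_big = fit_small.loglik_ml, fit_big.loglik_ml
    df = fit_big.n_variance_params - fit_small.n_variance_params
    lrt = max(0.0, 2.0 * (ll_big - ll_small))
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 and df > 0 else 1.0
    return {
        "lrt_stat": float(lrt),
        "df": int(df),
        "p_value": p,
        "aic_small": fit_small.aic,
        "aic_big": fit_big.aic,
        "preferred": "big" if fit_big.aic < fit_small.aic else "small",
        "note": "chi2 reference without boundary correction (conservative)",
    }
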