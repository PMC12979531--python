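"""Count GLMMs (Poisson / NB2, log link) with Gaussian random intercepts.

The marginal likelihood over the random intercepts is formed with the
Laplace approximation.  For a model with linear predictor

    eta = X beta + Z_1 u_1 + ... + Z_K u_K,     u_k ~ N(0, sigma_k^2 I),

the mode ``u*`` of the joint (penalized) log-likelihood is found by Newton
iteration and the approximate marginal log-likelihood is

    l_Lap = sum_i l_i(eta(u*)) - 1/2 sum_k |u_k*|^2 / sigma_k^2
            - 1/2 log det D - 1/2 log det H(u*),

with D the random-effect covariance and H = Z' W Z + D^{-1} the negative
joint Hessian in u.  Because every Z_k is an indicator matrix, Z_k' W Z_k
is diagonal; with two (possibly crossed) grouping factors the Newton system
and log-determinant are handled through a Schur complement on the smaller
factor, so fits stay fast without sparse machinery.

``(beta, log theta, log sigma)`` are maximized by L-BFGS-B with
finite-difference gradients, warm-starting the inner mode between
evaluations.  When no free random intercepts remain the fit reduces to an
exact IRLS GLM (profiled over log theta for the negative binomial), so the
Laplace log-likelihood coincides with the exact GLM log-likelihood at
sigma = 0.

NB2 convention: variance mu + mu^2 / theta; smaller theta means more
overdispersion.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve

ETA_CLIP = 30.0
SINGULAR_SD = 1e-4


class EstimabilityError(ValueError):
    """Design matrix is rank deficient; message lists aliased columns."""


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass
class ModelSpec:
    """Declarative model description.

    ``fixed`` holds term strings: a column name (categorical columns are
    expanded to treatment-coded dummies against a reference level, numeric
    columns enter as-is) or interactions ``"a:b"``.  ``random`` holds
    grouping columns for random intercepts, possibly composite
    (``"subject_id:neuron_id"`` groups by the combination).  At most two
    random factors are supported.
    """

    response: str
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=list)
    family: str = "negbin"          # "poisson" | "negbin"
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.random) > 2:
            raise ValueError("at most two random-intercept factors supported")

    @classmethod
    def from_formula(cls, formula: str, family: str = "negbin",
                     reference: dict | None = None) -> "ModelSpec":
        """Parse ``"y ~ a*b + a:c + (1|g) + (1|s:n)"`` style formulas.

        Supported right-hand terms: factor/numeric columns, ``:``
        interactions, ``*`` crossing (expands to main effects plus
        interaction) and ``(1|group)`` random intercepts.
        """
        lhs, rhs = formula.split("~")
        fixed: list[str] = []
        random: list[str] = []
        for raw in rhs.split("+"):
            term = raw.strip()
            if not term or term == "1":
                continue
            if term.startswith("(") and term.endswith(")"):
                inner = term[1:-1].strip()
                if not inner.startswith("1|"):
                    raise ValueError(f"unsupported random term {term!r}")
                random.append(inner[2:].strip())
            elif "*" in term:
                parts = [p.strip() for p in term.split("*")]
                for p in parts:
                    if p not in fixed:
                        fixed.append(p)
                fixed.append(":".join(parts))
            else:
                fixed.append(term)
        return cls(response=lhs.strip(), fixed=fixed, random=random,
                   family=family, reference=dict(reference or {}))


class DesignInfo:
    """Treatment-coded fixed-effect design builder.

    Factor levels and reference levels are frozen at fit time so that
    prediction grids (marginal means) are coded identically.
    """

    def __init__(self, terms: list, data: pd.DataFrame, reference: dict):
        self.terms = list(terms)
        self.factors: dict[str, list] = {}
        self.numeric_means: dict[str, float] = {}
        self.reference = dict(reference)
        cols = {c for t in self.terms for c in t.split(":")}
        for col in cols:
            if col not in data.columns:
                raise KeyError(f"model column {col!r} not in data")
            series = data[col]
            if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
                levels = sorted(map(str, series.astype(str).unique()))
                ref = str(self.reference.get(col, levels[0]))
                if ref not in levels:
                    raise ValueError(f"reference level {ref!r} absent from {col!r}")
                self.reference[col] = ref
                self.factors[col] = levels
            else:
                self.numeric_means[col] = float(series.mean())
        self.column_names = ["(Intercept)"]
        self._specs: list[list] = [[]]
        for term in self.terms:
            parts = term.split(":")
            per_part = []
            for col in parts:
                if col in self.factors:
                    ref = self.reference[col]
                    per_part.append([(col, lv) for lv in self.factors[col] if lv != ref])
                else:
                    per_part.append([(col, None)])
            for combo in itertools.product(*per_part):
                name = ":".join(f"{c}[{lv}]" if lv is not None else c for c, lv in combo)
                if name in self.column_names:
                    continue
                self.column_names.append(name)
                self._specs.append(list(combo))

    def build(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        X = np.ones((n, len(self.column_names)))
        cache: dict = {}
        for j, spec in enumerate(self._specs):
            for col, lv in spec:
                if lv is None:
                    v = data[col].to_numpy(dtype=float)
                else:
                    key = (col, lv)
                    if key not in cache:
                        vals = data[col].astype(str)
                        unseen = set(vals.unique()) - set(self.factors[col])
                        if unseen:
                            raise ValueError(f"unseen level(s) {unseen} in {col!r}")
                        cache[key] = (vals == lv).to_numpy(dtype=float)
                    v = cache[key]
                X[:, j] *= v
        return X

    def check_rank(self, X: np.ndarray) -> None:
        from scipy.linalg import qr
        _q, r, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
        rank = int((d > tol).sum())
        if rank < X.shape[1]:
            aliased = [self.column_names[i] for i in piv[rank:]]
            raise EstimabilityError(f"aliased terms: {aliased}")


# ---------------------------------------------------------------------------
# families (log link throughout)


def _mu(eta: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))


def _loglik(y, eta, family, theta):
    mu = _mu(eta)
    if family == "poisson":
        return float(np.sum(y * np.clip(eta, -ETA_CLIP, ETA_CLIP) - mu
                            - special.gammaln(y + 1.0)))
    t = theta
    return float(np.sum(special.gammaln(y + t) - special.gammaln(t)
                        - special.gammaln(y + 1.0) + t * math.log(t)
                        + y * np.clip(eta, -ETA_CLIP, ETA_CLIP)
                        - (y + t) * np.log(t + mu)))


def _score_weight(y, eta, family, theta):
    """(dl/deta, -d2l/deta2) elementwise; the weight is >= 0 for both
    families, so the inner problem is concave."""
    mu = _mu(eta)
    if family == "poisson":
        return y - mu, mu
    t = theta
    denom = t + mu
    return y - (y + t) * mu / denom, (y + t) * t * mu / denom ** 2


def _sample(rng, mu, family, theta):
    if family == "poisson":
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# inner Laplace machinery


class _Inner:
    """Mode finder for the random intercepts with warm starts.

    Factors are ordered with the larger one first; its block of the joint
    Hessian is diagonal and the second factor is absorbed through a Schur
    complement, so each Newton step costs O(n + q1 * q2^2).
    """

    def __init__(self, y, family, idx_list, q_list):
        self.y = y
        self.family = family
        self.idx = idx_list
        self.q = q_list
        self.u = [np.zeros(q) for q in q_list]

    def _eta(self, eta_fix, u):
        eta = eta_fix.copy()
        for k, idx in enumerate(self.idx):
            eta += u[k][idx]
        return eta

    def _pen(self, eta, u, theta, inv_var):
        pen = _loglik(self.y, eta, self.family, theta)
        for k in range(len(u)):
            pen -= 0.5 * inv_var[k] * float(u[k] @ u[k])
        return pen

    def solve(self, eta_fix, theta, inv_var, tol=1e-8, maxit=100):
        """Return (eta_at_mode, penalized_loglik, logdet_H, w)."""
        u = [uk.copy() for uk in self.u]
        eta = self._eta(eta_fix, u)
        pen = self._pen(eta, u, theta, inv_var)
        two = len(self.idx) == 2
        for _it in range(maxit):
            s, w = _score_weight(self.y, eta, self.family, theta)
            grads = [np.bincount(self.idx[k], weights=s, minlength=self.q[k])
                     - u[k] * inv_var[k] for k in range(len(u))]
            gmax = max(np.abs(g).max() for g in grads)
            if gmax < tol:
                break
            A = np.bincount(self.idx[0], weights=w, minlength=self.q[0]) + inv_var[0]
            if two:
                C = np.bincount(self.idx[1], weights=w, minlength=self.q[1]) + inv_var[1]
                B = np.zeros((self.q[0], self.q[1]))
                np.add.at(B, (self.idx[0], self.idx[1]), w)
                S = np.diag(C) - B.T @ (B / A[:, None])
                rhs = grads[1] - B.T @ (grads[0] / A)
                try:
                    d1 = cho_solve(cho_factor(S), rhs)
                except np.linalg.LinAlgError:
                    d1 = np.linalg.solve(S, rhs)
                d0 = (grads[0] - B @ d1) / A
                step = [d0, d1]
            else:
                step = [grads[0] / A]
            t_step = 1.0
            for _half in range(30):
                u_new = [u[k] + t_step * step[k] for k in range(len(u))]
                eta_new = self._eta(eta_fix, u_new)
                pen_new = self._pen(eta_new, u_new, theta, inv_var)
                if pen_new >= pen - 1e-12:
                    break
                t_step *= 0.5
            if pen_new < pen - 1e-10:
                break   # no ascent possible; accept current mode
            u, eta, pen = u_new, eta_new, pen_new
        s, w = _score_weight(self.y, eta, self.family, theta)
        A = np.bincount(self.idx[0], weights=w, minlength=self.q[0]) + inv_var[0]
        if two:
            C = np.bincount(self.idx[1], weights=w, minlength=self.q[1]) + inv_var[1]
            B = np.zeros((self.q[0], self.q[1]))
            np.add.at(B, (self.idx[0], self.idx[1]), w)
            S = np.diag(C) - B.T @ (B / A[:, None])
            sign, logdet_S = np.linalg.slogdet(S)
            logdet = float(np.sum(np.log(A)) + logdet_S)
            self._schur = (A, B, S)
        else:
            logdet = float(np.sum(np.log(A)))
            self._schur = (A, None, None)
        self.u = u
        return eta, pen, logdet, w

    def solve_H(self, R_list):
        """H^{-1} applied to stacked per-factor right-hand sides."""
        A, B, S = self._schur
        if B is None:
            return [R_list[0] / A[:, None]]
        R0, R1 = R_list
        rhs = R1 - B.T @ (R0 / A[:, None])
        Y1 = np.linalg.solve(S, rhs)
        Y0 = (R0 - B @ Y1) / A[:, None]
        return [Y0, Y1]


# ---------------------------------------------------------------------------
# fitted-model container


@dataclass
class GlmmFit:
    """A fitted count GLMM (coefficients on the log-rate scale)."""

    beta: pd.Series
    se: pd.Series
    cov_beta: pd.DataFrame
    sigma: dict
    theta: float | None
    loglik: float
    aic: float
    n_params: int
    converged: bool
    singular: bool
    n_obs: int
    family: str
    design: DesignInfo
    spec: ModelSpec
    X: np.ndarray
    y: np.ndarray
    random_codes: list      # [(name, codes, q), ...]
    u_hat: list

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "sigma": {k: float(v) for k, v in self.sigma.items()},
            "theta": None if self.theta is None else float(self.theta),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "singular": bool(self.singular),
            "n_obs": int(self.n_obs),
        }


@dataclass
class FitOptions:
    fix_theta: float | None = None
    fix_sigma: dict = field(default_factory=dict)
    maxiter: int = 300
    theta_bounds: tuple = (math.exp(-6.0), math.exp(20.0))
    sigma_bounds: tuple = (1e-6, math.exp(5.0))


# ---------------------------------------------------------------------------
# exact GLM path (no free random effects)


def _irls(y, X, family, theta, beta0=None, tol=1e-10, maxit=100):
    p = X.shape[1]
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = math.log(y.mean() + 1e-3)
    else:
        beta = beta0.copy()
    ll = _loglik(y, X @ beta, family, theta)
    converged = False
    for _it in range(maxit):
        eta = X @ beta
        s, w = _score_weight(y, eta, family, theta)
        XtWX = (X * w[:, None]).T @ X
        g = X.T @ s
        try:
            step = np.linalg.solve(XtWX + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, g, rcond=None)[0]
        t_step = 1.0
        for _half in range(30):
            beta_new = beta + t_step * step
            ll_new = _loglik(y, X @ beta_new, family, theta)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t_step *= 0.5
        delta = np.abs(beta_new - beta).max()
        beta, ll = beta_new, ll_new
        if delta < tol * (1.0 + np.abs(beta).max()):
            converged = True
            break
    return beta, ll, converged


def _fit_fixed_only(y, X, family, options):
    if family == "poisson" or options.fix_theta is not None:
        theta = options.fix_theta if family == "negbin" else None
        beta, ll, conv = _irls(y, X, family, theta)
        est_theta = False
    else:
        lo, hi = np.log(options.theta_bounds)

        def neg_profile(log_t):
            b, llp, _c = _irls(y, X, family, math.exp(log_t))
            return -llp

        res = optimize.minimize_scalar(neg_profile, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        theta = math.exp(res.x)
        beta, ll, conv = _irls(y, X, family, theta)
        est_theta = True
    _s, w = _score_weight(y, X @ beta, family, theta)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, theta, ll, conv, cov, est_theta


# ---------------------------------------------------------------------------
# public fitting API


def fit_glmm(table: pd.DataFrame, spec: ModelSpec,
             options: FitOptions | None = None) -> GlmmFit:
    """Maximize the Laplace-approximate marginal likelihood.

    Returns ``converged=False`` rather than raising on non-convergence;
    ``singular=True`` when any estimated random-effect SD falls below
    1e-4 (downstream analyses exclude such units).
    """
    options = options or FitOptions()
    if len(table) == 0:
        raise ValueError("empty data")
    y = table[spec.response].to_numpy()
    if y.min() < 0 or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integers")
    y = y.astype(float)

    design = DesignInfo(spec.fixed, table, spec.reference)
    X = design.build(table)
    design.check_rank(X)
    p = X.shape[1]

    # random structure: factorize grouping keys, drop factors pinned at 0
    sigma_out: dict = {}
    rand: list[tuple[str, np.ndarray, int]] = []
    for g in spec.random:
        if g in options.fix_sigma and options.fix_sigma[g] == 0.0:
            sigma_out[g] = 0.0
            continue
        key = table[g.split(":")[0]].astype(str)
        for part in g.split(":")[1:]:
            key = key + ":" + table[part].astype(str)
        codes, levels = pd.factorize(key, sort=True)
        if len(levels) < 2:
            raise ValueError(f"grouping factor {g!r} needs >= 2 levels")
        rand.append((g, codes.astype(np.int64), len(levels)))
    rand.sort(key=lambda t: -t[2])   # bigger factor first (diagonal block)

    family = spec.family
    est_theta = family == "negbin" and options.fix_theta is None

    if not rand:
        beta, theta, ll, conv, cov, est_theta = _fit_fixed_only(y, X, family, options)
        n_params = p + (1 if est_theta else 0)
        se = np.sqrt(np.diag(cov))
        names = design.column_names
        return GlmmFit(
            beta=pd.Series(beta, index=names), se=pd.Series(se, index=names),
            cov_beta=pd.DataFrame(cov, index=names, columns=names),
            sigma=sigma_out, theta=theta, loglik=ll,
            aic=2 * n_params - 2 * ll, n_params=n_params,
            converged=conv, singular=False, n_obs=len(y), family=family,
            design=design, spec=spec, X=X, y=y, random_codes=[], u_hat=[])

    inner = _Inner(y, family, [r[1] for r in rand], [r[2] for r in rand])
    n_rand = len(rand)

    # starting values
    beta0, _ll0, _c0 = _irls(y, X, "poisson", None, tol=1e-6, maxit=30)
    if est_theta:
        mu0 = _mu(X @ beta0)
        excess = np.mean((y - mu0) ** 2 - mu0) / max(np.mean(mu0 ** 2), 1e-12)
        theta0 = float(np.clip(1.0 / max(excess, 1e-3), 0.05, 1e4))
    x0 = np.concatenate([
        beta0,
        [math.log(theta0)] if est_theta else [],
        np.full(n_rand, math.log(0.3)),
    ])
    lo_t, hi_t = np.log(options.theta_bounds)
    lo_s, hi_s = np.log(options.sigma_bounds)
    bounds = [(None, None)] * p
    if est_theta:
        bounds.append((lo_t, hi_t))
    bounds += [(lo_s, hi_s)] * n_rand

    def unpack(params):
        beta = params[:p]
        k = p
        if est_theta:
            theta = math.exp(params[k]); k += 1
        else:
            theta = options.fix_theta
        sig = np.exp(params[k:k + n_rand])
        return beta, theta, sig

    def neg_laplace(params):
        beta, theta, sig = unpack(params)
        inv_var = (1.0 / sig ** 2)
        eta, pen, logdet, _w = inner.solve(X @ beta, theta, inv_var)
        l_lap = pen - float(np.sum([rand[k][2] * math.log(sig[k] ** 2)
                                    for k in range(n_rand)])) / 2.0 - 0.5 * logdet
        return -l_lap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            neg_laplace, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-11,
                     "gtol": 1e-6, "eps": 1e-5,
                     "maxfun": 100 * options.maxiter})

    beta, theta, sig = unpack(res.x)
    inv_var = 1.0 / sig ** 2
    eta, pen, logdet, w = inner.solve(X @ beta, theta, inv_var, tol=1e-10)
    ll = pen - float(np.sum([rand[k][2] * math.log(sig[k] ** 2)
                             for k in range(n_rand)])) / 2.0 - 0.5 * logdet

    # covariance of beta conditional on the variance parameters:
    # beta-block of the inverse joint Hessian at the mode
    XtWX = (X * w[:, None]).T @ X
    R = []
    for k in range(n_rand):
        Mk = np.zeros((rand[k][2], p))
        np.add.at(Mk, rand[k][1], X * w[:, None])
        R.append(Mk)
    Y = inner.solve_H(R)
    corr = sum(R[k].T @ Y[k] for k in range(n_rand))
    info = XtWX - corr
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = (cov + cov.T) / 2.0

    for k in range(n_rand):
        sigma_out[rand[k][0]] = float(sig[k])
    n_params = p + (1 if est_theta else 0) + n_rand
    names = design.column_names
    return GlmmFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names),
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
        sigma=sigma_out, theta=theta if family == "negbin" else None,
        loglik=float(ll), aic=2 * n_params - 2 * float(ll),
        n_params=n_params, converged=bool(res.success),
        singular=bool(any(s < SINGULAR_SD for s in sig)),
        n_obs=len(y), family=family, design=design, spec=spec,
        X=X, y=y, random_codes=rand, u_hat=[u.copy() for u in inner.u])


def wald_table(fit: GlmmFit) -> pd.DataFrame:
    """Two-sided Wald Z test per fixed-effect coefficient."""
    z = fit.beta / fit.se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"estimate": fit.beta, "se": fit.se, "z": z, "p": p})


def compare_models(fit_a: GlmmFit, fit_b: GlmmFit):
    """Likelihood-ratio comparison of two nested fits on the same data.

    Returns ``(delta_aic, chi2, df, p)`` with ``delta_aic =
    AIC(nested) - AIC(full)`` (positive favors the richer model) and the
    p-value from the chi-squared reference distribution.
    """
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("models were fitted to different data sizes")
    full, nested = (fit_a, fit_b) if fit_a.n_params >= fit_b.n_params else (fit_b, fit_a)
    df = full.n_params - nested.n_params
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return nested.aic - full.aic, chi2, df, p


def zero_inflation_check(fit: GlmmFit, n_sims: int = 1000, seed: int = 0):
    """Simulation-based zero-inflation diagnostic.

    Simulates ``n_sims`` datasets from the fitted model (random intercepts
    redrawn from their estimated distribution) and compares the observed
    number of zeros with the simulated distribution.  Returns ``(ratio,
    p)``: observed zeros / mean simulated zeros and a two-sided p-value.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if n_sims < 100:
        warnings.warn("n_sims < 100 gives a coarse zero-inflation p-value")
    rng = np.random.default_rng(seed)
    eta_fix = fit.X @ fit.beta.to_numpy()
    obs = int(np.sum(fit.y == 0))
    sims = np.empty(n_sims)
    for b in range(n_sims):
        eta = eta_fix.copy()
        for name, codes, q in fit.random_codes:
            eta += rng.normal(0.0, fit.sigma[name], size=q)[codes]
        y_sim = _sample(rng, _mu(eta), fit.family, fit.theta)
        sims[b] = np.sum(y_sim == 0)
    ratio = obs / max(sims.mean(), 1e-12)
    p_lo = (1 + np.sum(sims <= obs)) / (n_sims + 1)
    p_hi = (1 + np.sum(sims >= obs)) / (n_sims + 1)
    return float(ratio), float(min(1.0, 2.0 * min(p_lo, p_hi)))
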