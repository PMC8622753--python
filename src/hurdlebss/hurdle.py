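"""Maximum-likelihood hurdle regression for zero-inflated count outcomes.

The hurdle model factorises the count law into

* a zero part: logistic regression on the indicator ``1{y > 0}`` with
  coefficients interpretable as log odds ratios (OR), and
* a count part: a zero-truncated Poisson or negative-binomial regression on
  the positive observations only, with coefficients interpretable as log
  incidence rate ratios (IRR).

Because the likelihood separates, the two parts are maximised independently;
the reported log-likelihood and AIC refer to the joint model.  The negative
binomial uses the mean--dispersion parameterisation (variance
``lambda + lambda^2 / theta``), so ``theta -> inf`` recovers the Poisson.

Standard errors come from the observed information (negative Hessian at the
optimum); Wald 95% intervals on the OR/IRR scale are ``exp(b +- 1.96 se)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "HurdleSpec",
    "HurdleFit",
    "PredictiveDistribution",
    "truncated_log_pmf",
    "fit_hurdle",
    "predict_distribution",
    "select_distribution",
    "FitError",
    "SeparationError",
]


class FitError(RuntimeError):
    """Model fitting failed (non-convergence, rank deficiency, ...)."""


class SeparationError(FitError):
    """Degenerate zero part: all outcomes zero or all positive."""


@dataclass(frozen=True)
class HurdleSpec:
    """Predictor lists per model part; intercepts are always included."""
    zero_part_predictors: tuple[str, ...]
    count_part_predictors: tuple[str, ...]
    count_distribution: str = "poisson"  # "poisson" | "negbin"

    def __post_init__(self):
        if self.count_distribution not in ("poisson", "negbin"):
            raise ValueError(f"unknown count distribution {self.count_distribution!r}")
        object.__setattr__(self, "zero_part_predictors", tuple(self.zero_part_predictors))
        object.__setattr__(self, "count_part_predictors", tuple(self.count_part_predictors))

    def to_json(self) -> str:
        return json.dumps({"zero_part_predictors": list(self.zero_part_predictors),
                           "count_part_predictors": list(self.count_part_predictors),
                           "count_distribution": self.count_distribution})

    @classmethod
    def from_json(cls, s: str) -> "HurdleSpec":
        d = json.loads(s)
        return cls(tuple(d["zero_part_predictors"]), tuple(d["count_part_predictors"]),
                   d["count_distribution"])


@dataclass
class HurdleFit:
    spec: HurdleSpec
    beta_zero: np.ndarray          # log odds, intercept first
    beta_count: np.ndarray         # log IRR, intercept first
    theta: float | None            # negbin dispersion, None for Poisson
    loglik: float
    aic: float
    vcov_zero: np.ndarray
    vcov_count: np.ndarray         # includes log-theta row/col for negbin
    converged: bool
    n_obs: int
    k_params: int
    loglik_zero: float = 0.0
    loglik_count: float = 0.0

    @property
    def zero_terms(self) -> list[str]:
        return ["intercept", *self.spec.zero_part_predictors]

    @property
    def count_terms(self) -> list[str]:
        return ["intercept", *self.spec.count_part_predictors]

    def se_zero(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_zero))

    def se_count(self) -> np.ndarray:
        k = len(self.beta_count)
        return np.sqrt(np.diag(self.vcov_count)[:k])

    def summary_table(self) -> pd.DataFrame:
        """OR/IRR table with Wald 95% CIs, mirroring the usual presentation."""
        rows = []
        for part, terms, beta, se in (("zero", self.zero_terms, self.beta_zero, self.se_zero()),
                                      ("count", self.count_terms, self.beta_count, self.se_count())):
            for t, b, s in zip(terms, beta, se):
                rows.append({"part": part, "term": t, "coef": b, "se": s,
                             "ratio": np.exp(b),
                             "ci_low": np.exp(b - 1.96 * s),
                             "ci_high": np.exp(b + 1.96 * s)})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "spec": json.loads(self.spec.to_json()),
            "beta_zero": dict(zip(self.zero_terms, self.beta_zero.tolist())),
            "beta_count": dict(zip(self.count_terms, self.beta_count.tolist())),
            "theta": self.theta, "loglik": self.loglik, "aic": self.aic,
            "converged": self.converged, "n_obs": self.n_obs, "k_params": self.k_params,
        })


@dataclass
class PredictiveDistribution:
    """Per-subject forecast of the hurdle law, truncated at ``k_max``."""
    p_positive: np.ndarray      # pi_i
    pmf: np.ndarray             # (n, k_max+1); pmf[:, 0] = 1 - pi
    mean: np.ndarray
    sd: np.ndarray
    k_max: int

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf, axis=1)


# ---------------------------------------------------------------------------
# truncated pmf
# ---------------------------------------------------------------------------

def _log1m_f0_poisson(lam):
    # log(1 - e^{-lam}); -expm1 form is exact at both extremes
    return np.log(-np.expm1(-lam))


def _log1m_f0_negbin(lam, theta):
    return np.log(-np.expm1(theta * (np.log(theta) - np.log(theta + lam))))


def truncated_log_pmf(k, lam, theta=None):
    """Log pmf of the zero-truncated Poisson / negative binomial at ``k >= 1``.

    ``log[f(k) / (1 - f(0))]`` with the Poisson pmf for ``theta=None`` and
    the mean--dispersion negative binomial otherwise.  Stable for lambda
    from below 1e-8 up to around 1e3.
    """
    k = np.asarray(k)
    lam = np.asarray(lam, dtype=float)
    if np.any(k < 1):
        raise ValueError("truncated support starts at k=1")
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    if theta is None:
        return k * np.log(lam) - lam - special.gammaln(k + 1) - _log1m_f0_poisson(lam)
    theta = float(theta)
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_f = (special.gammaln(k + theta) - special.gammaln(theta)
             - special.gammaln(k + 1)
             + theta * (np.log(theta) - np.log(theta + lam))
             + k * (np.log(lam) - np.log(theta + lam)))
    return log_f - _log1m_f0_negbin(lam, theta)


# ---------------------------------------------------------------------------
# part fits
# ---------------------------------------------------------------------------

_MAX_ETA = 30.0


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing cells; impute first")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-8 if diag.max() > 0 else 1e-8
    bad = [names[j] for j in np.where(diag < tol)[0]]
    if bad:
        raise FitError(f"rank-deficient design; collinear columns: {bad}")


def _fit_logit(X: np.ndarray, z: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Newton-Raphson logistic regression with step halving."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((z.mean() + 1e-12) / (1 - z.mean() + 1e-12))

    def nll(b):
        eta = X @ b
        return -(z @ eta - np.logaddexp(0.0, eta).sum())

    prev = nll(beta)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        mu = special.expit(eta)
        g = X.T @ (z - mu)
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError as e:
            raise FitError(f"singular information matrix in zero part: {e}") from e
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            val = nll(cand)
            if val <= prev + 1e-12:
                break
            t /= 2
        beta, cur = cand, val
        if abs(prev - cur) < tol * (abs(prev) + 1):
            converged = True
            prev = cur
            break
        prev = cur
    if np.max(np.abs(beta)) > 50:
        raise SeparationError("zero-part coefficients diverged (perfect separation?)")
    eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
    mu = special.expit(eta)
    w = mu * (1 - mu)
    H = X.T @ (X * w[:, None])
    vcov = np.linalg.inv(H + 1e-12 * np.eye(p))
    return beta, vcov, -prev, converged


def _trunc_poisson_nll_grad(beta, X, y):
    eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
    lam = np.exp(eta)
    ll = y @ eta - lam.sum() - special.gammaln(y + 1).sum() - _log1m_f0_poisson(lam).sum()
    # d/dbeta: x * (y - mu_trunc), mu_trunc = lam / (1 - e^-lam)
    mu_trunc = lam / (-np.expm1(-lam))
    grad = X.T @ (y - mu_trunc)
    return -ll, -grad


def _trunc_negbin_nll_grad(params, X, y):
    beta, log_theta = params[:-1], params[-1]
    theta = np.exp(np.clip(log_theta, -20, 20))
    eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
    lam = np.exp(eta)
    log_ratio = np.log(theta) - np.log(theta + lam)
    log_f = (special.gammaln(y + theta) - special.gammaln(theta)
             - special.gammaln(y + 1) + theta * log_ratio
             + y * (eta - np.log(theta + lam)))
    # floor guards against underflow when the optimiser explores lam -> 0
    one_m_f0 = np.maximum(-np.expm1(theta * log_ratio), 1e-300)
    ll = (log_f - np.log(one_m_f0)).sum()

    f0 = 1.0 - one_m_f0
    # d/dlam and d/dtheta of [log f(y) - log(1 - f0)]
    dll_dlam = (y / lam - (y + theta) / (theta + lam)
                - theta * f0 / ((theta + lam) * one_m_f0))
    grad_beta = X.T @ (dll_dlam * lam)
    dlogf_dtheta = (special.digamma(y + theta) - special.digamma(theta)
                    + log_ratio + 1 - (y + theta) / (theta + lam))
    dlogf0_dtheta = log_ratio + 1 - theta / (theta + lam)
    dll_dtheta = (dlogf_dtheta + f0 * dlogf0_dtheta / one_m_f0).sum()
    grad = np.concatenate([grad_beta, [dll_dtheta * theta]])  # chain rule to log-theta
    return -ll, -grad


def _numeric_hessian(grad_fn, x0, eps=1e-5):
    p = len(x0)
    H = np.empty((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps * max(1.0, abs(x0[j]))
        gp = grad_fn(x0 + step)
        gm = grad_fn(x0 - step)
        H[:, j] = (gp - gm) / (2 * step[j])
    return (H + H.T) / 2


def _fit_truncated(X: np.ndarray, y: np.ndarray, family: str):
    n, p = X.shape
    # start: Poisson regression on positives ignoring truncation (one Newton-ish
    # shortcut: intercept at log mean, slopes 0, then let BFGS work)
    beta0 = np.zeros(p)
    beta0[0] = np.log(max(y.mean() - 0.5, 0.1))
    if family == "poisson":
        fun = lambda b: _trunc_poisson_nll_grad(b, X, y)
        x0 = beta0
        bounds = None
    else:
        fun = lambda par: _trunc_negbin_nll_grad(par, X, y)
        x0 = np.concatenate([beta0, [0.0]])  # theta = 1
        # the likelihood is flat in log-theta at the Poisson limit; bound it
        bounds = [(None, None)] * p + [(-10.0, 15.0)]
    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8})
    # the optimiser can stop on precision loss at the optimum; judge by the
    # gradient (ignoring the log-theta component when pinned at its bound)
    jac = np.abs(np.asarray(res.jac, dtype=float))
    if bounds is not None and res.x[-1] >= bounds[-1][1] - 1e-6:
        jac = jac[:-1]
    gnorm = float(jac.max()) if len(jac) else 0.0
    converged = bool(res.success) or gnorm < 1e-4 * (1 + abs(res.fun))
    if not converged and gnorm > 1e-3 * (1 + abs(res.fun)):
        raise FitError(f"count-part optimisation failed: {res.message}")
    grad_only = lambda x: fun(x)[1]
    H = _numeric_hessian(grad_only, res.x)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError as e:
        raise FitError(f"singular observed information in count part: {e}") from e
    if family == "poisson":
        return res.x, None, vcov, -res.fun, converged
    return res.x[:-1], float(np.exp(res.x[-1])), vcov, -res.fun, converged


def _design_matrix(design: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in predictors if c not in design.columns]
    if missing:
        raise KeyError(f"predictors absent from design: {missing}")
    X = np.column_stack([np.ones(len(design))]
                        + [pd.to_numeric(design[c]).to_numpy(float) for c in predictors]) \
        if predictors else np.ones((len(design), 1))
    return X


def fit_hurdle(design: pd.DataFrame, y, spec: HurdleSpec) -> HurdleFit:
    """Fit the hurdle model by maximising the separable log-likelihood.

    The zero part is a Bernoulli logit on ``1{y > 0}`` over all rows; the
    count part is the zero-truncated family likelihood over the positive
    rows only.  Requires at least one zero and one positive outcome.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("y must be non-negative counts")
    if np.any(y != np.floor(y)):
        raise ValueError("y must be integer counts")
    y = y.astype(int)
    z = (y > 0).astype(float)
    if z.all() or not z.any():
        raise SeparationError("outcome is all-zero or all-positive; hurdle undefined")

    Xz = _design_matrix(design, spec.zero_part_predictors)
    _check_design(Xz, ["intercept", *spec.zero_part_predictors])
    beta_zero, vcov_zero, ll_zero, conv_z = _fit_logit(Xz, z)

    pos = y > 0
    Xc = _design_matrix(design.loc[np.asarray(pos)], spec.count_part_predictors)
    _check_design(Xc, ["intercept", *spec.count_part_predictors])
    beta_count, theta, vcov_count, ll_count, conv_c = _fit_truncated(
        Xc, y[pos], spec.count_distribution)

    k = len(beta_zero) + len(beta_count) + (1 if theta is not None else 0)
    loglik = ll_zero + ll_count
    return HurdleFit(spec=spec, beta_zero=beta_zero, beta_count=beta_count,
                     theta=theta, loglik=loglik, aic=-2 * loglik + 2 * k,
                     vcov_zero=vcov_zero, vcov_count=vcov_count,
                     converged=conv_z and conv_c, n_obs=len(y), k_params=k,
                     loglik_zero=ll_zero, loglik_count=ll_count)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_parts(fit: HurdleFit, new_design: pd.DataFrame):
    """(pi, lam) linear-predictor transforms for each row of *new_design*."""
    Xz = _design_matrix(new_design, fit.spec.zero_part_predictors)
    Xc = _design_matrix(new_design, fit.spec.count_part_predictors)
    pi = special.expit(np.clip(Xz @ fit.beta_zero, -_MAX_ETA, _MAX_ETA))
    lam = np.exp(np.clip(Xc @ fit.beta_count, -_MAX_ETA, _MAX_ETA))
    return pi, lam


def predict_distribution(fit: HurdleFit, new_design: pd.DataFrame,
                         k_max: int = 50) -> PredictiveDistribution:
    """Per-subject forecast pmf over ``0..k_max`` plus exact mean and sd.

    ``P(0) = 1 - pi``; positive mass is ``pi`` times the truncated pmf.
    Moments use the closed-form first and second moments of the two-part
    law, not the truncated pmf grid, so they are exact regardless of k_max.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    pi, lam = predict_parts(fit, new_design)
    ks = np.arange(1, k_max + 1)
    logp = truncated_log_pmf(ks[None, :], lam[:, None], fit.theta)
    pmf = np.empty((len(pi), k_max + 1))
    pmf[:, 0] = 1 - pi
    pmf[:, 1:] = pi[:, None] * np.exp(logp)

    if fit.theta is None:
        denom = -np.expm1(-lam)
        ek = lam / denom
        ek2 = (lam + lam ** 2) / denom
    else:
        th = fit.theta
        f0 = np.exp(th * (np.log(th) - np.log(th + lam)))
        denom = 1 - f0
        ek = lam / denom
        ek2 = (lam + lam ** 2 * (1 + 1 / th)) / denom
    mean = pi * ek
    var = pi * ek2 - mean ** 2
    return PredictiveDistribution(p_positive=pi, pmf=pmf, mean=mean,
                                  sd=np.sqrt(np.maximum(var, 0)), k_max=k_max)


def select_distribution(design: pd.DataFrame, y, spec_poisson: HurdleSpec,
                        spec_negbin: HurdleSpec):
    """AIC choice between Poisson and negative-binomial count parts.

    Returns ``(family, fit_poisson, fit_negbin)``; ties below 1e-6 go to the
    Poisson, which has one parameter fewer.
    """
    fit_p = fit_hurdle(design, y, spec_poisson)
    fit_nb = fit_hurdle(design, y, spec_negbin)
    family = "poisson" if fit_p.aic <= fit_nb.aic + 1e-6 else "negbin"
    return family, fit_p, fit_nb
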