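"""Strictly proper scoring rules for count forecasts and fit diagnostics.

All rules are negatively oriented (smaller is better) and strictly proper:
in expectation only the true predictive distribution minimises them.

* logarithmic: ``-log P(y)``
* quadratic / Brier: ``-2 P(y) + sum_k P(k)^2`` (bounded in [-1, 1])
* Dawid--Sebastiani: ``((y - mu) / sigma)^2 + 2 log sigma``
* ranked probability score: ``sum_k (F(k) - 1{y <= k})^2``

Also provided: the score test for zero inflation of a count outcome against
a fitted Poisson model (van den Broek form) and rootogram data (square-root
scale observed vs expected count frequencies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hurdle import PredictiveDistribution

__all__ = [
    "ScoreReport", "score", "brier_binary",
    "ZeroInflationTest", "zero_inflation_score_test", "DegenerateTestError",
    "RootogramData", "rootogram",
]

RULES = ("logarithmic", "quadratic_brier", "dawid_sebastiani", "ranked_probability")


@dataclass
class ScoreReport:
    rule: str
    per_observation: np.ndarray
    mean: float


class UndefinedScoreError(ValueError):
    """The requested rule is undefined for this forecast (e.g. sigma = 0)."""


def score(dist: PredictiveDistribution, y, rule: str) -> ScoreReport:
    """Score a predictive distribution against observed counts.

    Observed values beyond the pmf truncation receive the (tiny) residual
    tail mass under the logarithmic/Brier rules; a forecast that assigns
    exactly zero mass to an observed value scores ``+inf`` under the
    logarithmic rule, with a warning.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    y = np.asarray(y, dtype=int)
    n, width = dist.pmf.shape
    if len(y) != n:
        raise ValueError("y length does not match forecast rows")

    idx = np.arange(n)
    y_cap = np.minimum(y, width - 1)
    tail = np.clip(1.0 - dist.pmf.sum(axis=1), 0.0, None)
    p_y = np.where(y <= width - 1, dist.pmf[idx, y_cap], tail)

    if rule == "logarithmic":
        with np.errstate(divide="ignore"):
            vals = -np.log(p_y)
        if np.isinf(vals).any():
            warnings.warn("forecast assigned zero mass to an observed count; "
                          "logarithmic score is +inf there")
    elif rule == "quadratic_brier":
        vals = -2 * p_y + (dist.pmf ** 2).sum(axis=1)
    elif rule == "dawid_sebastiani":
        if np.any(dist.sd <= 0):
            raise UndefinedScoreError("Dawid-Sebastiani undefined for sigma = 0")
        vals = ((y - dist.mean) / dist.sd) ** 2 + 2 * np.log(dist.sd)
    else:  # ranked_probability
        F = dist.cdf
        indicator = (y[:, None] <= np.arange(width)[None, :]).astype(float)
        vals = ((F - indicator) ** 2).sum(axis=1)
    return ScoreReport(rule=rule, per_observation=vals, mean=float(np.mean(vals)))


def brier_binary(p_positive, outcome_positive) -> ScoreReport:
    """Classical Brier score for the zero part: ``(pi - 1{y>0})^2``.

    Affinely equivalent to the quadratic count rule applied to the implied
    two-point forecast, so it ranks models identically.
    """
    p = np.asarray(p_positive, float)
    z = np.asarray(outcome_positive, float)
    vals = (p - z) ** 2
    return ScoreReport(rule="brier_binary", per_observation=vals, mean=float(vals.mean()))


# ---------------------------------------------------------------------------
# zero-inflation score test
# ---------------------------------------------------------------------------

class DegenerateTestError(RuntimeError):
    """Score-test denominator non-positive; the test statistic is undefined."""


@dataclass
class ZeroInflationTest:
    statistic: float
    df: int
    p_value: float


def zero_inflation_score_test(y, covariates: pd.DataFrame | None = None) -> ZeroInflationTest:
    """Score test for excess zeros against a fitted Poisson model.

    With Poisson fitted means ``lam_i`` and ``p0_i = exp(-lam_i)``, the
    statistic is::

        S = [sum_i (1{y_i=0} - p0_i) / p0_i]^2
            / (sum_i (1 - p0_i) / p0_i  -  n * ybar)

    referred to the chi-square distribution with 1 degree of freedom.  With
    no covariates the Poisson fit is intercept-only (``lam = ybar``), i.e. a
    test of the marginal outcome distribution.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        lam = np.full(n, y.mean())
        if y.mean() <= 0:
            raise DegenerateTestError("outcome mean is zero; Poisson fit degenerate")
    else:
        import statsmodels.api as sm
        X = sm.add_constant(np.asarray(covariates, dtype=float))
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        lam = np.asarray(res.mu)
    p0 = np.exp(-lam)
    num = (((y == 0) - p0) / p0).sum() ** 2
    den = ((1 - p0) / p0).sum() - n * y.mean()
    if den <= 0:
        raise DegenerateTestError("score-test denominator non-positive")
    s = num / den
    return ZeroInflationTest(statistic=float(s), df=1,
                             p_value=float(stats.chi2.sf(s, df=1)))


# ---------------------------------------------------------------------------
# rootograms
# ---------------------------------------------------------------------------

@dataclass
class RootogramData:
    """Observed vs model-expected count frequencies on the square-root scale.

    ``hanging`` style hangs the observed bar from the expected curve: the
    bar base sits at ``sqrt(e_k) - sqrt(o_k)``; a base below zero at k=0
    means the model under-predicts zeros (zero under-fitting).
    """
    k: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    sqrt_observed: np.ndarray
    sqrt_expected: np.ndarray
    bar_base: np.ndarray
    style: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "observed": self.observed,
                             "expected": self.expected, "bar_base": self.bar_base})


def rootogram(dist: PredictiveDistribution, y, k_max: int | None = None,
              style: str = "hanging") -> RootogramData:
    if style not in ("hanging", "standing"):
        raise ValueError("style must be 'hanging' or 'standing'")
    y = np.asarray(y, dtype=int)
    if k_max is None:
        k_max = max(int(y.max()), 1)
    if k_max < int(y.max()):
        raise ValueError("k_max must cover max(y)")
    k = np.arange(k_max + 1)
    observed = np.bincount(y, minlength=k_max + 1)[: k_max + 1].astype(float)
    width = dist.pmf.shape[1]
    expected = dist.pmf[:, : k_max + 1].sum(axis=0)
    if k_max >= width:
        expected = np.pad(expected, (0, k_max + 1 - width))
    so, se = np.sqrt(observed), np.sqrt(expected)
    base = se - so if style == "hanging" else np.zeros_like(so)
    return RootogramData(k=k, observed=observed, expected=expected,
                         sqrt_observed=so, sqrt_expected=se, bar_base=base,
                         style=style)
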