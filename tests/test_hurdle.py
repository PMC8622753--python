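"""Hurdle regression: truncated likelihoods, MLE, prediction, family choice."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special

from hurdlebss import hurdle
from hurdlebss.hurdle import (FitError, HurdleSpec, SeparationError,
                              fit_hurdle, predict_distribution,
                              select_distribution, truncated_log_pmf)
from tests.conftest import sample_hurdle_poisson


def series_truncated_log_pmf(k, lam, terms=50):
    """Independent oracle: truncated Poisson pmf via explicit series for 1-f(0)."""
    log_f = k * math.log(lam) - lam - math.lgamma(k + 1)
    one_minus_f0 = sum(math.exp(-lam) * lam ** j / math.factorial(j)
                       for j in range(1, terms))
    return log_f - math.log(one_minus_f0)


class TestTruncatedPmf:
    def test_poisson_value_against_series_oracle(self):
        expected = series_truncated_log_pmf(2, 1.0)       # = -1.2344720...
        assert truncated_log_pmf(2, 1.0) == pytest.approx(expected, abs=1e-10)
        assert truncated_log_pmf(2, 1.0) == pytest.approx(-1.2344720352, abs=1e-9)

    def test_tiny_lambda_mass_concentrates_at_one(self):
        assert truncated_log_pmf(1, 1e-10) == pytest.approx(0.0, abs=1e-9)

    def test_large_lambda_stable(self):
        v = truncated_log_pmf(1000, 1e3)
        assert np.isfinite(v)

    def test_negbin_poisson_limit(self):
        assert truncated_log_pmf(2, 1.0, theta=1e6) == pytest.approx(
            truncated_log_pmf(2, 1.0), abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            truncated_log_pmf(0, 1.0)
        with pytest.raises(ValueError):
            truncated_log_pmf(1, -1.0)
        with pytest.raises(ValueError):
            truncated_log_pmf(1, 1.0, theta=0.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(lam=st.floats(1e-4, 40.0), theta=st.one_of(st.none(), st.floats(0.1, 50.0)))
    def test_normalisation(self, lam, theta):
        var = lam + (lam ** 2 / theta if theta else 0.0)
        k_hi = int(lam + 60 * np.sqrt(var)) + 10
        ks = np.arange(1, k_hi)
        total = np.exp(truncated_log_pmf(ks, lam, theta)).sum()
        assert total == pytest.approx(1.0, abs=1e-6)


class TestFit:
    def test_intercept_only_zero_part(self):
        fit = fit_hurdle(pd.DataFrame(index=range(4)), [0, 0, 1, 1],
                         HurdleSpec((), (), "poisson"))
        assert fit.beta_zero[0] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_count_part_mean_equation(self):
        # lambda-hat solves lam/(1-e^-lam) = mean of positives = 4/3
        oracle = optimize.brentq(
            lambda lam: lam / (1 - np.exp(-lam)) - 4 / 3, 1e-8, 10)
        fit = fit_hurdle(pd.DataFrame(index=range(6)), [0, 0, 0, 1, 1, 2],
                         HurdleSpec((), (), "poisson"))
        assert np.exp(fit.beta_count[0]) == pytest.approx(oracle, abs=1e-6)
        assert oracle == pytest.approx(0.606, abs=1e-3)

    def test_mle_matches_grid_search_oracle(self):
        """On a 20-row fixture the MLE must agree with exhaustive grid search."""
        rng = np.random.default_rng(42)
        x1 = rng.binomial(1, 0.5, 20).astype(float)
        x2 = rng.normal(0, 1, 20).round(1)
        y = np.array([0, 0, 1, 2, 0, 1, 0, 0, 3, 1, 0, 0, 2, 0, 1, 0, 0, 1, 4, 0])
        design = pd.DataFrame({"x1": x1, "x2": x2})
        fit = fit_hurdle(design, y, HurdleSpec(("x1",), ("x2",), "poisson"))

        grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
        z = (y > 0).astype(float)
        B0, B1 = np.meshgrid(grid, grid, indexing="ij")
        eta = B0[..., None] + B1[..., None] * x1[None, None, :]
        ll_zero = (z * eta - np.logaddexp(0, eta)).sum(-1)
        i, j = np.unravel_index(np.argmax(ll_zero), ll_zero.shape)
        assert fit.beta_zero == pytest.approx([grid[i], grid[j]], abs=0.01)

        yp, xp = y[y > 0], x2[y > 0]
        eta = B0[..., None] + B1[..., None] * xp[None, None, :]
        lam = np.exp(eta)
        ll_cnt = (yp * eta - lam - special.gammaln(yp + 1)
                  - np.log(-np.expm1(-lam))).sum(-1)
        i, j = np.unravel_index(np.argmax(ll_cnt), ll_cnt.shape)
        assert fit.beta_count == pytest.approx([grid[i], grid[j]], abs=0.01)

    def test_separability_and_aic_identity(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame({"x": rng.normal(size=300)})
        y = sample_hurdle_poisson(rng, 0.5, 1.5, 300)
        fit = fit_hurdle(design, y, HurdleSpec(("x",), ("x",), "poisson"))
        assert fit.loglik == pytest.approx(fit.loglik_zero + fit.loglik_count,
                                           abs=1e-8)
        assert fit.aic == -2 * fit.loglik + 2 * fit.k_params
        # independently refit parts must reproduce the joint optimum
        fz = fit_hurdle(design, y, HurdleSpec(("x",), (), "poisson"))
        assert fz.loglik_zero == pytest.approx(fit.loglik_zero, abs=1e-6)

    def test_degenerate_outcomes_raise(self):
        df = pd.DataFrame(index=range(10))
        with pytest.raises(SeparationError):
            fit_hurdle(df, np.zeros(10, int), HurdleSpec((), (), "poisson"))
        with pytest.raises(SeparationError):
            fit_hurdle(df, np.ones(10, int), HurdleSpec((), (), "poisson"))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        y = sample_hurdle_poisson(rng, 0.5, 1.0, 60)
        with pytest.raises(FitError, match="collinear"):
            fit_hurdle(design, y, HurdleSpec(("a", "b"), (), "poisson"))

    def test_missing_cells_rejected(self):
        design = pd.DataFrame({"a": [1.0, np.nan, 0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            fit_hurdle(design, [0, 1, 0, 1], HurdleSpec(("a",), (), "poisson"))

    def test_crosscheck_against_statsmodels_hurdle(self):
        """Independent oracle: the count part of statsmodels' hurdle model
        (same zero-truncated Poisson likelihood) must agree coefficient-wise."""
        import statsmodels.api as sm
        from statsmodels.discrete.truncated_model import HurdleCountModel
        rng = np.random.default_rng(7)
        n = 600
        design = pd.DataFrame({"x1": rng.normal(size=n),
                               "x2": rng.binomial(1, 0.4, n).astype(float)})
        lam = np.exp(0.3 + 0.4 * design.x2)
        pi = special.expit(-0.5 + 0.8 * design.x1)
        y = sample_hurdle_poisson(rng, pi, lam, n)
        ours = fit_hurdle(design, y, HurdleSpec(("x1", "x2"), ("x1", "x2"), "poisson"))
        res = HurdleCountModel(y, sm.add_constant(design), dist="poisson",
                               zerodist="poisson").fit(disp=0)
        np.testing.assert_allclose(ours.beta_count, res.params.values[3:], atol=1e-3)
        # intercept-only zero parts describe the same P(y>0) despite differing links
        ours0 = fit_hurdle(design, y, HurdleSpec((), (), "poisson"))
        assert special.expit(ours0.beta_zero[0]) == pytest.approx((y > 0).mean(),
                                                                  abs=1e-6)


@pytest.fixture()
def unit_fit():
    # pi = 0.5, lambda = 1 by construction
    df = pd.DataFrame(index=range(8))
    y = [0, 0, 0, 0, 1, 1, 1, 1]
    fit = fit_hurdle(df, y, HurdleSpec((), (), "poisson"))
    fit.beta_zero[0] = 0.0
    fit.beta_count[0] = 0.0
    return fit


class TestPredict:
    def test_closed_form_cells(self, unit_fit):
        dist = predict_distribution(unit_fit, pd.DataFrame(index=[0]), k_max=50)
        assert dist.p_positive[0] == pytest.approx(0.5)
        assert dist.pmf[0, 0] == pytest.approx(0.5)
        expected_p1 = 0.5 * np.exp(-1) / (1 - np.exp(-1))   # 0.29099...
        assert dist.pmf[0, 1] == pytest.approx(expected_p1, abs=1e-10)
        assert dist.pmf[0, 1] == pytest.approx(0.2910, abs=5e-5)

    def test_moments_match_pmf_grid(self, unit_fit):
        dist = predict_distribution(unit_fit, pd.DataFrame(index=[0]), k_max=80)
        ks = np.arange(81)
        mean_grid = (ks * dist.pmf[0]).sum()
        var_grid = (ks ** 2 * dist.pmf[0]).sum() - mean_grid ** 2
        assert dist.mean[0] == pytest.approx(mean_grid, abs=1e-10)
        assert dist.sd[0] == pytest.approx(np.sqrt(var_grid), abs=1e-10)

    def test_truncation_tail_bound(self):
        df = pd.DataFrame(index=range(4))
        fit = fit_hurdle(df, [0, 5, 9, 20], HurdleSpec((), (), "poisson"))
        dist = predict_distribution(fit, df, k_max=50)
        assert (dist.pmf.sum(axis=1) >= 0.999).all()

    def test_k_max_validation(self, unit_fit):
        with pytest.raises(ValueError):
            predict_distribution(unit_fit, pd.DataFrame(index=[0]), k_max=0)


class TestSelectDistribution:
    def test_poisson_data_prefers_poisson(self):
        # AIC overselects the boundary NB in a known ~8% of samples, so the
        # consistency property is asserted over replicates, not a single draw
        chosen = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 5000
            y = sample_hurdle_poisson(rng, 0.6, 2.0, n)
            fam, _, _ = select_distribution(pd.DataFrame(index=range(n)), y,
                                            HurdleSpec((), (), "poisson"),
                                            HurdleSpec((), (), "negbin"))
            chosen.append(fam)
        assert chosen.count("poisson") >= 6

    def test_overdispersed_data_prefers_negbin(self):
        from scipy import stats
        rng = np.random.default_rng(12)
        n, th, lam = 5000, 0.5, np.exp(0.8)
        p_nb = th / (th + lam)
        f0 = p_nb ** th
        pos = rng.random(n) < 0.6
        y = np.zeros(n, int)
        u = rng.random(int(pos.sum()))
        y[pos] = np.maximum(stats.nbinom.ppf(f0 + u * (1 - f0), th, p_nb).astype(int), 1)
        fam, _, fit_nb = select_distribution(pd.DataFrame(index=range(n)), y,
                                             HurdleSpec((), (), "poisson"),
                                             HurdleSpec((), (), "negbin"))
        assert fam == "negbin"
        assert fit_nb.theta == pytest.approx(th, rel=0.2)

    def test_equidispersed_boundary_goes_to_poisson(self):
        # theta runs to its upper bound on Poisson data; the extra parameter
        # buys nothing, so the AIC tie-break keeps the Poisson
        rng = np.random.default_rng(13)
        y = sample_hurdle_poisson(rng, 0.5, 1.0, 400)
        fam, fit_p, fit_nb = select_distribution(pd.DataFrame(index=range(400)), y,
                                                 HurdleSpec((), (), "poisson"),
                                                 HurdleSpec((), (), "negbin"))
        assert fam == "poisson"
        assert abs(fit_nb.loglik - fit_p.loglik) < 1e-2


def test_spec_round_trip_and_validation():
    spec = HurdleSpec(("a", "b"), ("c",), "negbin")
    assert HurdleSpec.from_json(spec.to_json()) == spec
    with pytest.raises(ValueError):
        HurdleSpec((), (), "gaussian")
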