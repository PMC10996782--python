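import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from farsight.choice_task import TaskDesign, build_choice_set
from farsight.cohort import simulate_agent_choices
from farsight.discounting import (
    DiscountingParams,
    GroupPrior,
    McmcSettings,
    choice_probability,
    classify_choices,
    detect_random_responders,
    ebert_prelec_sv,
    fit_hierarchical,
    hyperbolic_sv,
)
from tests.conftest import choices_frame


class TestHyperbolicSV:
    def test_zero_delay_identity(self):
        assert hyperbolic_sv(50, 0.123, 0) == 50

    def test_half_value_point(self):
        assert hyperbolic_sv(100, 0.01, 100) == pytest.approx(50)

    def test_against_high_precision_arithmetic(self):
        # independent evaluation with sympy's arbitrary precision
        import sympy

        expected = float(170 / (1 + sympy.exp(sympy.Rational(-53, 10)) * 180))
        assert hyperbolic_sv(170, math.exp(-5.3), 180) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hyperbolic_sv(50, -0.1, 10)
        with pytest.raises(ValueError):
            hyperbolic_sv(50, 0.1, -1)

    @given(
        st.floats(1, 200), st.floats(1e-6, 1.0),
        st.floats(0, 365), st.floats(0, 365),
    )
    def test_monotone_nonincreasing_in_delay(self, amount, k, t1, t2):
        lo, hi = sorted((t1, t2))
        assert hyperbolic_sv(amount, k, hi) <= hyperbolic_sv(amount, k, lo)


class TestEbertPrelecSV:
    def test_no_discounting_at_zero_impatience(self):
        assert ebert_prelec_sv(30, 0.0, 1.0, 100) == pytest.approx(30)

    def test_exponential_limit(self):
        assert ebert_prelec_sv(30, 0.01, 1.0, 100) == pytest.approx(30 * math.exp(-1))

    def test_against_high_precision_arithmetic(self):
        import sympy

        a, b, t = sympy.Rational(1, 100), sympy.Rational(1, 2), 150
        expected = float(30 * sympy.exp(-((a * t) ** b)))
        assert ebert_prelec_sv(30, 0.01, 0.5, 150) == pytest.approx(expected, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ebert_prelec_sv(30, 0.01, 0.0, 10)

    @given(st.floats(1, 200), st.floats(0, 0.2), st.floats(0.1, 3))
    def test_agrees_with_hyperbolic_at_zero_delay(self, amount, a, b):
        assert ebert_prelec_sv(amount, a, b, 0) == pytest.approx(
            hyperbolic_sv(amount, a, 0)
        )


class TestChoiceProbability:
    def test_equal_values_give_half(self):
        for alpha, eps in [(0.5, 0.0), (3.0, 0.1), (10.0, 0.5)]:
            assert choice_probability(20, 20, alpha, eps) == pytest.approx(0.5)

    def test_pure_noise_limit(self):
        assert choice_probability(5, 80, 1.0, 0.5) == pytest.approx(0.5)

    def test_one_noise_unit_difference(self):
        # SV difference of exactly alpha, no lapses: standard normal CDF at 1
        assert choice_probability(10, 10 + 3.0, 3.0, 0.0) == pytest.approx(
            norm.cdf(1.0), abs=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            choice_probability(10, 20, 0.0, 0.1)
        with pytest.raises(ValueError):
            choice_probability(10, 20, 1.0, 0.7)

    @given(
        st.floats(-100, 100), st.floats(-100, 100), st.floats(0.01, 50),
        st.floats(0, 0.5),
    )
    def test_bounded_and_monotone(self, sv_ss, sv_ll, alpha, eps):
        p = choice_probability(sv_ss, sv_ll, alpha, eps)
        assert eps - 1e-12 <= p <= 1 - eps + 1e-12
        p_hi = choice_probability(sv_ss, sv_ll + 1.0, alpha, eps)
        assert p_hi >= p - 1e-12


class TestDiscountingParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(log_k=float("inf"), alpha=1, epsilon=0.1),
            dict(log_k=-5, alpha=0, epsilon=0.1),
            dict(log_k=-5, alpha=1, epsilon=0.6),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiscountingParams(**kwargs)


class TestHierarchicalFit:
    def test_data_free_fit_recovers_prior(self):
        # with no trials the group-level posterior must match the prior
        empty = pd.DataFrame(
            columns=["participant_id", "ss_amount", "ss_delay_days",
                     "ll_amount", "ll_delay_days", "choice"]
        )
        fit = fit_hierarchical(
            empty,
            settings=McmcSettings(n_chains=4, n_samples=2500, n_burnin=500, seed=9),
            participants=["a", "b", "c"],
        )
        mu = fit.posterior["mu_logk"].ravel()
        assert abs(mu.mean() - (-5.3)) < 0.4
        assert np.percentile(mu, 2.5) < -5.3 < np.percentile(mu, 97.5)

    def test_deterministic_agents_bracketed(self, trial_set):
        true = [-5.8, -3.6]
        agents = [
            (f"p{i}", DiscountingParams(log_k=lk, alpha=0.5, epsilon=0.0), 30 + i)
            for i, lk in enumerate(true)
        ]
        df = choices_frame(trial_set, agents)
        fit = fit_hierarchical(
            df, settings=McmcSettings(n_chains=4, n_samples=1500, n_burnin=400, seed=2)
        )
        s = fit.summary.set_index("participant_id")
        for pid, lk in zip(["p0", "p1"], true):
            assert s.loc[pid, "logk_hdi_2.5"] < lk < s.loc[pid, "logk_hdi_97.5"]
        assert classify_choices(fit) >= 0.95

    def test_shrinkage_toward_group_mean(self, trial_set):
        # a sparse-data participant generated off-group is pulled toward the
        # group mean relative to an independent (flat-hierarchy) fit
        group_true = [-5.6, -5.2, -5.4, -5.0, -5.5]
        agents = [
            (f"g{i}", DiscountingParams(log_k=lk, alpha=1.0, epsilon=0.01), 50 + i)
            for i, lk in enumerate(group_true)
        ]
        sparse_params = DiscountingParams(log_k=-2.8, alpha=1.0, epsilon=0.01)
        df = choices_frame(trial_set, agents)
        df_sparse = choices_frame(trial_set[:10], [("sparse", sparse_params, 99)])
        full = pd.concat([df, df_sparse], ignore_index=True)
        settings = McmcSettings(n_chains=4, n_samples=1500, n_burnin=400, seed=6)
        fit = fit_hierarchical(full, settings=settings)
        s = fit.summary.set_index("participant_id")
        pooled = s.loc["sparse", "logk_mean"]
        group_mean = s.loc[[f"g{i}" for i in range(5)], "logk_mean"].mean()
        # independent fit: same model, sparse participant alone, diffuse prior
        alone = fit_hierarchical(
            df_sparse,
            prior=GroupPrior(logk_mean=-5.3, logk_sd=10.0, logk_group_sd_scale=10.0),
            settings=settings,
        )
        independent = alone.summary["logk_mean"].iloc[0]
        assert abs(pooled - group_mean) < abs(independent - group_mean)

    def test_empty_group_rejected(self):
        empty = pd.DataFrame(
            columns=["participant_id", "ss_amount", "ss_delay_days",
                     "ll_amount", "ll_delay_days", "choice"]
        )
        with pytest.raises(ValueError, match="empty group"):
            fit_hierarchical(empty)

    def test_unknown_choice_codes_rejected(self, trial_set):
        df = choices_frame(
            trial_set[:5], [("p", DiscountingParams(-5, 1, 0.0), 1)]
        )
        df.loc[0, "choice"] = "later"
        with pytest.raises(ValueError, match="choice codes"):
            fit_hierarchical(df)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            McmcSettings(n_chains=1).validate()
        with pytest.raises(ValueError):
            McmcSettings(n_samples=100, n_burnin=100).validate()

    def test_paper_scale_settings_constructible(self):
        s = McmcSettings.paper_scale()
        s.validate()
        assert s.n_chains == 4
        assert s.n_samples == 25_000
        assert s.n_burnin == 1_000
        assert s.n_retained == 96_000
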