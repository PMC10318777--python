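import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from pbam.bias_params import (
    BiasModel,
    BiasParamSpec,
    fit_beta_moments,
    fit_logit_logistic,
    fit_triangular,
    sample_draws,
)

LOGISTIC_SD = math.pi / math.sqrt(3.0)


class TestTriangularFit:
    @pytest.mark.parametrize(
        "estimate, lo, hi, expected",
        [
            (0.65, 0.41, 0.89, (0.41, 0.89, 0.65)),
            (0.92, 0.77, 1.00, (0.77, 1.00, 0.92)),
            (0.5, 0.5, 0.5, (0.5, 0.5, 0.5)),  # degenerate point mass
        ],
    )
    def test_support_is_ci_and_mode_is_estimate(self, estimate, lo, hi, expected):
        spec = fit_triangular(estimate, lo, hi)
        assert spec.params == expected

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            fit_triangular(0.3, 0.5, 0.9)

    def test_degenerate_ppf_is_constant(self):
        spec = fit_triangular(0.5, 0.5, 0.5)
        assert np.all(spec.ppf(np.linspace(0.01, 0.99, 9)) == 0.5)


class TestBetaMomentFit:
    def test_pooled_case_sensitivity_parameters(self):
        spec = fit_beta_moments(0.65, 0.41, 0.89)
        assert spec.params[0] == pytest.approx(9.21, abs=5e-3)
        assert spec.params[1] == pytest.approx(4.96, abs=5e-3)

    def test_symmetric_ci_gives_equal_shapes(self):
        spec = fit_beta_moments(0.5, 0.5 - 1.96 * 0.05, 0.5 + 1.96 * 0.05)
        assert spec.params[0] == pytest.approx(spec.params[1])

    def test_matches_independent_optimizer(self):
        # independently fit (alpha, beta) by numerically matching mean and sd
        m, lo, hi = 0.54, 0.42, 0.65
        sd = (hi - lo) / (2 * 1.96)

        def loss(p):
            a, b = p
            mean = a / (a + b)
            var = a * b / ((a + b) ** 2 * (a + b + 1))
            return (mean - m) ** 2 + (math.sqrt(var) - sd) ** 2

        res = optimize.minimize(loss, x0=[5.0, 5.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14})
        spec = fit_beta_moments(m, lo, hi)
        assert spec.params == pytest.approx(tuple(res.x), rel=1e-4)

    def test_too_wide_ci_fails_with_bound(self):
        # CI so wide no beta with this mean has the implied sd
        with pytest.raises(ValueError, match="too large"):
            fit_beta_moments(0.05, 0.0, 0.9)

    @given(
        m=st.floats(0.05, 0.95),
        half=st.floats(0.01, 0.15),
    )
    @settings(max_examples=100, deadline=None)
    def test_mean_round_trip(self, m, half):
        lo, hi = max(0.0, m - half), min(1.0, m + half)
        try:
            spec = fit_beta_moments(m, lo, hi)
        except ValueError:
            return
        a, b = spec.params
        assert a / (a + b) == pytest.approx(m, abs=1e-12)


class TestLogitLogisticFit:
    @pytest.mark.parametrize(
        "estimate, lo, hi, scale",
        [(0.65, 0.41, 0.89, 0.0675)],
    )
    def test_location_and_scale(self, estimate, lo, hi, scale):
        spec = fit_logit_logistic(estimate, lo, hi)
        assert spec.params[0] == estimate
        assert spec.params[1] == pytest.approx(scale, abs=5e-5)

    @pytest.mark.parametrize("m, lo, hi", [(0.6, 0.49, 0.77), (0.9, 0.85, 1.0), (0.3, 0.2, 0.42)])
    def test_scale_equals_beta_sd_over_logistic_sd(self, m, lo, hi):
        beta_spec = fit_beta_moments(m, lo, hi)
        sd = stats.beta(*beta_spec.params).std()
        spec = fit_logit_logistic(m, lo, hi)
        assert spec.params[1] == pytest.approx(sd / LOGISTIC_SD, rel=1e-12)

    def test_identity_link_draws_truncated_to_unit_interval(self):
        spec = fit_logit_logistic(0.92, 0.77, 1.0)
        draws = spec.ppf(np.linspace(1e-9, 1 - 1e-9, 10001))
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_logit_link_alternative(self):
        spec = fit_logit_logistic(0.65, 0.41, 0.89, link="logit")
        u = np.linspace(1e-6, 1 - 1e-6, 1001)
        draws = spec.ppf(u)
        assert np.all((draws > 0) & (draws < 1))
        assert spec.ppf(0.5) == pytest.approx(0.65)  # median preserved


class TestSampling:
    def _nd_model(self):
        return BiasModel.from_pooled(
            "triangular",
            total={"sensitivity": {"estimate": 0.65, "ci": [0.41, 0.89]},
                   "specificity": {"estimate": 0.92, "ci": [0.77, 1.0]}},
        )

    def _diff_model(self, correlation, family="beta", correlate="across_groups"):
        block_case = {"sensitivity": {"estimate": 0.65, "ci": [0.41, 0.89]},
                      "specificity": {"estimate": 0.93, "ci": [0.80, 1.0]}}
        block_ctrl = {"sensitivity": {"estimate": 0.54, "ci": [0.42, 0.65]},
                      "specificity": {"estimate": 0.90, "ci": [0.85, 1.0]}}
        return BiasModel.from_pooled(family, case=block_case, control=block_ctrl,
                                     differential=True, correlation=correlation,
                                     correlate=correlate)

    def test_all_draws_in_unit_interval(self):
        for model in (self._nd_model(), self._diff_model(0.5, "logit_logistic")):
            d = model.sample(20_000, seed=0)
            for arr in (d.sens_case, d.spec_case, d.sens_control, d.spec_control):
                assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_nondifferential_draws_shared_between_groups(self):
        d = self._nd_model().sample(1000, seed=7)
        np.testing.assert_array_equal(d.sens_case, d.sens_control)
        np.testing.assert_array_equal(d.spec_case, d.spec_control)

    def test_triangular_mean(self):
        # closed-form triangular mean (min+max+mode)/3
        spec = fit_triangular(0.65, 0.41, 0.89)
        draws = spec.ppf(np.random.default_rng(11).random(1_000_000))
        sd = stats.triang((0.65 - 0.41) / 0.48, loc=0.41, scale=0.48).std()
        assert draws.mean() == pytest.approx(0.65, abs=3 * sd / 1000)

    def test_comonotone_limit_correlation_one(self):
        # same marginal in both groups + copula r=1 -> identical quantiles
        block = {"sensitivity": {"estimate": 0.65, "ci": [0.41, 0.89]},
                 "specificity": {"estimate": 0.93, "ci": [0.80, 1.0]}}
        model = BiasModel.from_pooled("beta", case=block, control=block,
                                      differential=True, correlation=1.0)
        d = model.sample(5000, seed=3)
        np.testing.assert_allclose(d.sens_case, d.sens_control, rtol=1e-12)

    def test_zero_correlation_empirically_uncorrelated(self):
        n = 100_000
        d = self._diff_model(0.0).sample(n, seed=5)
        r = np.corrcoef(d.sens_case, d.sens_control)[0, 1]
        assert abs(r) < 3 / math.sqrt(n)

    def test_copula_preserves_marginals(self):
        # KS distance between coupled draws and direct marginal draws
        n = 100_000
        model = self._diff_model(0.8)
        d = model.sample(n, seed=9)
        direct = model.sens_case.ppf(np.random.default_rng(13).random(n))
        ks = stats.ks_2samp(d.sens_case, direct)
        assert ks.statistic < 1.36 * math.sqrt(2.0 / n) * 1.5  # 5% critical value, slack

    def test_deterministic_given_seed(self):
        m = self._diff_model(0.25, "logit_logistic")
        d1, d2 = m.sample(500, seed=42), m.sample(500, seed=42)
        np.testing.assert_array_equal(d1.sens_case, d2.sens_case)
        np.testing.assert_array_equal(d1.spec_control, d2.spec_control)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            sample_draws(BiasParamSpec.point_mass(0.6), BiasParamSpec.point_mass(0.9),
                         n=10, correlation=1.5)

    def test_within_group_correlation_mode(self):
        n = 50_000
        d = self._diff_model(0.8, correlate="within_group").sample(n, seed=17)
        r_within = np.corrcoef(d.sens_case, d.spec_case)[0, 1]
        r_across = np.corrcoef(d.sens_case, d.sens_control)[0, 1]
        assert r_within > 0.5
        assert abs(r_across) < 3 / math.sqrt(n)
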