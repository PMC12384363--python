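import numpy as np
import pytest
from scipy import stats

from histoprior import (
    BetaSpec,
    IntervalSummary,
    ValidationError,
    beta_quantile,
    fit_beta_mixture,
    fit_beta_to_interval,
)
from histoprior.beta_tools import FitError, em_fit


class TestBetaQuantile:
    def test_alpha_one_closed_form(self):
        # Beta(1, b): q(p) = 1 - (1-p)^(1/b)
        got = beta_quantile(BetaSpec(1, 308), 0.975)
        assert got == pytest.approx(1 - 0.025 ** (1 / 308), rel=1e-12)

    @pytest.mark.parametrize("spec", [BetaSpec(1, 1), BetaSpec(2, 2)])
    def test_symmetric_median(self, spec):
        assert beta_quantile(spec, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_q(self):
        spec = BetaSpec(0.7, 120)
        qs = [beta_quantile(spec, q) for q in (0.05, 0.25, 0.5, 0.75, 0.95)]
        assert qs == sorted(qs)

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            beta_quantile(BetaSpec(1, 1), 1.0)


class TestFitBetaToInterval:
    def test_round_trip_identity(self):
        truth = BetaSpec(2, 50)
        summary = IntervalSummary(
            lower=beta_quantile(truth, 0.025),
            upper=beta_quantile(truth, 0.975),
            point=truth.mean,
        )
        fit = fit_beta_to_interval(summary)
        assert fit.alpha == pytest.approx(2, rel=0.01)
        assert fit.beta == pytest.approx(50, rel=0.01)

    def test_pooled_historical_summary(self):
        # posterior-mean summary of the common-rate historical posterior
        fit = fit_beta_to_interval(
            IntervalSummary(lower=0.00008, upper=0.0119, point=0.00324)
        )
        assert fit.alpha == pytest.approx(1.0, rel=0.05)
        assert fit.beta == pytest.approx(308, rel=0.05)

    def test_meta_analytic_summary(self):
        # Wald-interval summary: point is a median-type location and the
        # lower bound is jointly infeasible for a two-parameter beta
        fit = fit_beta_to_interval(
            IntervalSummary(
                lower=0.00055, upper=0.02713, point=0.0039, point_type="median"
            ),
            use_lower=False,
        )
        assert fit.alpha == pytest.approx(0.74, rel=0.02)
        assert fit.beta == pytest.approx(113.57, rel=0.02)

    def test_self_consistency_via_quantiles(self):
        truth = BetaSpec(1.5, 80)
        summary = IntervalSummary(
            lower=beta_quantile(truth, 0.025),
            upper=beta_quantile(truth, 0.975),
            point=truth.mean,
        )
        fit = fit_beta_to_interval(summary)
        assert beta_quantile(fit, 0.025) == pytest.approx(summary.lower, rel=0.01)
        assert beta_quantile(fit, 0.975) == pytest.approx(summary.upper, rel=0.01)

    def test_zero_lower_bound_fits_upper_and_mean(self):
        truth = BetaSpec(1, 300)
        summary = IntervalSummary(
            lower=0.0, upper=beta_quantile(truth, 0.975), point=truth.mean
        )
        fit = fit_beta_to_interval(summary)
        assert fit.beta == pytest.approx(300, rel=0.05)

    def test_infeasible_summary_raises_with_residual(self):
        # nearly point-mass interval with a point far outside any beta's reach
        bad = IntervalSummary(lower=0.4, upper=0.6, point=0.401, point_type="median")
        with pytest.raises(FitError) as exc:
            fit_beta_to_interval(bad)
        assert exc.value.residual is not None and exc.value.residual > 0.01

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValidationError):
            IntervalSummary(lower=0.5, upper=0.2)
        with pytest.raises(ValidationError):
            IntervalSummary(lower=0.1, upper=0.2, point=0.5)


class TestBetaMixtureFit:
    def test_single_beta_recovery(self):
        rng = np.random.default_rng(11)
        draws = rng.beta(3, 100, 10_000)
        mixture, k, aic = fit_beta_mixture(draws, k_max=2)
        assert k == 1
        (w, comp), = mixture.components
        assert w == pytest.approx(1.0)
        assert comp.alpha == pytest.approx(3, rel=0.10)
        assert comp.beta == pytest.approx(100, rel=0.10)
        assert aic[1] < aic[2]

    def test_unimodal_data_rarely_splits_into_two_components(self):
        # AIC has a known non-vanishing overfit probability (the extra
        # component's likelihood-ratio gain occasionally exceeds the
        # penalty), so we require k = 1 in at least 9 of 10 seeds rather
        # than in every realization
        hits = 0
        for seed in range(10):
            draws = np.random.default_rng(seed).beta(2, 300, 5000)
            _, k, _ = fit_beta_mixture(draws, k_max=2)
            hits += k == 1
        assert hits >= 9

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(5)
        draws = np.concatenate([rng.beta(2, 200, 5000), rng.beta(50, 50, 5000)])
        mixture, k, _ = fit_beta_mixture(draws, k_max=3)
        assert k >= 2
        comps = sorted(mixture.components, key=lambda ws: ws[1].mean)
        lo_w, lo = comps[0]
        hi_w, hi = comps[-1]
        assert lo_w == pytest.approx(0.5, abs=0.05)
        assert lo.alpha == pytest.approx(2, rel=0.15)
        assert lo.beta == pytest.approx(200, rel=0.15)
        assert hi.alpha == pytest.approx(50, rel=0.15)
        assert hi.beta == pytest.approx(50, rel=0.15)

    @pytest.mark.parametrize("k", [1, 2])
    def test_em_loglik_monotone(self, k):
        rng = np.random.default_rng(3)
        draws = np.concatenate([rng.beta(2, 150, 3000), rng.beta(10, 30, 3000)])
        _, _, trace = em_fit(draws, k)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-7 * (1 + np.abs(trace[:-1])))

    def test_draws_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            fit_beta_mixture(np.array([0.1, 0.5, 1.0]), k_max=1)
        with pytest.raises(ValidationError):
            fit_beta_mixture(np.array([0.0, 0.5]), k_max=1)

    def test_invalid_k_max(self):
        with pytest.raises(ValidationError):
            fit_beta_mixture(np.array([0.1, 0.2, 0.3]), k_max=0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        draws = rng.beta(5, 20, 4000)
        mixture, _, _ = fit_beta_mixture(draws, k_max=3)
        assert float(mixture.weights.sum()) == pytest.approx(1.0, abs=1e-9)
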