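import math

import numpy as np
import pytest

from histoprior import (
    EventCount,
    HistoricalSet,
    HistoricalStudy,
    beta_quantile,
    corrected_proportion,
    dersimonian_laird_tau2,
    meta_pool,
    meta_prior_for_wildtype,
)


def make_set(*counts):
    return HistoricalSet(
        tuple(
            HistoricalStudy(f"s{i}", x, n, follow_up_weeks=130.0)
            for i, (x, n) in enumerate(counts)
        )
    )


class TestCorrectedProportion:
    def test_zero_event_study_gets_continuity_correction(self):
        p, theta, se = corrected_proportion(EventCount("s", 0, 234))
        assert p == pytest.approx(0.5 / 235)
        assert theta == pytest.approx(math.log((0.5 / 235) / (1 - 0.5 / 235)))
        assert se**2 == pytest.approx(1 / 0.5 + 1 / 234.5)

    def test_small_zero_event_study(self):
        p, _, _ = corrected_proportion(EventCount("s", 0, 69))
        assert p == pytest.approx(0.5 / 70)

    def test_interior_study_uncorrected(self):
        p, theta, se = corrected_proportion(EventCount("s", 5, 10))
        assert p == 0.5
        assert theta == 0.0
        assert se**2 == pytest.approx(1 / 5 + 1 / 5)

    def test_all_event_study_symmetric_correction(self):
        p, _, se = corrected_proportion(EventCount("s", 10, 10))
        assert p == pytest.approx(10.5 / 11)
        assert se**2 == pytest.approx(1 / 10.5 + 1 / 0.5)


class TestDerSimonianLaird:
    def test_zero_event_fixture_has_no_heterogeneity(self, historical):
        effects = [
            corrected_proportion(s.event_count())[1:] for s in historical.studies
        ]
        assert dersimonian_laird_tau2(effects) == 0.0

    def test_identical_studies(self):
        effects = [(-3.0, 0.5), (-3.0, 0.5)]
        assert dersimonian_laird_tau2(effects) == 0.0

    def test_three_studies_vs_direct_recomputation(self):
        effects = [(-2.0, 0.5), (0.0, 0.5), (2.0, 0.5)]
        # direct evaluation of the moment formula with equal weights w = 4
        w = 4.0
        theta_bar = 0.0
        q = sum(w * (t - theta_bar) ** 2 for t, _ in effects)  # 32
        c = 3 * w - 3 * w**2 / (3 * w)  # 8
        want = (q - 2) / c
        assert dersimonian_laird_tau2(effects) == pytest.approx(want, rel=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.meta_analysis import combine_effects

        theta = [-5.2, -4.1, -6.0]
        se = [0.9, 0.7, 1.1]
        got = dersimonian_laird_tau2(list(zip(theta, se)))
        res = combine_effects(np.array(theta), np.array(se) ** 2, method_re="dl")
        assert got == pytest.approx(res.tau2, rel=1e-8)

    def test_single_study_returns_zero(self):
        assert dersimonian_laird_tau2([(-3.0, 0.5)]) == 0.0


class TestMetaPool:
    def test_fixture_reproduces_printed_summary(self, historical):
        result = meta_pool(historical)
        assert result.tau2 == 0.0
        assert round(result.pooled.point, 4) == 0.0039
        assert round(result.pooled.lower, 5) == 0.00055
        assert round(result.pooled.upper, 5) == 0.02713

    def test_single_study_degenerates_to_its_own_estimate(self):
        result = meta_pool(make_set((1, 100)))
        p, theta, se = corrected_proportion(EventCount("s", 1, 100))
        assert result.theta_hat == pytest.approx(theta, rel=1e-12)
        assert result.se_theta_hat == pytest.approx(se, rel=1e-12)
        assert result.pooled.point == pytest.approx(p, rel=1e-12)

    def test_two_identical_studies_shrink_se(self):
        one = meta_pool(make_set((1, 100)))
        two = meta_pool(make_set((1, 100), (1, 100)))
        assert two.pooled.point == pytest.approx(one.pooled.point, rel=1e-12)
        assert two.se_theta_hat == pytest.approx(one.se_theta_hat / math.sqrt(2), rel=1e-12)

    def test_pooled_logit_within_study_range(self):
        result = meta_pool(make_set((3, 100), (2, 50), (0, 400)))
        thetas = [e.theta for e in result.per_study]
        assert min(thetas) <= result.theta_hat <= max(thetas)

    def test_matches_statsmodels_random_effects_pooling(self):
        from statsmodels.stats.meta_analysis import combine_effects

        # heterogeneous studies so that tau2 > 0 (statsmodels does not
        # truncate a negative moment estimate, so only this regime is
        # directly comparable)
        counts = [(30, 100), (2, 50), (4, 400)]
        result = meta_pool(make_set(*counts))
        assert result.tau2 > 0
        theta = [e.theta for e in result.per_study]
        var = [e.se**2 for e in result.per_study]
        res = combine_effects(np.array(theta), np.array(var), method_re="dl")
        frame = res.summary_frame()
        assert result.theta_hat == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-8
        )
        assert result.se_theta_hat == pytest.approx(
            frame.loc["random effect", "sd_eff"], rel=1e-8
        )


class TestMetaPrior:
    def test_fixture_prior_near_printed_values(self, historical):
        prior = meta_prior_for_wildtype(meta_pool(historical))
        assert prior.alpha == pytest.approx(0.74, rel=0.02)
        assert prior.beta == pytest.approx(113.57, rel=0.02)

    def test_prior_reproduces_pooled_targets(self, historical):
        result = meta_pool(historical)
        prior = meta_prior_for_wildtype(result)
        assert beta_quantile(prior, 0.5) == pytest.approx(result.pooled.point, rel=0.01)
        assert beta_quantile(prior, 0.975) == pytest.approx(result.pooled.upper, rel=0.01)

    def test_oracle_set_self_consistency(self):
        result = meta_pool(make_set((3, 100), (2, 50)))
        prior = meta_prior_for_wildtype(result)
        assert beta_quantile(prior, 0.975) == pytest.approx(result.pooled.upper, rel=0.02)
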