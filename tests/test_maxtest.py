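"""Joint covariance, equicoordinate quantile, and the maximum test."""

import numpy as np
import pytest
from scipy import stats as sps

from survmctp import (
    SurvivalData,
    default_weights,
    equicoordinate_quantile,
    log_rank_weight,
    make_contrasts,
    multiweightedlr_test,
    wlr_sigma,
    wlr_statistic,
)
from survmctp.contrasts import pairwise_contrasts
from survmctp.maxtest import joint_wlr, psd_repair_correlation
from .conftest import make_null_data


def equicorrelated(d, rho):
    R = np.full((d, d), rho)
    np.fill_diagonal(R, 1.0)
    return R


class TestEquicoordinateQuantile:
    def test_dimension_one_is_normal_quantile(self):
        assert equicoordinate_quantile(np.eye(1), 0.05) == pytest.approx(
            1.95996, abs=1e-3
        )

    def test_two_independent_closed_form(self):
        # (2 Phi(c) - 1)^2 = 0.95
        truth = sps.norm.ppf((1 + np.sqrt(0.95)) / 2)
        c = equicoordinate_quantile(np.eye(2), 0.05, seed=0)
        assert c == pytest.approx(truth, abs=1e-3)

    @pytest.mark.parametrize("d", [2, 5])
    def test_perfect_correlation_collapses_to_univariate(self, d):
        c = equicoordinate_quantile(np.ones((d, d)), 0.05, seed=0)
        assert c == pytest.approx(1.95996, abs=1e-3)

    def test_bonferroni_sandwich(self, rng):
        """z_{1-a/2} <= c <= z_{1-a/(2d)} for random correlation matrices."""
        for d in (3, 6):
            A = rng.normal(size=(d, d))
            R = A @ A.T
            s = np.sqrt(np.diag(R))
            R = R / np.outer(s, s)
            np.fill_diagonal(R, 1.0)
            c = equicoordinate_quantile(R, 0.05, seed=1)
            lo = sps.norm.ppf(1 - 0.05 / 2)
            hi = sps.norm.ppf(1 - 0.05 / (2 * d))
            assert lo - 2e-3 <= c <= hi + 2e-3

    def test_monotone_in_correlation(self):
        cs = [
            equicoordinate_quantile(equicorrelated(4, rho), 0.05, seed=2)
            for rho in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a >= b - 2e-3 for a, b in zip(cs, cs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="square"):
            equicoordinate_quantile(np.ones((2, 3)), 0.05)
        with pytest.raises(ValueError, match="unit diagonal"):
            equicoordinate_quantile(2 * np.eye(2), 0.05)


class TestJointCovariance:
    def test_disjoint_pairs_zero_block(self, rng):
        d = make_null_data(rng, k=4, n=30, censor_upper=2.0)
        cs = pairwise_contrasts([(0, 1), (2, 3)], 4)
        jw = joint_wlr(d, cs, default_weights())
        np.testing.assert_array_equal(jw.sigma[:2, 2:], 0.0)

    def test_k2_single_contrast_equals_pairwise_sigma(self, rng):
        d = make_null_data(rng, k=2, n=30, censor_upper=2.0)
        cs = make_contrasts("tukey", 2)
        jw = joint_wlr(d, cs, default_weights())
        np.testing.assert_array_equal(
            jw.sigma, wlr_sigma(d, (0, 1), default_weights())
        )

    def test_diagonal_blocks_bitmatch_pairwise(self, rng):
        d = make_null_data(rng, k=4, n=25, censor_upper=2.0)
        cs = make_contrasts("tukey", 4)
        jw = joint_wlr(d, cs, default_weights())
        m = 2
        for a, pair in enumerate(cs.pairs):
            np.testing.assert_array_equal(
                jw.sigma[a * m : (a + 1) * m, a * m : (a + 1) * m],
                wlr_sigma(d, pair, default_weights()),
            )

    def test_shared_group_block_signs(self, rng):
        """Contrasts (1,2) and (1,3) share group 1 with equal signs, so the
        log-rank/log-rank cross entry is positive on null data."""
        d = make_null_data(rng, k=3, n=60, censor_upper=2.0)
        cs = make_contrasts("dunnett", 3)
        jw = joint_wlr(d, cs, (log_rank_weight(),))
        assert jw.sigma[0, 1] > 0


class TestPsdRepair:
    def test_repair_clips_and_rescales(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = psd_repair_correlation(R)
        np.testing.assert_allclose(np.diag(fixed), 1.0)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10

    def test_psd_input_untouched(self):
        R = equicorrelated(3, 0.4)
        np.testing.assert_array_equal(psd_repair_correlation(R), R)


class TestMultiWeightedLR:
    def test_identical_groups_never_rejects(self, rng):
        t = rng.exponential(1.0, 15)
        d = SurvivalData.from_arrays(
            np.tile(t, 3), np.ones(45, int), np.repeat([1, 2, 3], 15)
        )
        res = multiweightedlr_test(d, make_contrasts("tukey", 3), seed=0)
        np.testing.assert_allclose(res.statistics, 0.0, atol=1e-10)
        assert not res.reject_global

    def test_single_contrast_single_weight_reduces_to_logrank(self, rng):
        d = make_null_data(rng, k=2, n=40, censor_upper=2.0)
        cs = make_contrasts("tukey", 2)
        res = multiweightedlr_test(d, cs, weights=(log_rank_weight(),), seed=0)
        t = wlr_statistic(d, (0, 1), log_rank_weight())
        s = wlr_sigma(d, (0, 1), (log_rank_weight(),))[0, 0]
        assert res.statistics[0] == pytest.approx(abs(t) / np.sqrt(s))
        assert res.critical_value == pytest.approx(sps.norm.ppf(0.975), abs=2e-3)
        # two-sided standardized log-rank decision at level alpha
        assert res.reject_local[0] == (abs(t) / np.sqrt(s) > res.critical_value)

    def test_zero_variance_coordinate_dropped_with_warning(self, rng):
        t = rng.exponential(1.0, 10)
        time = np.concatenate([t, t, rng.exponential(1.0, 10)])
        status = np.concatenate([np.zeros(20, int), np.ones(10, int)])
        d = SurvivalData.from_arrays(time, status, np.repeat([1, 2, 3], 10))
        cs = pairwise_contrasts([(0, 1), (0, 2)], 3)
        with pytest.warns(UserWarning, match="zero estimated"):
            res = multiweightedlr_test(d, cs, seed=0)
        assert res.pvalues[0] == 1.0 and not res.reject_local[0]

    def test_null_fwer_controlled_small_study(self):
        """Global null (four identical exponential groups, n=100): the
        maximum test — the most conservative procedure here — keeps the
        family-wise error rate at or below nominal within Monte-Carlo
        error, at smoke scale."""
        from survmctp import run_study, scenario

        s = scenario("null", n=100, censoring=0.2, contrast_kind="dunnett")
        rep = run_study(s, methods=["multiweightedlr"], runs=60, master_seed=17)
        assert rep.fwer["multiweightedlr"] <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_adjusted_pvalues_consistent_with_decisions(self, rng):
        d = make_null_data(rng, k=3, n=40, censor_upper=2.0)
        res = multiweightedlr_test(d, make_contrasts("dunnett", 3), seed=3)
        assert np.all((res.pvalues > 0) & (res.pvalues <= 1))
        # p < alpha should track statistic > c up to quantile tolerance
        for p, t, r in zip(res.pvalues, res.statistics, res.reject_local):
            if abs(t - res.critical_value) > 0.02:
                assert (p < res.alpha) == r
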