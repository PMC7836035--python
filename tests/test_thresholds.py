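"""GCLT, small-eps and worst-case (RRA) thresholds and the inverse maps."""

import math

import numpy as np
import pytest

from gmpcomb import (
    bonferroni,
    fisher,
    fpr_under_independence,
    fpr_worst_case,
    gclt_coefficients,
    gclt_threshold,
    rra_multiplier,
    rra_threshold,
    sidak,
    simes,
    small_eps_threshold,
)
from gmpcomb.gmp_core import gmp_rows


class TestGcltCoefficients:
    def test_harmonic_mean_row(self):
        c = gclt_coefficients(-1.0, 1000)
        assert c.a == pytest.approx(1000 * math.log(1000), rel=1e-12)  # 6907.755
        assert c.b == pytest.approx(math.pi / 2 * 1000, rel=1e-12)  # 1570.796
        assert c.lam == 1.0

    def test_arithmetic_mean_row(self):
        c = gclt_coefficients(1.0, 1000)
        assert c.a == pytest.approx(500.0)
        assert c.b == pytest.approx(math.sqrt(1000.0 / 24.0), rel=1e-12)  # 6.45497

    def test_r_minus_two_constant_is_half_pi(self):
        # [(2/pi) Gamma(1/2) sin(pi/4)]^{-2} = [sqrt(2/pi)]^{-2} = pi/2
        c = gclt_coefficients(-2.0, 100)
        assert c.a == 0.0
        assert c.C == pytest.approx(math.pi / 2, rel=1e-12)
        assert c.b == pytest.approx(math.pi / 2 * 100**2, rel=1e-12)

    @pytest.mark.parametrize("r", [-3.0, -1.0, -0.75, -0.5, -0.25, 1.0])
    def test_c_is_normalized_scaling(self, r):
        K = 250
        c = gclt_coefficients(r, K)
        assert c.C == pytest.approx(c.b / K ** max(0.5, -r), rel=1e-12)

    def test_rejects_r_zero(self):
        with pytest.raises(ValueError):
            gclt_coefficients(0.0, 100)


class TestGcltThreshold:
    def test_arithmetic_mean_example(self):
        # (500 + sqrt(1000/24) * sqrt(2) * Phi^{-1}(0.01)) / 1000
        res = gclt_threshold(1.0, 1000, 0.01)
        assert res.psi == pytest.approx(0.47876, abs=5e-6)

    def test_hmp_threshold_approaches_eps(self):
        # the harmonic mean p-value is directly interpretable as eps -> 0
        ratios = [gclt_threshold(-1.0, 1000, e).psi / e for e in (1e-3, 1e-4, 1e-6)]
        devs = [abs(x - 1) for x in ratios]
        assert devs[0] < 0.01
        assert devs[1] < devs[0]
        assert devs[2] < 1e-4

    def test_monte_carlo_oracle_r_minus_two(self, rng):
        # empirical 0.05-quantile of M_{-2,1000} under independent uniforms
        r, K, eps, n = -2.0, 1000, 0.05, 100_000
        psi = gclt_threshold(r, K, eps).psi
        hits = 0
        for _ in range(10):
            p = rng.uniform(size=(n // 10, K))
            hits += int((gmp_rows(p, r) <= psi).sum())
        mcse = math.sqrt(eps * (1 - eps) / n)
        assert hits / n == pytest.approx(eps, abs=4 * mcse)

    def test_lambda_clamp_equals_normal_construction(self):
        # for -1/2 < r < 0 the construction is the plain CLT with Normal(0,2)
        from scipy.stats import norm

        r, K, eps = -0.25, 1000, 0.05
        c = gclt_coefficients(r, K)
        manual = ((c.a + c.b * math.sqrt(2) * norm.ppf(1 - eps)) / K) ** (1 / r)
        assert gclt_threshold(r, K, eps).psi == manual

    def test_psi_increasing_in_eps(self):
        psis = [gclt_threshold(-1.5, 500, e).psi for e in (0.001, 0.01, 0.05, 0.1)]
        assert psis == sorted(psis)

    def test_warns_for_large_eps(self):
        with pytest.warns(UserWarning, match="degrade"):
            gclt_threshold(-3.0, 300, 0.25)

    def test_rejects_r_zero_and_bad_eps(self):
        with pytest.raises(ValueError, match="Fisher"):
            gclt_threshold(0.0, 100, 0.05)
        with pytest.raises(ValueError):
            gclt_threshold(-1.0, 100, 0.0)


class TestSmallEpsAndRra:
    def test_small_eps_closed_forms(self):
        assert small_eps_threshold(-1.0, 50, 0.037).psi == pytest.approx(0.037)
        assert small_eps_threshold(-1.0, 5000, 0.037).psi == pytest.approx(0.037)
        assert small_eps_threshold(-2.0, 100, 0.005).psi == pytest.approx(5e-4)

    def test_small_eps_bonferroni_limit(self):
        assert small_eps_threshold(-1e6, 1000, 0.05).psi == pytest.approx(
            5e-5, rel=1e-4
        )

    def test_small_eps_refuses_light_tails(self):
        for r in (-0.5, -0.4, 0.5):
            with pytest.raises(ValueError):
                small_eps_threshold(r, 100, 0.05)

    def test_rra_closed_forms(self):
        assert rra_threshold(-1.0, 1000, 0.05).psi == pytest.approx(
            0.05 / math.log(1000), rel=1e-12
        )  # 0.0072382
        assert rra_threshold(1.0, 77, 0.05).psi == pytest.approx(0.025)
        assert rra_threshold(-2.0, 100, 0.01).psi == pytest.approx(5e-4, rel=1e-12)

    def test_rra_geometric_mean_multiplier_is_inv_e(self):
        assert rra_multiplier(0.0, 100) == pytest.approx(1 / math.e)
        # continuous limit from either side
        assert rra_multiplier(1e-9, 100) == pytest.approx(1 / math.e, rel=1e-6)

    def test_small_eps_convergence_of_full_threshold(self):
        # the full GCLT construction approaches the closed form as eps -> 0
        for r in (-2.0, -1.0):
            ratio = (
                gclt_threshold(r, 1000, 1e-6).psi
                / small_eps_threshold(r, 1000, 1e-6).psi
            )
            assert ratio == pytest.approx(1.0, abs=1e-4)

    def test_rra_more_stringent_for_heavy_tails(self):
        for r in (-10.0, -2.0, -1.25, -1.0):
            for K in (100, 1000):
                for eps in (0.01, 0.05):
                    assert (
                        rra_threshold(r, K, eps).psi <= gclt_threshold(r, K, eps).psi
                    )

    def test_two_fold_gap_at_r_minus_two(self):
        for K in (10, 100, 1000):
            for eps in (0.001, 0.01, 0.05):
                ratio = (
                    small_eps_threshold(-2.0, K, eps).psi
                    / rra_threshold(-2.0, K, eps).psi
                )
                assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_sidak_bonferroni_limits(self):
        K, r = 1000, -1e6
        for eps in (0.01, 0.05):
            sidak_thr = 1 - (1 - eps) ** (1 / K)
            assert gclt_threshold(r, K, eps).psi == pytest.approx(
                sidak_thr, rel=1e-3
            )
            assert rra_threshold(r, K, eps).psi == pytest.approx(eps / K, rel=1e-3)


class TestInverseMaps:
    @pytest.mark.parametrize("r", [-2.0, -1.25, -1.0, -0.75, -0.25, 1.0, 2.0])
    @pytest.mark.parametrize("eps", [0.01, 0.05])
    def test_round_trip(self, r, eps):
        t = gclt_threshold(r, 1000, eps).psi
        assert fpr_under_independence(t, r, 1000) == pytest.approx(eps, rel=1e-6)

    def test_rra_is_conservative_under_independence(self):
        t = rra_threshold(-1.0, 1000, 0.01).psi
        assert fpr_under_independence(t, -1.0, 1000) < 0.01

    def test_rra_gclt_agree_for_very_negative_r(self):
        t = rra_threshold(-10.0, 1000, 0.01).psi
        assert fpr_under_independence(t, -10.0, 1000) == pytest.approx(0.01, rel=0.15)

    def test_worst_case_inverts_rra_exactly(self):
        t = rra_threshold(-1.5, 1000, 0.02).psi
        assert fpr_worst_case(t, -1.5, 1000) == pytest.approx(0.02, rel=1e-12)

    def test_worst_case_amp(self):
        # direct use of the AMP's GCLT threshold is badly anti-conservative
        t = gclt_threshold(1.0, 1000, 0.01)
        assert fpr_worst_case(t, 1.0, 1000) == pytest.approx(0.96, abs=0.005)

    def test_worst_case_hmp_sixfold(self):
        t = gclt_threshold(-1.0, 1000, 0.01)
        fold = fpr_worst_case(t, -1.0, 1000) / 0.01
        assert fold == pytest.approx(6.2, abs=0.05)

    def test_cap_at_one(self):
        assert fpr_worst_case(0.9, 1.0, 10) == 1.0


class TestComparators:
    def test_simes_by_brute_force(self):
        d = simes([0.01, 0.04, 0.05], 0.05)
        assert d.statistic == pytest.approx(min(3 * 0.01 / 1, 3 * 0.04 / 2, 3 * 0.05 / 3))
        assert d.reject

    def test_fisher_closed_form(self):
        d = fisher([0.05, 0.05], 0.05)
        stat = -4 * math.log(0.05)
        assert d.statistic == pytest.approx(stat, rel=1e-12)
        # chi-squared(4) survival: exp(-x/2) (1 + x/2)
        assert d.combined_p == pytest.approx(
            math.exp(-stat / 2) * (1 + stat / 2), rel=1e-10
        )
        assert d.reject

    def test_bonferroni_per_test_threshold(self):
        d = bonferroni([0.5] * 1000, 0.05)
        assert d.threshold == pytest.approx(5e-5)
        assert not d.reject

    def test_sidak_threshold(self):
        d = sidak([1e-5] + [0.5] * 9, 0.05)
        assert d.threshold == pytest.approx(1 - 0.95 ** (1 / 10))
        assert d.reject
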