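import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actimr.errors import DomainError, EmptyInputError, InsufficientVariantsError
from actimr.mr_estimators import (
    RatioEstimate,
    cochran_q,
    ivw,
    mr_egger,
    scale_to_sd,
    subgroup_heterogeneity,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)

from conftest import make_harmonised


def ratios_from(thetas, ses):
    return [
        RatioEstimate(rsid=f"rs{i}", theta=t, se_theta=s)
        for i, (t, s) in enumerate(zip(thetas, ses))
    ]


class TestWaldRatios:
    def test_forced_arithmetic(self):
        h = make_harmonised([0.03], [0.005], [-0.021], [0.012])
        (r,) = wald_ratios(h)
        assert r.theta == pytest.approx(-0.7)
        assert r.se_theta == pytest.approx(0.4)
        assert r.weight == pytest.approx(1 / 0.4**2, rel=1e-12)

    def test_sign_consistency(self):
        h = make_harmonised([-0.03], [0.005], [0.021], [0.012])
        (r,) = wald_ratios(h)
        assert r.theta == pytest.approx(-0.7)
        assert r.se_theta == pytest.approx(0.4)

    def test_zero_exposure_beta_excluded(self):
        h = make_harmonised([0.03, 0.0], [0.005, 0.005], [0.01, 0.01], [0.01, 0.01])
        with pytest.warns(UserWarning, match="excluded"):
            ratios = wald_ratios(h)
        assert len(ratios) == 1


class TestIvw:
    def test_hand_computed_fixed(self):
        res = ivw(ratios_from([0.5, 1.0], [0.1, 0.2]), effects="fixed")
        assert res.beta == pytest.approx(0.6)
        assert res.se == pytest.approx(0.089443, abs=1e-6)
        assert res.or_ == pytest.approx(math.exp(0.6), rel=1e-12)
        assert res.ci_low < res.or_ < res.ci_high

    def test_homogeneous_ratios(self):
        res_f = ivw(ratios_from([0.3] * 4, [0.1, 0.2, 0.3, 0.4]), effects="fixed")
        res_r = ivw(ratios_from([0.3] * 4, [0.1, 0.2, 0.3, 0.4]), effects="random")
        assert res_f.beta == pytest.approx(0.3)
        assert res_f.q_stat == pytest.approx(0.0, abs=1e-20)
        assert res_r.se == res_f.se  # inflation floored at 1

    def test_single_ratio_degenerate(self):
        res = ivw(ratios_from([0.4], [0.1]))
        assert res.degenerate
        assert res.beta == 0.4
        assert res.se == 0.1

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            ivw([])

    def test_auto_switches_to_random(self):
        het = ratios_from([-5.0, 5.0, 0.0], [0.1, 0.1, 0.1])
        res = ivw(het, effects="auto")
        assert res.effects_model == "random"
        assert res.se > ivw(het, effects="fixed").se
        hom = ratios_from([0.1, 0.12, 0.11], [0.1, 0.1, 0.1])
        assert ivw(hom, effects="auto").effects_model == "fixed"

    def test_equals_origin_wls_slope(self, rng):
        """Oracle: fixed IVW == weighted least squares through the origin."""
        for _ in range(20):
            j = rng.integers(2, 12)
            bx = rng.normal(0.1, 0.05, j)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(0, 0.1, j)
            sy = rng.uniform(0.01, 0.2, j)
            h = make_harmonised(bx, np.full(j, 0.005), by, sy)
            res = ivw(wald_ratios(h), effects="fixed")
            w = 1 / sy**2
            slope = np.sum(w * bx * by) / np.sum(w * bx**2)
            assert res.beta == pytest.approx(slope, rel=1e-10)

    def test_permutation_invariance(self, rng):
        th = rng.normal(0, 1, 8)
        se = rng.uniform(0.05, 0.3, 8)
        base = ivw(ratios_from(th, se))
        perm = rng.permutation(8)
        shuffled = ivw(ratios_from(th[perm], se[perm]))
        assert shuffled.beta == pytest.approx(base.beta, abs=1e-12)
        assert shuffled.se == pytest.approx(base.se, abs=1e-12)


class TestCochranQ:
    def test_hand_computed(self):
        q, df, p, i2 = cochran_q(ratios_from([0.0, 1.0], [1.0, 1.0]))
        assert q == pytest.approx(0.5)
        assert df == 1
        assert i2 == 0.0  # Q < df

    def test_identical(self):
        q, _, _, i2 = cochran_q(ratios_from([0.7, 0.7, 0.7], [0.1, 0.1, 0.1]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0

    def test_extreme_heterogeneity(self):
        # Q = 100*25 + 100*25 = 5000
        q, df, p, i2 = cochran_q(ratios_from([-5.0, 5.0], [0.1, 0.1]))
        assert q == pytest.approx(5000.0)
        assert i2 > 99.0

    def test_too_few(self):
        with pytest.raises(InsufficientVariantsError):
            cochran_q(ratios_from([0.1], [0.1]))


class TestMrEgger:
    def test_exact_line(self):
        h = make_harmonised(
            [1.0, 2.0, 3.0], [0.01] * 3, [0.6, 1.1, 1.6], [0.1] * 3
        )
        res = mr_egger(h)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_line_through_origin(self):
        h = make_harmonised(
            [1.0, 2.0, 3.0, 4.0], [0.01] * 4, [0.5, 1.0, 1.5, 2.0], [0.1] * 4
        )
        res = mr_egger(h)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-10)
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_equals_ivw_when_intercept_zero(self):
        # balanced design around the weighted centroid => fitted intercept 0
        h = make_harmonised(
            [1.0, 2.0, 3.0], [0.01] * 3, [0.5, 1.0, 1.5], [0.1] * 3
        )
        egger = mr_egger(h)
        fixed = ivw(wald_ratios(h), effects="fixed")
        assert egger.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert egger.beta == pytest.approx(fixed.beta, abs=1e-10)

    def test_orientation_invariance(self):
        """Flipping a SNP's alleles (both betas negated) changes nothing."""
        h1 = make_harmonised(
            [0.1, 0.2, 0.3, 0.15], [0.01] * 4, [0.06, 0.13, 0.14, 0.1], [0.05] * 4
        )
        h2 = make_harmonised(
            [-0.1, 0.2, 0.3, 0.15], [0.01] * 4, [-0.06, 0.13, 0.14, 0.1], [0.05] * 4
        )
        r1, r2 = mr_egger(h1), mr_egger(h2)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-12)
        assert r1.egger_intercept == pytest.approx(r2.egger_intercept, abs=1e-12)

    def test_too_few_variants(self):
        h = make_harmonised([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(InsufficientVariantsError):
            mr_egger(h)

    def test_constant_exposure_unidentifiable(self):
        h = make_harmonised([0.1] * 3, [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(DomainError, match="unidentifiable"):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weight_is_ordinary_median(self):
        assert weighted_median_point(
            np.array([0.2, 0.5, 0.9]), np.array([1.0, 1.0, 1.0])
        ) == pytest.approx(0.5)

    def test_interpolated_derived_value(self):
        # s = {0.125, 0.375, 0.75}; interpolate at 0.5 -> 2 + (0.125/0.375)*8
        got = weighted_median_point(np.array([1.0, 2.0, 10.0]), np.array([1.0, 1.0, 2.0]))
        assert got == pytest.approx(2 + (0.5 - 0.375) / (0.75 - 0.375) * 8)
        assert got == pytest.approx(14 / 3)

    def test_weight_concentration(self):
        h = make_harmonised(
            [0.1, 0.1, 0.1], [0.001] * 3, [0.02, 0.09, 0.05], [1.0, 1.0, 0.001]
        )
        res = weighted_median(h, n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.5, abs=1e-3)

    def test_within_ratio_range(self, rng):
        for _ in range(10):
            j = int(rng.integers(3, 10))
            bx = rng.uniform(0.05, 0.3, j)
            by = rng.normal(0, 0.1, j)
            sy = rng.uniform(0.02, 0.2, j)
            h = make_harmonised(bx, np.full(j, 0.005), by, sy)
            res = weighted_median(h, n_boot=50, seed=7)
            th = by / bx
            assert th.min() - 1e-12 <= res.beta <= th.max() + 1e-12

    def test_seed_reproducible(self):
        h = make_harmonised(
            [0.1, 0.2, 0.3, 0.15], [0.01] * 4, [0.06, 0.13, 0.14, 0.1], [0.05] * 4
        )
        r1 = weighted_median(h, n_boot=500, seed=42)
        r2 = weighted_median(h, n_boot=500, seed=42)
        assert r1.se == r2.se
        r3 = weighted_median(h, n_boot=500, seed=43)
        assert r3.se != r1.se

    def test_too_few(self):
        h = make_harmonised([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(InsufficientVariantsError):
            weighted_median(h)


class TestScaleToSd:
    def test_forced_arithmetic(self):
        base = ivw(ratios_from([-0.05, -0.05], [0.02, 0.02]))
        scaled = scale_to_sd(base, 8.14)
        assert scaled.beta == pytest.approx(-0.407)
        assert scaled.se == pytest.approx(base.se * 8.14)

    def test_identity(self):
        base = ivw(ratios_from([0.5, 1.0], [0.1, 0.2]))
        same = scale_to_sd(base, 1.0)
        assert same.beta == base.beta
        assert same.or_ == base.or_

    def test_or_consistent(self):
        base = ivw(ratios_from([-0.05, -0.04], [0.02, 0.02]))
        scaled = scale_to_sd(base, 8.14)
        assert scaled.or_ == pytest.approx(math.exp(scaled.beta), rel=1e-12)
        assert scaled.pvalue == pytest.approx(base.pvalue, rel=1e-12)

    def test_domain(self):
        base = ivw(ratios_from([0.5, 1.0], [0.1, 0.2]))
        with pytest.raises(DomainError):
            scale_to_sd(base, 0.0)


class TestSubgroupHeterogeneity:
    def test_sex_contrast_i2_zero(self):
        # men OR 0.79 (0.50-1.23) vs women OR 0.57 (0.36-0.90)
        het = subgroup_heterogeneity([(0.79, 0.50, 1.23), (0.57, 0.36, 0.90)])
        assert het.i2_percent == 0.0
        assert het.df == 1

    def test_identical_estimates(self):
        het = subgroup_heterogeneity([(0.7, 0.5, 0.98), (0.7, 0.5, 0.98)])
        assert het.q_stat == pytest.approx(0.0, abs=1e-20)
        assert het.i2_percent == 0.0

    def test_er_subtype_contrast_vs_oracle(self):
        """Brute-force two-group fixed-effects Q recomputation."""
        groups = [(0.45, 0.20, 1.01), (0.95, 0.44, 2.04)]
        betas = [math.log(g[0]) for g in groups]
        ses = [(math.log(g[2]) - math.log(g[1])) / (2 * 1.96) for g in groups]
        w = [1 / s**2 for s in ses]
        pooled = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
        q_oracle = sum(wi * (bi - pooled) ** 2 for wi, bi in zip(w, betas))
        het = subgroup_heterogeneity(groups)
        assert het.q_stat == pytest.approx(q_oracle, rel=1e-12)
        assert het.i2_percent == pytest.approx(max(0, (q_oracle - 1) / q_oracle) * 100)

    def test_accepts_beta_se_pairs(self):
        a = subgroup_heterogeneity([(-0.2, 0.1), (-0.5, 0.2)])
        b = subgroup_heterogeneity(
            [(math.exp(-0.2), math.exp(-0.2 - 1.96 * 0.1), math.exp(-0.2 + 1.96 * 0.1)),
             (math.exp(-0.5), math.exp(-0.5 - 1.96 * 0.2), math.exp(-0.5 + 1.96 * 0.2))]
        )
        assert a.q_stat == pytest.approx(b.q_stat, rel=1e-9)

    def test_too_few(self):
        with pytest.raises(InsufficientVariantsError):
            subgroup_heterogeneity([(0.5, 0.3, 0.8)])
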