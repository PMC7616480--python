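"""Method-agreement battery: MAPE, CCC, Bland-Altman, Passing-Bablok, TOST."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.weightstats import ttost_paired

from bisffm.agreement import (
    bland_altman,
    ccc,
    evaluate_agreement,
    mape,
    passing_bablok,
    percent_of_mean,
    tost,
)

paired_arrays = st.integers(10, 60).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(8.0, 16.0), min_size=n, max_size=n),
        st.lists(st.floats(8.0, 16.0), min_size=n, max_size=n),
    )
)


class TestMape:
    def test_identical_arrays_give_zero(self, rng):
        x = rng.uniform(9, 14, 40)
        assert mape(x, x) == 0.0

    def test_uniform_ten_percent_overestimate(self, rng):
        x = rng.uniform(9, 14, 40)
        assert mape(1.1 * x, x) == pytest.approx(10.0, rel=1e-10)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0, 2.0, 3.0], [1.0, 0.0, 3.0])

    def test_half_normal_analytic_limit(self, rng):
        """Gaussian errors of SD sigma around a constant reference give
        MAPE -> 100*sigma*sqrt(2/pi)/ref as n grows."""
        sigma, ref, n = 0.39, 11.4, 200_000
        pred = ref + rng.normal(0, sigma, n)
        limit = 100 * sigma * np.sqrt(2 / np.pi) / ref
        assert mape(pred, np.full(n, ref)) == pytest.approx(limit, rel=0.02)


class TestCcc:
    def test_perfect_agreement(self, rng):
        x = rng.uniform(9, 14, 30)
        val, lo, hi = ccc(x, x)
        assert val == 1.0 and lo == 1.0 and hi == 1.0

    def test_location_shift_penalized_below_pearson(self, rng):
        x = rng.uniform(9, 14, 50)
        val, _, _ = ccc(x + 0.8, x)
        assert val < 1.0  # pearson r of the shifted pair is exactly 1

    def test_six_point_fixture_matches_direct_formula_oracle(self):
        # frozen from a hand evaluation of Lin's formula on this fixture
        x = [10.2, 11.5, 9.8, 12.1, 10.9, 11.7]
        y = [10.5, 11.2, 10.1, 12.5, 10.6, 11.9]
        val, lo, hi = ccc(y, x)
        assert val == pytest.approx(0.9325842696629212, rel=1e-12)
        assert lo < val < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ccc(np.full(10, 3.0), np.arange(10.0))

    def test_equal_moments_make_ccc_equal_pearson(self, rng):
        # same mean and variance: the penalty term vanishes
        x = rng.normal(0, 1, 2000)
        x = (x - x.mean()) / x.std()
        y = rng.normal(0, 1, 2000)
        y = (y - y.mean()) / y.std()
        val, _, _ = ccc(x, y)
        pearson = float(np.corrcoef(x, y)[0, 1])
        assert val == pytest.approx(pearson, abs=1e-12)


class TestBlandAltman:
    def test_identical_arrays(self, rng):
        x = rng.uniform(9, 14, 30)
        ba = bland_altman(x, x)
        assert ba.bias == 0 and ba.sd == 0
        assert ba.loa_low == 0 and ba.loa_high == 0

    def test_pure_constant_shift(self, rng):
        x = rng.uniform(9, 14, 30)
        ba = bland_altman(x + 0.5, x)
        assert ba.bias == pytest.approx(0.5, rel=1e-12)
        assert ba.sd == pytest.approx(0.0, abs=1e-12)
        assert ba.proportional_bias_p == 1.0  # no proportional bias

    def test_loa_arithmetic_reproduces_published_rounding(self):
        # bias -0.43, SD 0.63 -> LOA (-1.66, 0.80); published (-1.65, 0.79)
        # comes from unrounded inputs, so agreement is within one rounding step
        bias, sd = -0.43, 0.63
        assert bias - 1.96 * sd == pytest.approx(-1.65, abs=0.02)
        assert bias + 1.96 * sd == pytest.approx(0.79, abs=0.02)

    @given(data=paired_arrays)
    def test_loa_identity_exact(self, data):
        p, r = map(np.asarray, data)
        ba = bland_altman(p, r)
        assert ba.loa_low == ba.bias - 1.96 * ba.sd
        assert ba.loa_high == ba.bias + 1.96 * ba.sd

    def test_proportional_bias_detected_when_present(self, rng):
        ref = rng.uniform(9, 14, 200)
        pred = ref + 0.4 * (ref - ref.mean())  # error grows with size
        ba = bland_altman(pred, ref)
        assert ba.proportional_bias_p < 1e-6

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestPassingBablok:
    def test_identity_line(self, rng):
        x = rng.uniform(9, 14, 20)
        pb = passing_bablok(x, x)
        assert pb.slope == pytest.approx(1.0, abs=1e-12)
        assert pb.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_relation(self, rng):
        x = rng.uniform(9, 14, 20)
        pb = passing_bablok(2 * x + 1, x)
        assert pb.slope == pytest.approx(2.0, abs=1e-12)
        assert pb.intercept == pytest.approx(1.0, abs=1e-10)

    def test_twelve_point_fixture_matches_enumeration_oracle(self):
        # frozen from a brute-force enumeration of all pairwise slopes with
        # the -1 exclusion and shift rule (65 valid slopes, K = 0)
        x = [8.7, 9.4, 10.1, 10.6, 11.0, 11.3, 11.8, 12.2, 12.6, 13.1, 13.7, 14.2]
        y = [9.1, 9.2, 10.6, 10.4, 11.5, 11.2, 12.3, 12.0, 13.1, 13.4, 13.6, 14.9]
        pb = passing_bablok(y, x)
        assert pb.slope == pytest.approx(1.0256410256410255, rel=1e-12)
        assert pb.intercept == pytest.approx(0.07051282051282204, rel=1e-9)
        assert pb.slope_ci[0] == pytest.approx(0.9, rel=1e-12)
        assert pb.slope_ci[1] == pytest.approx(1.2, rel=1e-12)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.uniform(9, 14, 25)
        y = 1.3 * x + rng.normal(0, 0.05, 25)
        forward = passing_bablok(y, x)
        backward = passing_bablok(x, y)
        assert backward.slope == pytest.approx(1 / forward.slope, rel=0.05)

    def test_scale_equivariance(self, rng):
        x = rng.uniform(9, 14, 25)
        y = x + rng.normal(0, 0.3, 25)
        pb = passing_bablok(y, x)
        pb_scaled = passing_bablok(10 * y, 10 * x)
        assert pb_scaled.slope == pytest.approx(pb.slope, rel=1e-12)
        assert pb_scaled.intercept == pytest.approx(10 * pb.intercept, rel=1e-9)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            passing_bablok(np.arange(10.0), np.full(10, 5.0))


class TestTost:
    def test_all_zero_differences_equivalent(self, rng):
        x = rng.uniform(9, 14, 20)
        p, ci, equivalent = tost(x, x, bound=0.25)
        assert equivalent and p == 0.0
        assert ci == (0.0, 0.0)

    def test_zero_variance_outside_bound_not_equivalent(self, rng):
        x = rng.uniform(9, 14, 20)
        p, _, equivalent = tost(x + 0.3, x, bound=0.25)
        assert not equivalent and p == 1.0

    def test_point_estimate_outside_bound_never_equivalent(self, rng):
        x = rng.uniform(9, 14, 20)
        pred = x + 0.26 + rng.normal(0, 0.4, 20)
        if abs(np.mean(pred - x)) > 0.25:  # holds for this seed
            p, _, equivalent = tost(pred, x, bound=0.25)
            assert p > 0.5 and not equivalent

    def test_small_bias_tight_ci_equivalent(self, rng):
        # mirrors a -0.04 kg bias with a (-0.21, 0.13) 90% CI at bound 0.25
        x = rng.uniform(9, 14, 20)
        pred = x - 0.04 + rng.normal(0, 0.45, 20)
        p, ci, equivalent = tost(pred, x, bound=0.25)
        assert (ci[0] > -0.25 and ci[1] < 0.25) == equivalent

    @given(data=paired_arrays, bound=st.floats(0.05, 0.5))
    def test_decision_equals_ci_inclusion_rule(self, data, bound):
        p, r = map(np.asarray, data)
        if np.std(p - r, ddof=1) == 0:
            return
        pval, ci, equivalent = tost(p, r, bound=bound)
        assert equivalent == (ci[0] > -bound and ci[1] < bound)
        assert equivalent == (pval < 0.05)

    def test_p_value_cross_checked_against_statsmodels(self, rng):
        x = rng.uniform(9, 14, 25)
        pred = x + rng.normal(0.05, 0.2, 25)
        p, _, _ = tost(pred, x, bound=0.25)
        p_sm, _, _ = ttost_paired(pred, x, -0.25, 0.25)
        assert p == pytest.approx(p_sm, rel=1e-10)

    def test_nonpositive_bound_rejected(self, rng):
        x = rng.uniform(9, 14, 10)
        with pytest.raises(ValueError):
            tost(x, x, bound=0.0)


class TestPercentOfMean:
    @pytest.mark.parametrize(
        "value,expected",
        [(-0.43, -3.8), (-2.05, -18.0), (0.74, 6.5), (0.0, 0.0)],
    )
    def test_table_footnote_percentages(self, value, expected):
        assert round(percent_of_mean(value, 11.4), 1) == expected

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_of_mean(1.0, 0.0)


class TestEvaluateAgreement:
    def test_report_internally_consistent(self, rng):
        ref = rng.uniform(9, 14, 40)
        pred = ref + rng.normal(0.1, 0.3, 40)
        rep = evaluate_agreement(pred, ref, tost_bound=0.25)
        assert rep.n == 40
        assert rep.loa_low_kg == rep.bias_kg - 1.96 * rep.sd_diff_kg
        assert rep.loa_high_kg == rep.bias_kg + 1.96 * rep.sd_diff_kg
        assert abs(rep.ccc) <= abs(rep.pearson_r) + 1e-12
        assert rep.ccc_ci[0] <= rep.ccc <= rep.ccc_ci[1]
        assert rep.mape_pct >= 0
        assert rep.bias_pct_of_mean == pytest.approx(
            100 * rep.bias_kg / ref.mean(), rel=1e-12
        )

    def test_explicit_cohort_mean_scales_percentages(self, rng):
        ref = rng.uniform(9, 14, 40)
        pred = ref + 0.5
        rep = evaluate_agreement(pred, ref, mean_reference=11.4)
        assert rep.bias_pct_of_mean == pytest.approx(100 * 0.5 / 11.4, rel=1e-9)
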