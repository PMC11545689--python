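"""Unit and property tests of the flexit* sex-ratio curve."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsdnorm import FlexitParams, SexCountRecord, loglik_counts, qbt, sex_ratio, trt_limits
from tsdnorm.tsd_curve import EmptyDataError


# hypothesis strategy for well-behaved curve parameters: the limb-slope
# ratio S2/S1 is kept in [1/2, 2] (extreme negative asymmetry makes the QBT
# blend ripple) and both slopes below s_max so the TRT limits sit outside
# the QBT blending zone
def flexit_strategy(s_max=5.0):
    def make(P, S, ratio):
        return FlexitParams(P=P, S=S, deltaS=S * (ratio - 1.0))

    return st.builds(
        make,
        P=st.floats(25.0, 34.0),
        S=st.floats(0.1, s_max / 2.0),
        ratio=st.floats(0.5, 2.0),
    )


class TestQbt:
    def test_pivot_value_is_exactly_half(self):
        for P in (25.0, 29.5, 33.2):
            assert qbt(P, P) == 0.5

    def test_limits_and_closed_form(self):
        assert qbt(29.5, 35.0) == pytest.approx(1.0, abs=1e-15)
        assert qbt(29.5, 24.0) == pytest.approx(0.0, abs=1e-15)
        # one step of 0.01 degC below the pivot: (1 + e)^-1
        assert qbt(29.5, 29.49) == pytest.approx(1.0 / (1.0 + math.e), rel=1e-9)

    def test_switches_within_a_tenth_of_a_degree(self):
        assert qbt(29.5, 29.61) > 1.0 - 1e-4
        assert qbt(29.5, 29.39) < 1e-4

    def test_no_overflow_far_from_pivot(self):
        assert qbt(29.5, 129.5) == 1.0
        assert qbt(29.5, -70.5) == 0.0


class TestSexRatio:
    def test_half_at_pivot(self, flexit_default):
        assert sex_ratio(flexit_default, flexit_default.P) == 0.5

    def test_symmetric_logistic_closed_form(self):
        p = FlexitParams(P=29.5, S=1.0, deltaS=0.0)
        # 4.5 degC below the pivot: (1 + e^18)^-1
        assert sex_ratio(p, 25.0) == pytest.approx(1.0 / (1.0 + math.exp(18.0)),
                                                   rel=1e-9)

    def test_asymptotes(self, flexit_default):
        assert sex_ratio(flexit_default, 80.0) == pytest.approx(1.0, abs=1e-15)
        assert sex_ratio(flexit_default, -20.0) == pytest.approx(0.0, abs=1e-100)

    def test_vectorized_over_temperature(self, flexit_default):
        T = np.array([27.0, 29.49, 32.0])
        out = sex_ratio(flexit_default, T)
        assert out.shape == (3,)
        assert out[1] == 0.5

    @settings(max_examples=200, derandomize=True)
    @given(flexit_strategy())
    def test_pivot_identity_randomized(self, params):
        assert abs(sex_ratio(params, params.P) - 0.5) < 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(flexit_strategy())
    def test_monotone_on_fine_grid(self, params):
        T = np.arange(20.0, 40.0, 0.01)
        sr = sex_ratio(params, T)
        assert np.all(np.diff(sr) >= 0.0)
        # strictly increasing near the pivot, where float64 has not yet
        # saturated the logistic at exactly 0 or 1
        width = trt_limits(params).width
        near = ((T > params.P - 3 * width) & (T < params.P + 3 * width)
                & (sr > 1e-12) & (sr < 1.0 - 1e-12))
        assert np.all(np.diff(sr[near]) > 0.0)

    def test_reduces_to_plain_logistic_when_symmetric(self):
        p = FlexitParams(P=29.5, S=2.0, deltaS=0.0)
        T = np.concatenate([np.arange(25.0, 29.45, 0.01),
                            np.arange(29.56, 34.0, 0.01)])
        plain = 1.0 / (1.0 + np.exp(4.0 * p.S * (p.P - T)))
        assert np.allclose(sex_ratio(p, T), plain, atol=1e-9)

    def test_limb_slopes(self):
        # away from the pivot the log-odds slope is 4*S1 below and 4*S2 above
        p = FlexitParams(P=29.5, S=1.0, deltaS=1.0)
        def logit(x):
            return math.log(x / (1.0 - x))
        below = (logit(sex_ratio(p, 28.6)) - logit(sex_ratio(p, 28.5)))
        above = (logit(sex_ratio(p, 30.5)) - logit(sex_ratio(p, 30.4)))
        assert below == pytest.approx(4.0 * 1.0 * 0.1, rel=1e-6)
        assert above == pytest.approx(4.0 * 2.0 * 0.1, rel=1e-6)


class TestTrtLimits:
    def test_symmetric_closed_form(self):
        lim = trt_limits(FlexitParams(P=29.5, S=1.0, deltaS=0.0, l=0.05))
        assert lim.lower == pytest.approx(29.5 - math.log(19.0) / 4.0, rel=1e-12)
        assert lim.upper == pytest.approx(29.5 + math.log(19.0) / 4.0, rel=1e-12)
        assert lim.width == pytest.approx(math.log(19.0) / 2.0, rel=1e-12)

    def test_symmetry_when_slopes_equal(self):
        lim = trt_limits(FlexitParams(P=30.1, S=2.0, deltaS=0.0))
        assert (lim.upper - 30.1) == pytest.approx(30.1 - lim.lower, rel=1e-12)

    def test_asymmetry_scales_with_slope_ratio(self):
        # S2 = 2*S1 halves the upper-side distance
        lim = trt_limits(FlexitParams(P=29.5, S=1.0, deltaS=1.0, l=0.05))
        assert (lim.upper - 29.5) == pytest.approx((29.5 - lim.lower) / 2.0,
                                                   rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(flexit_strategy(s_max=5.0))
    def test_round_trip_through_sex_ratio(self, params):
        lim = trt_limits(params)
        assert sex_ratio(params, lim.lower) == pytest.approx(params.l, abs=1e-6)
        assert sex_ratio(params, lim.upper) == pytest.approx(1 - params.l, abs=1e-6)
        assert lim.lower < params.P < lim.upper

    def test_rejects_bad_tail_probability(self, flexit_default):
        with pytest.raises(ValueError):
            trt_limits(flexit_default, l=0.7)
        with pytest.raises(ValueError):
            FlexitParams(P=29.5, S=1.0, l=0.5)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(P=29.5, S=0.0), dict(P=29.5, S=1.0, deltaS=-1.0),
         dict(P=math.nan, S=1.0), dict(P=29.5, S=1.0, l=0.0)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FlexitParams(**kwargs)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SexCountRecord(temperature=29.0, males=-1, females=2)


class TestLoglikCounts:
    def test_single_record_at_pivot(self, flexit_default):
        rec = SexCountRecord(temperature=flexit_default.P, males=1, females=1)
        # no binomial coefficient: 1*log(.5) + 1*log(.5)
        assert loglik_counts(flexit_default, [rec]) == pytest.approx(
            -2.0 * math.log(2.0), rel=1e-12
        )

    def test_all_male_record(self, flexit_default):
        rec = SexCountRecord(temperature=28.0, males=17, females=0)
        q = sex_ratio(flexit_default, 28.0)
        assert loglik_counts(flexit_default, [rec]) == pytest.approx(
            17.0 * math.log(1.0 - q), rel=1e-12
        )

    def test_additive_over_records(self, flexit_default):
        rec = SexCountRecord(temperature=29.8, males=3, females=5)
        one = loglik_counts(flexit_default, [rec])
        assert loglik_counts(flexit_default, [rec, rec]) == pytest.approx(
            2.0 * one, rel=1e-12
        )

    def test_matches_per_egg_bernoulli_product(self, flexit_default, rng):
        # brute-force oracle: likelihood of each egg separately
        temps = rng.uniform(28.0, 31.0, size=8)
        recs = [
            SexCountRecord(temperature=T, males=int(m), females=int(f))
            for T, m, f in zip(temps, rng.integers(0, 3, 8), rng.integers(1, 4, 8))
        ]
        brute = 0.0
        for r in recs:
            p = sex_ratio(flexit_default, r.temperature)
            brute += r.females * math.log(p) + r.males * math.log(1.0 - p)
        assert loglik_counts(flexit_default, recs) == pytest.approx(brute, rel=1e-12)

    def test_finite_even_far_from_pivot(self, flexit_default):
        rec = SexCountRecord(temperature=20.0, males=0, females=5)
        assert math.isfinite(loglik_counts(flexit_default, [rec]))

    def test_empty_data_distinct_from_zero_counts(self, flexit_default):
        with pytest.raises(EmptyDataError):
            loglik_counts(flexit_default, [])
        rec = SexCountRecord(temperature=29.0, males=0, females=0)
        with pytest.raises(ValueError) as err:
            loglik_counts(flexit_default, [rec])
        assert not isinstance(err.value, EmptyDataError)

    @pytest.mark.parametrize(
        "policy,expected_f,expected_n",
        [("exclude", 4, 10), ("female", 6, 12), ("male", 4, 12), ("half", 5, 12)],
    )
    def test_intersex_policies(self, flexit_default, policy, expected_f, expected_n):
        rec = SexCountRecord(temperature=29.6, males=6, females=4, intersex=2)
        p = sex_ratio(flexit_default, 29.6)
        expected = expected_f * math.log(p) + (expected_n - expected_f) * math.log(1 - p)
        assert loglik_counts(flexit_default, [rec], intersex=policy) == pytest.approx(
            expected, rel=1e-12
        )

    def test_unknown_intersex_policy(self, flexit_default):
        rec = SexCountRecord(temperature=29.6, males=6, females=4)
        with pytest.raises(ValueError):
            loglik_counts(flexit_default, [rec], intersex="discard")
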