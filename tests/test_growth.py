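"""Tests of the Schoolfield growth norm, trajectory integration and TSP."""

import math

import numpy as np
import pytest

from tsdnorm import (
    DidNotHatchError,
    SchoolfieldParams,
    TemperatureSeries,
    integrate_trajectory,
    predict_duration,
    schoolfield_rate,
    tsp_window,
)
from tsdnorm.growth import GAS_CONSTANT, T_REF_K, DurationSummary


class TestSchoolfieldRate:
    def test_reference_identity_without_inhibition(self):
        # with the low-temperature term switched off (dHL -> very negative
        # and T12L far below), r(25) = rho25
        p = SchoolfieldParams(rho25=1e-4, dHA=5e4, dHL=-4.9e5, T12L=271.0)
        assert schoolfield_rate(p, 25.0) == pytest.approx(1e-4, rel=1e-6)

    def test_hand_evaluated_oracle(self):
        # independent evaluation of the closed form, term by term
        p = SchoolfieldParams(rho25=1e-5, dHA=5e4, dHL=-1e5, T12L=293.15)
        TK = 303.15
        expected = (
            1e-5
            * (TK / T_REF_K)
            * math.exp((5e4 / GAS_CONSTANT) * (1 / T_REF_K - 1 / TK))
            / (1.0 + math.exp((-1e5 / GAS_CONSTANT) * (1 / 293.15 - 1 / TK)))
        )
        assert schoolfield_rate(p, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_increasing_over_incubation_range(self, growth_default):
        T = np.arange(25.0, 35.0, 0.1)
        r = schoolfield_rate(growth_default, T)
        assert np.all(r > 0)
        assert np.all(np.diff(r) > 0)

    def test_no_overflow_at_extreme_cold(self, growth_default):
        assert schoolfield_rate(growth_default, -200.0) >= 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SchoolfieldParams(rho25=-1e-5, dHA=5e4, dHL=-1e5, T12L=285.0)
        with pytest.raises(ValueError):
            SchoolfieldParams(rho25=1e-5, dHA=5e4, dHL=-1e5, T12L=400.0)


class TestIntegrateTrajectory:
    def test_constant_temperature_matches_closed_form(self, growth_default,
                                                      constant_series):
        for T in (27.0, 29.5, 31.0):
            r = schoolfield_rate(growth_default, T)
            exact = math.log(59.3 / 1.7) / r / 1440.0
            d = predict_duration(growth_default, constant_series(T, days=120))
            assert d == pytest.approx(exact, rel=1e-3)

    def test_step_size_convergence(self, growth_default):
        rng = np.random.default_rng(7)
        times = np.arange(0.0, 100 * 1440.0, 720.0)
        temps = 29.5 + 0.5 * np.sin(2 * np.pi * times / 1440.0) \
            + 0.05 * rng.standard_normal(times.size)
        series = TemperatureSeries(times=times, temps=temps)
        d60 = predict_duration(growth_default, series, step_min=60.0)
        d30 = predict_duration(growth_default, series, step_min=30.0)
        assert abs(d30 - d60) / d60 < 5e-4

    def test_temperature_shuffle_invariance(self, growth_default):
        # the growth law has no memory: day-level rearrangements of a
        # 28/31 degC pattern leave the duration unchanged up to the length
        # of one rearranged segment (the day the hatching threshold is
        # crossed), and the duration matches the closed form under the
        # time-average of the two rates
        def day_series(day_temps):
            times = np.arange(0.0, len(day_temps) * 1440.0, 60.0)
            temps = np.array([day_temps[int(tt // 1440)] for tt in times])
            return TemperatureSeries(times=times, temps=temps)

        alternating = [28.0, 31.0] * 40
        rng = np.random.default_rng(3)
        durations = [predict_duration(growth_default, day_series(alternating))]
        for _ in range(3):
            shuffled = list(rng.permutation(alternating))
            durations.append(predict_duration(growth_default,
                                              day_series(shuffled)))
        assert max(durations) - min(durations) < 2.0  # days

        r_mean = 0.5 * (schoolfield_rate(growth_default, 28.0)
                        + schoolfield_rate(growth_default, 31.0))
        blend = math.log(59.3 / 1.7) / r_mean / 1440.0
        assert durations[0] == pytest.approx(blend, rel=0.02)

    def test_doubling_rho25_halves_duration(self, growth_default):
        double = SchoolfieldParams(rho25=2 * growth_default.rho25,
                                   dHA=growth_default.dHA,
                                   dHL=growth_default.dHL,
                                   T12L=growth_default.T12L)
        d1 = predict_duration(growth_default, 30.0)
        d2 = predict_duration(double, 30.0)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_spec_scale_example(self):
        # r = 1.3e-4 min^-1 constant: ln(59.3/1.7)/r = 27,319 min = 18.97 d
        p = SchoolfieldParams(rho25=1.3e-4, dHA=1e4, dHL=-4.9e5, T12L=271.0)
        r = schoolfield_rate(p, 30.0)
        expected = math.log(59.3 / 1.7) / r / 1440.0
        assert predict_duration(p, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_non_hatching_error_carries_attained_size(self, growth_default,
                                                      constant_series):
        with pytest.raises(DidNotHatchError) as err:
            integrate_trajectory(growth_default, constant_series(29.5, days=5))
        assert 1.7 < err.value.attained_scl < 59.3

    def test_determinism(self, growth_default, constant_series):
        s = constant_series(30.0, days=100)
        assert predict_duration(growth_default, s) == predict_duration(
            growth_default, s
        )

    def test_trajectory_monotone_and_bounded(self, growth_default,
                                             constant_series):
        traj = integrate_trajectory(growth_default, constant_series(30.0, days=100))
        assert np.all(np.diff(traj.scl) >= 0)
        assert traj.scl[0] == pytest.approx(1.7)
        assert traj.scl[-1] == pytest.approx(59.3, abs=1e-6)


class TestTspWindow:
    def test_constant_temperature_closed_form(self, growth_default,
                                              constant_series):
        traj = integrate_trajectory(growth_default, constant_series(30.0, days=100))
        tsp = tsp_window(traj, stage_fracs=(1 / 3, 2 / 3))
        r = schoolfield_rate(growth_default, 30.0)
        for t_obs, frac in ((tsp.t_start, 1 / 3), (tsp.t_end, 2 / 3)):
            exact = math.log(frac * 59.3 / 1.7) / r
            assert t_obs == pytest.approx(exact, rel=1e-3)
        assert tsp.t_start < tsp.t_end

    def test_fluctuating_temperature_moves_tsp_in_time(self, growth_default):
        # the stage-defined TSP is anchored to embryo size, not elapsed
        # time, so its position within incubation depends on when the warm
        # phase occurs: a cold finish (growth slow late) pulls the window
        # relatively earlier, a warm finish pushes it later, with the
        # constant-temperature placement in between — the window is NOT a
        # fixed fraction (e.g. the middle third) of incubation time
        def rel_start(temps_fn):
            times = np.arange(0.0, 120 * 1440.0, 60.0)
            series = TemperatureSeries(times=times, temps=temps_fn(times))
            traj = integrate_trajectory(growth_default, series)
            tsp = tsp_window(traj)
            return tsp.t_start / (traj.times[-1] - traj.times[0])

        warm_finish = rel_start(
            lambda tt: np.where(tt < 30 * 1440.0, 28.0, 32.0))
        cold_finish = rel_start(
            lambda tt: np.where(tt < 30 * 1440.0, 32.0, 28.0))
        constant = rel_start(lambda tt: np.full(tt.size, 30.0))
        assert cold_finish < constant < warm_finish
        assert abs(warm_finish - 1.0 / 3.0) > 0.05  # not the middle third

    def test_threshold_not_crossed_is_explicit(self, growth_default,
                                               constant_series):
        traj = integrate_trajectory(growth_default, constant_series(30.0, days=100))
        short = type(traj)(
            times=traj.times[:100], scl=traj.scl[:100],
            scl0=traj.scl0, scl_hatch=traj.scl_hatch,
        )
        with pytest.raises(ValueError, match="never crosses"):
            tsp_window(short)

    def test_invalid_fractions(self, growth_default, constant_series):
        traj = integrate_trajectory(growth_default, constant_series(30.0, days=100))
        with pytest.raises(ValueError):
            tsp_window(traj, stage_fracs=(0.7, 0.3))


class TestDurationSummary:
    def test_requires_exactly_one_condition(self, constant_series):
        with pytest.raises(ValueError):
            DurationSummary(mean_days=60.0, sd_days=2.0, n=5)
        with pytest.raises(ValueError):
            DurationSummary(mean_days=60.0, sd_days=2.0, n=5,
                            temperature=29.0, series=constant_series(29.0))


class TestSeriesValidation:
    def test_rejects_unsorted_and_extreme(self):
        with pytest.raises(ValueError):
            TemperatureSeries(times=np.array([0.0, 0.0]), temps=np.array([29.0, 29.0]))
        with pytest.raises(ValueError):
            TemperatureSeries(times=np.array([0.0, 60.0]), temps=np.array([29.0, 60.0]))
        with pytest.raises(ValueError):
            TemperatureSeries(times=np.array([0.0]), temps=np.array([29.0]))
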