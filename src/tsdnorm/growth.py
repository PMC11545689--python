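"""Thermal reaction norm of embryonic growth and trajectory integration.

Instantaneous growth rate follows a four-parameter Schoolfield-type model
(high-temperature branch omitted, low-temperature inhibition retained),
which is monotonically increasing over the temperatures tropical sea-turtle
nests experience.  Embryo size (straight carapace length, SCL, mm) grows
exponentially at that instantaneous rate, so the integrated trajectory is

    SCL(t) = SCL0 * exp( integral_0^t r(T(u)) du )

and incubation ends when SCL reaches the hatchling size.  All acceptance
quantities built on this trajectory (TSP timing, CTE weighting) depend only
on relative timing, which is invariant to monotone re-parameterizations of
the size axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "T_REF_K",
    "KELVIN_OFFSET",
    "SchoolfieldParams",
    "TemperatureSeries",
    "GrowthTrajectory",
    "TSPWindow",
    "DurationSummary",
    "DidNotHatchError",
    "schoolfield_rate",
    "integrate_trajectory",
    "predict_duration",
    "tsp_window",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
KELVIN_OFFSET = 273.15
T_REF_K = 298.15  # 25 degC reference

MINUTES_PER_DAY = 1440.0

#: default initial embryo SCL, mm
DEFAULT_SCL0 = 1.7
#: default hatchling SCL, mm (Northwest Atlantic pooled / West Pacific)
DEFAULT_SCL_HATCH_NWA = 59.3
DEFAULT_SCL_HATCH_WP = 57.3


@dataclass(frozen=True)
class SchoolfieldParams:
    """Four-parameter thermal reaction norm of instantaneous growth rate.

    Parameters
    ----------
    rho25 : float
        Growth rate at the 25 degC reference temperature, min^-1.
    dHA : float
        Activation enthalpy-like parameter, J mol^-1 (> 0 for a rate that
        increases with temperature).
    dHL : float
        Low-temperature inhibition enthalpy-like parameter, J mol^-1
        (negative: the inhibition term grows as temperature falls).
    T12L : float
        Temperature of half low-temperature inhibition, K.
    """

    rho25: float
    dHA: float
    dHL: float
    T12L: float

    def __post_init__(self) -> None:
        if not (self.rho25 > 0):
            raise ValueError(f"rho25 must be > 0, got {self.rho25}")
        if not (270.0 < self.T12L < 310.0):
            raise ValueError(f"T12L must lie in (270, 310) K, got {self.T12L}")


@dataclass(frozen=True)
class TemperatureSeries:
    """Time-stamped nest temperatures; piecewise-linear in between samples."""

    times: np.ndarray  # minutes since start, strictly increasing
    temps: np.ndarray  # degC

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or times.shape != temps.shape:
            raise ValueError("times and temps must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError("a temperature series needs at least 2 points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(temps < 15.0) or np.any(temps > 45.0):
            raise ValueError("temperatures must lie within 15-45 degC")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def at(self, t) -> np.ndarray:
        """Linearly interpolated temperature at time(s) ``t`` (minutes)."""
        return np.interp(t, self.times, self.temps)


@dataclass(frozen=True)
class GrowthTrajectory:
    """Integrated embryo-size curve SCL(t)."""

    times: np.ndarray  # minutes
    scl: np.ndarray  # mm, non-decreasing
    scl0: float
    scl_hatch: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        scl = np.asarray(self.scl, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scl", scl)
        if np.any(np.diff(scl) < -1e-9):
            raise ValueError("SCL trajectory must be non-decreasing")
        if abs(scl[0] - self.scl0) > 1e-9:
            raise ValueError("trajectory must start at scl0")

    @property
    def duration_days(self) -> float:
        return float(self.times[-1] - self.times[0]) / MINUTES_PER_DAY


@dataclass(frozen=True)
class TSPWindow:
    """Thermosensitive period bounded by two developmental-stage landmarks."""

    t_start: float  # minutes
    t_end: float
    scl_start: float  # mm
    scl_end: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_end):
            raise ValueError("TSP must have t_start < t_end")


@dataclass(frozen=True)
class DurationSummary:
    """Incubation-duration summary for one incubation condition.

    Either a constant ``temperature`` (degC) or a recorded
    :class:`TemperatureSeries` must be given.  ``scl_hatch`` optionally
    overrides the dataset-level hatchling size for this condition.
    """

    mean_days: float
    sd_days: float
    n: int
    temperature: float | None = None
    series: TemperatureSeries | None = None
    scl_hatch: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if (self.temperature is None) == (self.series is None):
            raise ValueError(
                "exactly one of temperature or series must be provided"
            )
        if self.mean_days <= 0 or self.sd_days < 0 or self.n < 1:
            raise ValueError("invalid duration summary")


class DidNotHatchError(RuntimeError):
    """The temperature series ended before the embryo reached hatchling size."""

    def __init__(self, attained_scl: float, scl_hatch: float):
        self.attained_scl = attained_scl
        self.scl_hatch = scl_hatch
        super().__init__(
            f"embryo did not hatch within series: attained SCL "
            f"{attained_scl:.2f} mm < {scl_hatch:.2f} mm"
        )


def schoolfield_rate(params: SchoolfieldParams, T):
    """Instantaneous growth rate (min^-1) at temperature ``T`` (degC).

    r(T) = rho25 * (TK/298.15) * exp[(dHA/R)(1/298.15 - 1/TK)]
           / (1 + exp[(dHL/R)(1/T12L - 1/TK)]),   TK = T + 273.15.

    Computed in log space so the low-temperature inhibition term cannot
    overflow.  Vectorized over ``T``.
    """
    T = np.asarray(T, dtype=float)
    TK = T + KELVIN_OFFSET
    log_r = (
        math.log(params.rho25)
        + np.log(TK / T_REF_K)
        + (params.dHA / GAS_CONSTANT) * (1.0 / T_REF_K - 1.0 / TK)
        - np.logaddexp(0.0, (params.dHL / GAS_CONSTANT) * (1.0 / params.T12L - 1.0 / TK))
    )
    out = np.exp(log_r)
    return float(out) if out.ndim == 0 else out


def _growth_grid(series: TemperatureSeries, step_min: float):
    """Fine integration grid over the series span, including both endpoints."""
    t0, t1 = series.span
    n = max(int(math.ceil((t1 - t0) / step_min)), 1)
    times = np.linspace(t0, t1, n + 1)
    return times, series.at(times)


def cumulative_growth(
    params: SchoolfieldParams, series: TemperatureSeries, step_min: float = 60.0
):
    """Trapezoidal cumulative integral of r(T(t)) on a fine grid.

    Returns ``(times, cumint)`` with ``cumint[0] = 0``; ``SCL(t) = scl0 *
    exp(cumint)``.
    """
    times, temps = _growth_grid(series, step_min)
    r = schoolfield_rate(params, temps)
    dt = np.diff(times)
    increments = 0.5 * (r[1:] + r[:-1]) * dt
    cumint = np.concatenate(([0.0], np.cumsum(increments)))
    return times, cumint


def _crossing_time(times: np.ndarray, cumint: np.ndarray, target: float) -> float:
    """First time at which the cumulative integral reaches ``target``."""
    idx = int(np.searchsorted(cumint, target))
    if idx == 0:
        return float(times[0])
    # linear interpolation within the bracketing step
    c0, c1 = cumint[idx - 1], cumint[idx]
    frac = (target - c0) / (c1 - c0) if c1 > c0 else 1.0
    return float(times[idx - 1] + frac * (times[idx] - times[idx - 1]))


def integrate_trajectory(
    params: SchoolfieldParams,
    series: TemperatureSeries,
    scl0: float = DEFAULT_SCL0,
    scl_hatch: float = DEFAULT_SCL_HATCH_NWA,
    step_min: float = 60.0,
) -> GrowthTrajectory:
    """Integrate dSCL/dt = r(T(t)) * SCL from ``scl0`` until hatchling size.

    Fixed-step trapezoidal update on log-SCL (default 60 min step) with the
    temperature series interpolated linearly; the trajectory is truncated
    at the interpolated instant SCL reaches ``scl_hatch``.

    Raises
    ------
    DidNotHatchError
        If the series ends before ``scl_hatch`` is reached; the exception
        carries the attained SCL.
    """
    if not (scl0 < scl_hatch):
        raise ValueError("scl0 must be smaller than scl_hatch")
    times, cumint = cumulative_growth(params, series, step_min)
    target = math.log(scl_hatch / scl0)
    if cumint[-1] < target:
        raise DidNotHatchError(scl0 * math.exp(cumint[-1]), scl_hatch)
    t_hatch = _crossing_time(times, cumint, target)
    keep = times < t_hatch
    traj_t = np.concatenate((times[keep], [t_hatch]))
    traj_c = np.concatenate((cumint[keep], [target]))
    return GrowthTrajectory(
        times=traj_t, scl=scl0 * np.exp(traj_c), scl0=scl0, scl_hatch=scl_hatch
    )


def predict_duration(
    params: SchoolfieldParams,
    series_or_temp,
    scl0: float = DEFAULT_SCL0,
    scl_hatch: float = DEFAULT_SCL_HATCH_NWA,
    step_min: float = 60.0,
) -> float:
    """Incubation duration in days until SCL reaches ``scl_hatch``.

    For a scalar constant temperature the exponential closed form
    ``ln(scl_hatch/scl0) / r(T)`` is used; for a :class:`TemperatureSeries`
    the trajectory is integrated.  Propagates :class:`DidNotHatchError`.
    """
    if not (scl0 < scl_hatch):
        raise ValueError("scl0 must be smaller than scl_hatch")
    if isinstance(series_or_temp, TemperatureSeries):
        series = series_or_temp
        times, cumint = cumulative_growth(params, series, step_min)
        target = math.log(scl_hatch / scl0)
        if cumint[-1] < target:
            raise DidNotHatchError(scl0 * math.exp(cumint[-1]), scl_hatch)
        t_hatch = _crossing_time(times, cumint, target)
        return (t_hatch - times[0]) / MINUTES_PER_DAY
    T = float(series_or_temp)
    r = schoolfield_rate(params, T)
    if r <= 0 or not math.isfinite(r):
        raise DidNotHatchError(scl0, scl_hatch)
    return math.log(scl_hatch / scl0) / r / MINUTES_PER_DAY


#: placeholder SCL landmarks for developmental stages 23 and 27, as
#: fractions of hatchling SCL; the exact staging-table values are not
#: fixed by this package and may be overridden wherever a TSP is computed.
DEFAULT_STAGE_FRACS = (1.0 / 3.0, 2.0 / 3.0)


def tsp_window(
    traj: GrowthTrajectory,
    stage_fracs: tuple[float, float] = DEFAULT_STAGE_FRACS,
) -> TSPWindow:
    """Thermosensitive period delimited by SCL landmarks.

    ``stage_fracs = (f23, f27)`` are the fractions of hatchling SCL at which
    stages 23 and 27 (the TSP boundaries in leatherbacks) are reached; the
    boundary times are first crossings of ``f * scl_hatch`` with linear
    interpolation between trajectory samples.  Under fluctuating
    temperatures this window generally is NOT the middle third of
    incubation time.
    """
    f23, f27 = stage_fracs
    if not (0.0 < f23 < f27 <= 1.0):
        raise ValueError("stage fractions must satisfy 0 < f23 < f27 <= 1")
    thresholds = (f23 * traj.scl_hatch, f27 * traj.scl_hatch)
    times = []
    for thr in thresholds:
        if thr < traj.scl[0] or thr > traj.scl[-1]:
            raise ValueError(
                f"trajectory (SCL {traj.scl[0]:.2f}-{traj.scl[-1]:.2f} mm) "
                f"never crosses the {thr:.2f} mm stage landmark"
            )
        idx = int(np.searchsorted(traj.scl, thr))
        if idx == 0:
            times.append(float(traj.times[0]))
            continue
        s0, s1 = traj.scl[idx - 1], traj.scl[idx]
        frac = (thr - s0) / (s1 - s0) if s1 > s0 else 1.0
        times.append(float(traj.times[idx - 1] + frac * (traj.times[idx] - traj.times[idx - 1])))
    return TSPWindow(
        t_start=times[0], t_end=times[1],
        scl_start=thresholds[0], scl_end=thresholds[1],
    )
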