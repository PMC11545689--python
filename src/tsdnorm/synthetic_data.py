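"""Generators emulating the study's inputs, plus small literature-data utilities.

The generators produce (i) sexed-count tables with the nested RMU / study /
clutch structure and optional among-group variation of the flexit*
parameters, (ii) near-constant tropical nest temperature series (a small
day-night cycle around a stable mean with slow drift and logger jitter,
sampled once per day by default), and (iii) incubation-duration summaries
from the growth norm plus Gaussian noise.  All generators are pure
functions of their configuration (the seed lives inside the config or is
passed explicitly), so every dataset is reproducible.

Two standalone helpers re-create the simple statistics applied to
literature data: estimating a standard deviation from a published range,
and the probability of observing a single-sex sample when the minority sex
has a given expected frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import (
    DEFAULT_SCL0,
    DEFAULT_SCL_HATCH_NWA,
    DurationSummary,
    SchoolfieldParams,
    TemperatureSeries,
    predict_duration,
)
from .tsd_curve import FlexitParams, SexCountRecord, sex_ratio

__all__ = [
    "SimConfig",
    "DEFAULT_TRUE_FLEXIT",
    "DEFAULT_TRUE_GROWTH",
    "gen_sexcounts",
    "gen_temperature_series",
    "gen_durations",
    "sd_from_range",
    "prob_all_one_sex",
]

#: flexit* truth used by default in simulations: the point estimates of the
#: leatherback TSD curve (pivot 29.49 degC, nearly symmetric limbs).
DEFAULT_TRUE_FLEXIT = FlexitParams(P=29.49, S=2.34, deltaS=0.49)

#: growth-norm truth giving realistic leatherback incubation durations
#: (about 75 d at 27 degC down to about 50 d at 31 degC, monotone rate).
DEFAULT_TRUE_GROWTH = SchoolfieldParams(
    rho25=2.8e-5, dHA=7.0e4, dHL=-1.4e5, T12L=285.0
)

#: constant-temperature design used by default for sexed counts (degC),
#: mirroring the 28-32 degC laboratory incubation grid.
DEFAULT_TEMPERATURES = (28.0, 29.0, 29.5, 30.0, 30.5, 31.0, 31.5, 32.0)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic-data generators.

    The defaults emulate the study conditions: a constant-temperature
    sex-count design on a 28-32 degC grid, near-constant tropical nest
    series (means within 27-31 degC, a small nychthemeral cycle, one
    recorded temperature per day over ~10 weeks) and duration noise of
    2 days.
    """

    flexit: FlexitParams = DEFAULT_TRUE_FLEXIT
    growth: SchoolfieldParams = DEFAULT_TRUE_GROWTH
    #: among-group SDs of the flexit* parameters, keyed (level, param),
    #: e.g. {("clutch", "P"): 0.3}; levels: "rmu", "study_id", "clutch".
    re_sd: dict = field(default_factory=dict)
    n_rmu: int = 1
    n_studies_per_rmu: int = 1
    n_clutches_per_study: int = 8
    eggs_per_clutch: int = 10
    #: temperatures assigned cyclically to clutches (degC)
    temperatures: tuple = DEFAULT_TEMPERATURES
    # fluctuating-series parameters
    series_mean: float = 29.5
    series_amplitude: float = 0.25  # nychthemeral half-range, degC
    series_drift: float = 0.0  # total linear drift over the series, degC
    series_jitter_sd: float = 0.05  # logger noise, degC
    series_interval_min: float = 1440.0  # one record per day
    series_days: float = 75.0
    duration_sd_days: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rmu, self.n_studies_per_rmu,
               self.n_clutches_per_study, self.eggs_per_clutch) < 1:
            raise ValueError("all layout counts must be >= 1")
        if self.series_amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for level, _ in self.re_sd:
            if level not in ("rmu", "study_id", "clutch"):
                raise ValueError(f"unknown random-effect level {level!r}")


def gen_sexcounts(cfg: SimConfig) -> list[SexCountRecord]:
    """Simulate sexed counts under the (possibly hierarchical) flexit* model.

    For each group at each nesting level, parameter deviations are drawn
    from ``Normal(0, re_sd[level, param])``; each clutch's eggs are then
    binomial with the female probability given by its clutch-specific
    curve at its assigned temperature.  Labels carry the full
    RMU/ID/Clutch nesting.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SexCountRecord] = []
    temps = cfg.temperatures
    tidx = 0

    def dev(level: str) -> dict:
        return {
            p: rng.normal(0.0, cfg.re_sd.get((level, p), 0.0))
            for p in ("P", "S", "dS")
        }

    for r in range(cfg.n_rmu):
        d_rmu = dev("rmu")
        for s in range(cfg.n_studies_per_rmu):
            d_study = dev("study_id")
            for c in range(cfg.n_clutches_per_study):
                d_clutch = dev("clutch")
                P = cfg.flexit.P + d_rmu["P"] + d_study["P"] + d_clutch["P"]
                S = cfg.flexit.S + d_rmu["S"] + d_study["S"] + d_clutch["S"]
                dS = cfg.flexit.deltaS + d_rmu["dS"] + d_study["dS"] + d_clutch["dS"]
                S = max(S, 1e-3)
                dS = max(dS, 1e-3 - S)
                params = FlexitParams(P=P, S=S, deltaS=dS, l=cfg.flexit.l)
                T = temps[tidx % len(temps)]
                tidx += 1
                p_female = sex_ratio(params, T)
                females = int(rng.binomial(cfg.eggs_per_clutch, p_female))
                records.append(
                    SexCountRecord(
                        temperature=T,
                        males=cfg.eggs_per_clutch - females,
                        females=females,
                        rmu=f"RMU{r + 1}",
                        study_id=f"S{r + 1}.{s + 1}",
                        clutch=f"C{r + 1}.{s + 1}.{c + 1}",
                    )
                )
    return records


def gen_temperature_series(
    cfg: SimConfig, seed: int | None = None
) -> TemperatureSeries:
    """Simulate a near-constant tropical nest temperature series.

    ``T(t) = mean + amplitude * sin(2 pi t / 1 day) + linear drift
    + Gaussian logger jitter``, sampled at the configured interval
    (daily by default, as in shaded incubation boxes read once a day).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t_end = cfg.series_days * 1440.0
    times = np.arange(0.0, t_end + 0.5 * cfg.series_interval_min,
                      cfg.series_interval_min)
    cycle = cfg.series_amplitude * np.sin(2.0 * np.pi * times / 1440.0
                                          + rng.uniform(0.0, 2.0 * np.pi))
    drift = cfg.series_drift * (times - times[0]) / max(t_end, 1.0)
    jitter = rng.normal(0.0, cfg.series_jitter_sd, size=times.size)
    return TemperatureSeries(times=times, temps=cfg.series_mean + cycle
                             + drift + jitter)


def gen_durations(
    conditions,
    growth_params: SchoolfieldParams,
    sd_days: float,
    n: int,
    seed: int = 0,
    scl0: float = DEFAULT_SCL0,
    scl_hatch: float = DEFAULT_SCL_HATCH_NWA,
) -> list[DurationSummary]:
    """Simulate incubation-duration summaries.

    ``conditions`` is an iterable of constant temperatures (degC) and/or
    :class:`TemperatureSeries`.  For each condition, ``n`` durations are
    drawn from ``Normal(predicted duration, sd_days)`` and summarized as
    (mean, sd, n); with ``sd_days = 0`` every duration equals the
    deterministic prediction.  Propagates the non-hatching error if a
    series is too short.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i, cond in enumerate(conditions):
        pred = predict_duration(growth_params, cond, scl0=scl0,
                                scl_hatch=scl_hatch)
        durs = pred + rng.normal(0.0, sd_days, size=n) if sd_days > 0 \
            else np.full(n, pred)
        is_series = isinstance(cond, TemperatureSeries)
        out.append(
            DurationSummary(
                mean_days=float(np.mean(durs)),
                sd_days=float(np.std(durs, ddof=1)) if n > 1 else 0.0,
                n=n,
                temperature=None if is_series else float(cond),
                series=cond if is_series else None,
                scl_hatch=scl_hatch,
                label=f"cond{i + 1}",
            )
        )
    return out


_EXPECTED_RANGE_CACHE: dict[int, float] = {}


def _expected_range_std_normal(n: int, reps: int = 100_000, seed: int = 20_240) -> float:
    """E[max - min] of n standard normals, by seeded Monte Carlo."""
    if n not in _EXPECTED_RANGE_CACHE:
        rng = np.random.default_rng(seed + n)
        x = rng.standard_normal((reps, n))
        _EXPECTED_RANGE_CACHE[n] = float(np.mean(x.max(axis=1) - x.min(axis=1)))
    return _EXPECTED_RANGE_CACHE[n]


def sd_from_range(range_width: float, n: int = 2, method: str = "z196") -> float:
    """Estimate a standard deviation from a published range.

    ``method="z196"``: ``range / (2 * 1.96)`` — treats the published
    extremes as the central 95% of a normal (no sample-size information
    needed).  ``method="expected_range"``: ``range / E[range of n standard
    normals]`` — an unbiased order-statistics estimator given the sample
    size; the expectation is obtained by seeded Monte Carlo.
    """
    if range_width <= 0:
        raise ValueError("range_width must be > 0")
    if method == "z196":
        return range_width / (2.0 * 1.96)
    if method == "expected_range":
        if n < 2:
            raise ValueError("expected_range needs n >= 2")
        return range_width / _expected_range_std_normal(n)
    raise ValueError(f"unknown method {method!r}")


def prob_all_one_sex(p_minor: float, n_eggs: int) -> float:
    """Probability that the minority sex goes unobserved in ``n_eggs`` eggs.

    With an expected minority-sex frequency ``p_minor``, the chance that a
    clutch of ``n_eggs`` contains none of that sex is ``(1 - p_minor) **
    n_eggs`` — e.g. 0.35 for p = 0.1 with 10 eggs, which is why small
    incubation batches make TRT limits hard to pin down.
    """
    if not (0.0 <= p_minor <= 1.0):
        raise ValueError("p_minor must lie in [0, 1]")
    if n_eggs < 1:
        raise ValueError("n_eggs must be >= 1")
    return (1.0 - p_minor) ** n_eggs
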