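"""Asymmetric sigmoid (flexit*) model of temperature-dependent sex determination.

The flexit* curve gives the expected proportion of females produced at a
constant incubation temperature ``T`` (or at a constant-temperature
equivalent for fluctuating nests).  It is parameterized by the pivotal
temperature ``P`` (the temperature producing a 1:1 sex ratio), a lower-limb
slope parameter ``S`` and a slope increment ``deltaS`` so that the slope
below the pivot is ``S1 = S`` and above it is ``S2 = S + deltaS``.  The two
limbs are blended across the pivot by a quasi-binary threshold (QBT), a very
steep logistic that switches from 0 to 1 over roughly 0.1 degC.

Sex-ratio convention: throughout this package ``sex_ratio`` is the
proportion of FEMALES, which rises with temperature (females are produced
at warm temperatures in sea turtles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "FlexitParams",
    "TRTLimits",
    "SexCountRecord",
    "qbt",
    "sex_ratio",
    "trt_limits",
    "loglik_counts",
]

# probabilities entering the binomial log-likelihood are clipped here
_P_EPS = 1e-15


@dataclass(frozen=True)
class FlexitParams:
    """Parameters of the flexit* sex-ratio curve.

    Parameters
    ----------
    P : float
        Pivotal temperature, degC: the constant temperature producing a
        1:1 sex ratio.
    S : float
        Lower-limb slope parameter (per degC scale); the effective logistic
        slope below the pivot is ``4 * S``.
    deltaS : float
        Slope increment; the upper limb has slope parameter ``S + deltaS``.
        ``deltaS = 0`` gives the symmetric logistic curve.
    l : float
        Tail sex-ratio defining the transitional range of temperatures
        (TRT): the TRT spans the temperatures producing sex ratios from
        ``l`` to ``1 - l``.  Default 0.05 (the conventional TRT95).
    """

    P: float
    S: float
    deltaS: float = 0.0
    l: float = 0.05

    def __post_init__(self) -> None:
        if not math.isfinite(self.P):
            raise ValueError("pivotal temperature P must be finite")
        if not (self.S > 0.0):
            raise ValueError(f"S must be > 0, got {self.S}")
        if not (self.S + self.deltaS > 0.0):
            raise ValueError(
                f"S + deltaS must be > 0, got {self.S + self.deltaS}"
            )
        if not (0.0 < self.l < 0.5):
            raise ValueError(f"l must lie in (0, 0.5), got {self.l}")

    @property
    def S1(self) -> float:
        """Slope parameter governing the limb below the pivot."""
        return self.S

    @property
    def S2(self) -> float:
        """Slope parameter governing the limb above the pivot."""
        return self.S + self.deltaS


@dataclass(frozen=True)
class TRTLimits:
    """Transitional range of temperatures: the interval producing both sexes."""

    lower: float
    upper: float
    width: float


@dataclass(frozen=True)
class SexCountRecord:
    """Sexed hatchling counts for one incubation group.

    ``temperature`` is the constant incubation temperature, or the median
    CTE within the thermosensitive period for a fluctuating nest.
    """

    temperature: float
    males: float
    females: float
    intersex: float = 0.0
    rmu: str = ""
    study_id: str = ""
    clutch: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        for name in ("males", "females", "intersex"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def qbt(P, T):
    """Quasi-binary threshold ``(1 + exp(100 (P - T)))**-1``.

    A logistic so steep it acts as a smooth 0/1 switch across the pivot:
    0 below ``P``, 1 above ``P``, exactly 0.5 at ``T = P``.  Overflow-safe
    for arbitrarily large ``|P - T|``.
    """
    return expit(100.0 * (np.asarray(T, dtype=float) - P))


def sex_ratio(params: FlexitParams, T):
    """Proportion of females at temperature ``T`` under the flexit* curve.

    ``sr(T) = (1 + exp(4 (S + deltaS * QBT) (P - T)))**-1``: a logistic with
    slope ``4 S`` below the pivot and ``4 (S + deltaS)`` above it, blended
    by the QBT in the immediate neighbourhood of ``P``.  Vectorized over
    ``T``; returns a scalar for scalar input.
    """
    T = np.asarray(T, dtype=float)
    slope = 4.0 * (params.S + params.deltaS * qbt(params.P, T))
    out = expit(slope * (T - params.P))
    return float(out) if out.ndim == 0 else out


def trt_limits(params: FlexitParams, l: float | None = None) -> TRTLimits:
    """Limits of the transitional range of temperatures.

    The lower limit produces a sex ratio of ``l`` and the upper a sex ratio
    of ``1 - l``; each is a closed-form inversion of the corresponding limb
    (QBT blending is negligible at these distances for realistic slopes):

    ``lower = P - ln((1-l)/l) / (4 S)``
    ``upper = P + ln((1-l)/l) / (4 (S + deltaS))``

    The width is reported as ``upper - lower`` (always positive).
    """
    if l is None:
        l = params.l
    if not (0.0 < l < 0.5):
        raise ValueError(f"l must lie in (0, 0.5), got {l}")
    logit_l = math.log((1.0 - l) / l)
    lower = params.P - logit_l / (4.0 * params.S1)
    upper = params.P + logit_l / (4.0 * params.S2)
    return TRTLimits(lower=lower, upper=upper, width=upper - lower)


class EmptyDataError(ValueError):
    """Raised when a likelihood is requested for an empty dataset."""


def _effective_counts(rec: SexCountRecord, intersex: str) -> tuple[float, float]:
    """(females, total) entering the binomial, under the intersex policy."""
    if intersex == "exclude":
        return rec.females, rec.males + rec.females
    if intersex == "female":
        return rec.females + rec.intersex, rec.males + rec.females + rec.intersex
    if intersex == "male":
        return rec.females, rec.males + rec.females + rec.intersex
    if intersex == "half":
        return (
            rec.females + 0.5 * rec.intersex,
            rec.males + rec.females + rec.intersex,
        )
    raise ValueError(
        f"unknown intersex policy {intersex!r}; "
        "expected 'exclude', 'female', 'male' or 'half'"
    )


def loglik_counts(
    params: FlexitParams,
    data: list[SexCountRecord],
    intersex: str = "exclude",
) -> float:
    """Binomial log-likelihood of sexed counts under the flexit* curve.

    Each record contributes ``f log p + m log(1-p)`` with
    ``p = sex_ratio(params, T)``; the binomial coefficient is omitted (it is
    constant in the parameters, so likelihood ratios, MCMC and information
    criteria that share the data are unaffected).  Probabilities are clipped
    to ``[1e-15, 1 - 1e-15]`` so the result is finite for all valid params.

    Intersex hatchlings are excluded by default; ``intersex`` may instead
    count them as ``'female'``, ``'male'`` or ``'half'`` (0.5 each way).

    Raises
    ------
    EmptyDataError
        If ``data`` is empty.
    ValueError
        If any record has zero sexed hatchlings after applying the
        intersex policy.
    """
    if len(data) == 0:
        raise EmptyDataError("no sex-count records supplied")
    fem = np.empty(len(data))
    tot = np.empty(len(data))
    temps = np.empty(len(data))
    for i, rec in enumerate(data):
        f, n = _effective_counts(rec, intersex)
        if n < 1:
            raise ValueError(
                f"record {i} ({rec.temperature} degC, "
                f"{rec.rmu}/{rec.study_id}/{rec.clutch}) has no sexed "
                "hatchlings entering the likelihood"
            )
        fem[i], tot[i], temps[i] = f, n, rec.temperature
    p = np.clip(sex_ratio(params, temps), _P_EPS, 1.0 - _P_EPS)
    return float(np.sum(fem * np.log(p) + (tot - fem) * np.log1p(-p)))
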