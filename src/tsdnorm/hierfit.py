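"""Bayesian MCMC fitting of the growth norm and the TSD curve.

Two fitters share the adaptive Metropolis-within-Gibbs engine in
:mod:`tsdnorm.mcmc`:

* :func:`fit_growth` — Schoolfield growth-norm parameters from
  incubation-duration summaries (Gaussian likelihood for the observed mean
  duration of each condition, with standard error ``sd / sqrt(n)`` taken
  from the summaries).
* :func:`fit_tsd` — flexit* parameters from sexed-count records (binomial
  likelihood), optionally with nested random effects (RMU / study ID /
  clutch) applied additively and independently to each of P, S and deltaS.
  Random effects use a non-centered parameterization (standard-normal
  deviates scaled by half-normal level SDs) to avoid funnel pathologies.

Both fitters are deterministic given their seed, and records are put into a
canonical order before fitting so that the result does not depend on input
ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .growth import (
    DEFAULT_SCL0,
    DEFAULT_SCL_HATCH_NWA,
    DurationSummary,
    SchoolfieldParams,
    schoolfield_rate,
)
from .growth import GAS_CONSTANT, MINUTES_PER_DAY, _crossing_time, _growth_grid
from .mcmc import McmcSettings, adaptive_mwg
from .tsd_curve import FlexitParams, SexCountRecord, _effective_counts, trt_limits

__all__ = [
    "RandomEffectSpec",
    "PosteriorDraws",
    "GrowthPriors",
    "TsdPriors",
    "fit_growth",
    "fit_tsd",
    "growth_loglik_fn",
    "tsd_loglik_fn",
    "posterior_summary",
]

_LEVELS = ("rmu", "study_id", "clutch")
_LEVEL_ALIASES = {"rmu": "rmu", "id": "study_id", "study_id": "study_id",
                  "clutch": "clutch"}
_PARAMS = ("P", "S", "dS")


@dataclass(frozen=True)
class RandomEffectSpec:
    """Nested random-effect structure on the flexit* parameters.

    ``levels`` is a prefix of ``("rmu", "study_id", "clutch")``: the four
    admissible structures are the intercept-only model and the nested
    chains RMU, RMU/ID and RMU/ID/Clutch.  ``sd_prior_scale`` is the
    half-normal prior scale of every level SD (a single float, or a mapping
    ``(level, param) -> scale``).
    """

    levels: tuple[str, ...] = ()
    sd_prior_scale: float | dict = 1.0

    def __post_init__(self) -> None:
        if tuple(self.levels) != _LEVELS[: len(self.levels)]:
            raise ValueError(
                f"levels must be a prefix of {_LEVELS}, got {self.levels}"
            )

    @classmethod
    def parse(cls, text: str, sd_prior_scale: float | dict = 1.0) -> "RandomEffectSpec":
        """Parse ``"1"``, ``"1|RMU"``, ``"1|RMU/ID"`` or ``"1|RMU/ID/Clutch"``."""
        text = text.strip()
        if text == "1":
            return cls(levels=(), sd_prior_scale=sd_prior_scale)
        if not text.startswith("1|"):
            raise ValueError(f"cannot parse random-effect structure {text!r}")
        parts = [p.strip().lower() for p in text[2:].split("/")]
        try:
            levels = tuple(_LEVEL_ALIASES[p] for p in parts)
        except KeyError as e:
            raise ValueError(f"unknown grouping level in {text!r}") from e
        return cls(levels=levels, sd_prior_scale=sd_prior_scale)

    def scale(self, level: str, param: str) -> float:
        if isinstance(self.sd_prior_scale, dict):
            return float(self.sd_prior_scale[(level, param)])
        return float(self.sd_prior_scale)

    def __str__(self) -> str:
        if not self.levels:
            return "1"
        names = {"rmu": "RMU", "study_id": "ID", "clutch": "Clutch"}
        return "1|" + "/".join(names[l] for l in self.levels)


@dataclass
class PosteriorDraws:
    """Thinned MCMC draws plus run metadata.

    ``draws`` has one row per retained draw and one column per parameter;
    ``meta`` records burn-in, iterations, thinning, seed, acceptance rates
    and the random-effect structure so any fit can be reproduced.
    """

    draws: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws.to_numpy())):
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def flexit_params(self, row: int | pd.Series, l: float = 0.05) -> FlexitParams:
        r = self.draws.iloc[row] if isinstance(row, int) else row
        return FlexitParams(P=r["P"], S=r["S"], deltaS=r["dS"], l=l)

    def schoolfield_params(self, row: int | pd.Series) -> SchoolfieldParams:
        r = self.draws.iloc[row] if isinstance(row, int) else row
        return SchoolfieldParams(
            rho25=r["rho25"], dHA=r["dHA"], dHL=r["dHL"], T12L=r["T12L"]
        )


@dataclass(frozen=True)
class GrowthPriors:
    """Wide uniform priors for the growth norm.

    ``rho25`` is uniform on the log10 scale (it spans orders of magnitude);
    the remaining parameters are uniform on their natural scale.
    """

    log10_rho25: tuple[float, float] = (-6.5, -2.5)
    dHA: tuple[float, float] = (1.0e4, 3.0e5)
    dHL: tuple[float, float] = (-5.0e5, -1.0e4)
    T12L: tuple[float, float] = (270.0, 310.0)


@dataclass(frozen=True)
class TsdPriors:
    """Priors for the flexit* fit: P ~ U(25, 35), S ~ U(0.05, 20),
    deltaS ~ U(-S + 0.05, 20) (keeping both limb slopes positive)."""

    P: tuple[float, float] = (25.0, 35.0)
    S: tuple[float, float] = (0.05, 20.0)
    dS_max: float = 20.0
    s_min: float = 0.05  # lower bound on both S and S + deltaS


def _init_from_prior(logpost, draw_start, max_tries: int = 100):
    """Draw start points until the log-posterior is finite (at most 100)."""
    for _ in range(max_tries):
        x0 = draw_start()
        if np.isfinite(logpost(x0)):
            return x0
    raise RuntimeError(
        f"no finite log-posterior start point found in {max_tries} prior draws"
    )


# ---------------------------------------------------------------------------
# growth fit
# ---------------------------------------------------------------------------


# The growth chain's first coordinate is log10 r(30 degC) rather than
# log10 rho25: the two differ by a deterministic shear in the other three
# parameters (unit Jacobian, so the uniform prior is unchanged), and r(30)
# is what duration data actually pin down — this removes the strong
# rho25/dHA posterior ridge.
_T30K = 30.0 + 273.15


def _growth_shear(dHA: float, dHL: float, T12L: float) -> float:
    """log10 of r(30)/rho25 for given shape parameters."""
    return (
        math.log10(_T30K / 298.15)
        + (dHA / GAS_CONSTANT) * (1.0 / 298.15 - 1.0 / _T30K) / math.log(10.0)
        - np.logaddexp(0.0, (dHL / GAS_CONSTANT) * (1.0 / T12L - 1.0 / _T30K))
        / math.log(10.0)
    )


def _growth_loglik_builder(
    duration_data: list[DurationSummary],
    scl0: float,
    scl_hatch: float,
    step_min: float,
):
    """Gaussian duration likelihood, precompiled over the data.

    Returns ``f(SchoolfieldParams) -> float``; each summary contributes
    ``mean_days ~ Normal(predicted duration, sd_days / sqrt(n))``, with
    the prediction from the constant-temperature closed form or from
    trajectory integration for a recorded series (``-inf`` if the embryo
    would not hatch within the record).
    """
    data = sorted(
        duration_data,
        key=lambda d: (d.temperature if d.temperature is not None else math.inf,
                       d.label, d.mean_days),
    )
    const = [(d.temperature, d.mean_days, max(d.sd_days, 1e-6) / math.sqrt(d.n),
              math.log((d.scl_hatch or scl_hatch) / scl0))
             for d in data if d.temperature is not None]
    const_T = np.array([c[0] for c in const])
    const_mean = np.array([c[1] for c in const])
    const_se = np.array([c[2] for c in const])
    const_target = np.array([c[3] for c in const])
    series_items = []
    for d in data:
        if d.series is None:
            continue
        grid_t, grid_temp = _growth_grid(d.series, step_min)
        series_items.append(
            (grid_t, grid_temp, d.mean_days, max(d.sd_days, 1e-6) / math.sqrt(d.n),
             math.log((d.scl_hatch or scl_hatch) / scl0))
        )

    def loglik(params: SchoolfieldParams) -> float:
        ll = 0.0
        if len(const):
            r = schoolfield_rate(params, const_T)
            pred = const_target / r / MINUTES_PER_DAY
            ll += float(np.sum(-0.5 * ((const_mean - pred) / const_se) ** 2
                               - np.log(const_se)))
        for grid_t, grid_temp, mean_days, se, target in series_items:
            r = schoolfield_rate(params, grid_temp)
            dt = np.diff(grid_t)
            cumint = np.concatenate(([0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * dt)))
            if cumint[-1] < target:
                return -np.inf  # embryo would not hatch within the record
            t_hatch = _crossing_time(grid_t, cumint, target)
            pred = (t_hatch - grid_t[0]) / MINUTES_PER_DAY
            ll += -0.5 * ((mean_days - pred) / se) ** 2 - math.log(se)
        return ll

    return loglik


def growth_loglik_fn(
    duration_data: list[DurationSummary],
    scl0: float = DEFAULT_SCL0,
    scl_hatch: float = DEFAULT_SCL_HATCH_NWA,
    step_min: float = 60.0,
):
    """Per-draw log-likelihood function for growth-model comparison.

    Returns ``f(row) -> float`` evaluating the duration likelihood of
    ``duration_data`` at one posterior draw (a row with columns ``rho25,
    dHA, dHL, T12L``), for use with
    :func:`tsdnorm.model_select.posterior_model_weights`.
    """
    base = _growth_loglik_builder(duration_data, scl0, scl_hatch, step_min)

    def fn(row: pd.Series) -> float:
        return base(SchoolfieldParams(rho25=row["rho25"], dHA=row["dHA"],
                                      dHL=row["dHL"], T12L=row["T12L"]))

    return fn


def fit_growth(
    duration_data: list[DurationSummary],
    priors: GrowthPriors | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
    scl0: float = DEFAULT_SCL0,
    scl_hatch: float = DEFAULT_SCL_HATCH_NWA,
    step_min: float = 60.0,
) -> PosteriorDraws:
    """Posterior of :class:`SchoolfieldParams` given duration summaries.

    Each summary contributes a Gaussian term for its observed mean
    duration: ``mean_days ~ Normal(predicted duration, sd_days / sqrt(n))``,
    with the prediction from the closed form at constant temperature or
    from trajectory integration for a recorded series.
    """
    priors = priors or GrowthPriors()
    settings = settings or McmcSettings()
    if len(duration_data) == 0:
        raise ValueError("no duration data supplied")
    n_temps = len({d.temperature for d in duration_data if d.temperature is not None})
    n_series = sum(1 for d in duration_data if d.series is not None)
    if n_temps < 3 and n_series < 2 and n_temps + n_series < 3:
        raise ValueError(
            "growth fit needs >= 3 distinct temperatures or >= 2 series"
        )

    base_loglik = _growth_loglik_builder(duration_data, scl0, scl_hatch, step_min)

    lo = np.array([priors.log10_rho25[0], priors.dHA[0], priors.dHL[0], priors.T12L[0]])
    hi = np.array([priors.log10_rho25[1], priors.dHA[1], priors.dHL[1], priors.T12L[1]])
    _shear = _growth_shear

    def logpost(x: np.ndarray) -> float:
        if np.any(x[1:] <= lo[1:]) or np.any(x[1:] >= hi[1:]):
            return -np.inf
        log10_rho25 = x[0] - _shear(x[1], x[2], x[3])
        if not (lo[0] < log10_rho25 < hi[0]):
            return -np.inf
        params = SchoolfieldParams(
            rho25=10.0 ** log10_rho25, dHA=x[1], dHL=x[2], T12L=x[3]
        )
        return base_loglik(params)

    rng = np.random.default_rng(seed)

    def draw_start() -> np.ndarray:
        x = rng.uniform(lo, hi)
        x[0] += _shear(x[1], x[2], x[3])  # prior draw mapped to chain coords
        return x

    x0 = _init_from_prior(logpost, draw_start)
    step0 = (hi - lo) / 10.0
    chain = adaptive_mwg(logpost, x0, step0, settings, rng,
                         joint_idx=(0, 1, 2, 3))
    df = pd.DataFrame(chain.draws, columns=["log10_r30", "dHA", "dHL", "T12L"])
    shear_col = np.array([_shear(a, b, c) for a, b, c
                          in df[["dHA", "dHL", "T12L"]].to_numpy()])
    df.insert(0, "rho25", 10.0 ** (df.pop("log10_r30") - shear_col))
    meta = {
        "model": "schoolfield4",
        "seed": int(seed),
        "n_burn": settings.n_burn,
        "n_iter": settings.n_iter,
        "thin": settings.thin,
        "accept_rate": chain.accept_rate.tolist(),
        "logpost": chain.logpost,
        "scl0": scl0,
        "scl_hatch": scl_hatch,
    }
    return PosteriorDraws(draws=df, meta=meta)


# ---------------------------------------------------------------------------
# TSD fit
# ---------------------------------------------------------------------------


def _canonical_records(
    data: list[SexCountRecord], intersex: str
) -> list[SexCountRecord]:
    """Drop empty records and sort into a canonical, order-independent form."""
    kept = [r for r in data if _effective_counts(r, intersex)[1] >= 1]
    if not kept:
        raise ValueError("no records with sexed hatchlings")
    return sorted(
        kept,
        key=lambda r: (r.rmu, r.study_id, r.clutch, r.temperature,
                       r.males, r.females, r.intersex),
    )


class _TsdModel:
    """Pre-indexed data + log-posterior for the (possibly hierarchical)
    flexit* binomial model.  Natural parameter vector layout:

    ``[P, S, dS] + per level: [sigma_P, sigma_S, sigma_dS,
                               z_P (one per group), z_S ..., z_dS ...]``

    The MCMC chain runs on transformed coordinates ``[P, log S1, log S2,
    ...]`` (the two limb slopes are nearly independent given the data,
    whereas S and deltaS are strongly anti-correlated); priors remain
    uniform on S and deltaS via the change-of-variables Jacobian.
    """

    def __init__(
        self,
        data: list[SexCountRecord],
        re_spec: RandomEffectSpec,
        priors: TsdPriors,
        intersex: str = "exclude",
    ):
        self.re_spec = re_spec
        self.priors = priors
        records = _canonical_records(data, intersex)
        self.records = records
        n = len(records)
        self.fem = np.empty(n)
        self.tot = np.empty(n)
        self.temps = np.empty(n)
        for i, rec in enumerate(records):
            f, t = _effective_counts(rec, intersex)
            self.fem[i], self.tot[i], self.temps[i] = f, t, rec.temperature

        self.level_groups: list[list] = []
        self.level_index: list[np.ndarray] = []
        for level in re_spec.levels:
            if level == "clutch":
                missing = [r for r in records if not r.clutch]
                if missing:
                    labels = ", ".join(
                        f"({r.rmu}/{r.study_id} @ {r.temperature} degC)"
                        for r in missing[:5]
                    )
                    raise ValueError(
                        f"clutch random effect requested but {len(missing)} "
                        f"record(s) lack a clutch label: {labels}"
                    )
            keyfn = {
                "rmu": lambda r: (r.rmu,),
                "study_id": lambda r: (r.rmu, r.study_id),
                "clutch": lambda r: (r.rmu, r.study_id, r.clutch),
            }[level]
            keys = sorted({keyfn(r) for r in records})
            lookup = {k: i for i, k in enumerate(keys)}
            self.level_groups.append(keys)
            self.level_index.append(
                np.array([lookup[keyfn(r)] for r in records], dtype=int)
            )

        self.columns = ["P", "S", "dS"]
        for level, groups in zip(re_spec.levels, self.level_groups):
            for p in _PARAMS:
                self.columns.append(f"sigma_{level}_{p}")
            for p in _PARAMS:
                for g in groups:
                    self.columns.append(f"z_{level}_{p}_" + "/".join(g))
        self.dim = len(self.columns)
        self.sd_scales = [
            [re_spec.scale(level, p) for p in _PARAMS] for level in re_spec.levels
        ]

    def record_params(self, x: np.ndarray):
        """Per-record (P, S, dS) arrays implied by a parameter vector."""
        n = len(self.fem)
        P_rec = np.full(n, x[0])
        S_rec = np.full(n, x[1])
        dS_rec = np.full(n, x[2])
        pos = 3
        for li, groups in enumerate(self.level_groups):
            idx = self.level_index[li]
            sigmas = x[pos: pos + 3]
            pos += 3
            for arr, sigma in zip((P_rec, S_rec, dS_rec), sigmas):
                ng = len(groups)
                z = x[pos: pos + ng]
                pos += ng
                arr += sigma * z[idx]
        return P_rec, S_rec, dS_rec

    def logprior(self, x: np.ndarray) -> float:
        pr = self.priors
        P, S, dS = x[0], x[1], x[2]
        if not (pr.P[0] < P < pr.P[1]):
            return -np.inf
        if not (pr.S[0] < S < pr.S[1]):
            return -np.inf
        if not (pr.s_min - S < dS < pr.dS_max):
            return -np.inf
        lp = 0.0
        pos = 3
        for li, groups in enumerate(self.level_groups):
            for t in range(3):
                sigma = x[pos]
                pos += 1
                if sigma < 0:
                    return -np.inf
                scale = self.sd_scales[li][t]
                lp += -0.5 * (sigma / scale) ** 2
            ng = len(groups)
            z = x[pos: pos + 3 * ng]
            pos += 3 * ng
            lp += -0.5 * float(z @ z)
        return lp

    def loglik(self, x: np.ndarray) -> float:
        P_rec, S_rec, dS_rec = self.record_params(x)
        if np.any(S_rec <= 0.0) or np.any(S_rec + dS_rec <= 0.0):
            return -np.inf
        q = expit(100.0 * (self.temps - P_rec))
        p = expit(4.0 * (S_rec + dS_rec * q) * (self.temps - P_rec))
        p = np.clip(p, 1e-15, 1.0 - 1e-15)
        return float(np.sum(self.fem * np.log(p)
                            + (self.tot - self.fem) * np.log1p(-p)))

    def logpost(self, x: np.ndarray) -> float:
        lp = self.logprior(x)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglik(x)

    # -- chain-coordinate transform: x_chain = [P, log S1, log S2, rest...]
    def to_natural(self, xc: np.ndarray) -> np.ndarray:
        x = np.array(xc, dtype=float)
        s1 = math.exp(xc[1])
        s2 = math.exp(xc[2])
        x[1] = s1
        x[2] = s2 - s1
        return x

    def to_chain(self, x: np.ndarray) -> np.ndarray:
        xc = np.array(x, dtype=float)
        xc[1] = math.log(x[1])
        xc[2] = math.log(x[1] + x[2])
        return xc

    def logpost_chain(self, xc: np.ndarray) -> float:
        if abs(xc[1]) > 50.0 or abs(xc[2]) > 50.0:
            return -np.inf
        # Jacobian of (S, deltaS) -> (log S1, log S2) is S1 * S2
        return self.logpost(self.to_natural(xc)) + xc[1] + xc[2]

    def _level_layout(self):
        """(sigma indices, z slices) per level x parameter in chain coords."""
        out = []
        base = 3
        for groups in self.level_groups:
            ng = len(groups)
            sig = [base + t for t in range(3)]
            zsl = [slice(base + 3 + t * ng, base + 3 + (t + 1) * ng)
                   for t in range(3)]
            out.append((sig, zsl, ng))
            base += 3 + 3 * ng
        return out

    def interweaving_moves(self):
        """MH kernels that travel along the hierarchical-posterior ridges.

        Random-walk Metropolis mixes poorly across (a) the global-parameter
        vs group-deviation trade-off (shifting theta_global while the
        deviations compensate leaves the likelihood unchanged) and (b) the
        sigma vs z funnel (scaling sigma while z shrinks leaves the group
        effects unchanged).  For every level and every flexit* parameter we
        therefore add a translation move along (a) and a rescaling move
        along (b); both are valid Metropolis-Hastings kernels whose
        log-correction accounts for the chain-coordinate Jacobian.
        """
        moves = []
        for (sig, zsl, ng) in self._level_layout():
            for t in range(3):
                moves.append((self._translation_move(t, sig[t], zsl[t]), 0.2))
                moves.append((self._rescale_move(sig[t], zsl[t], ng), 0.5))
        return moves

    @staticmethod
    def _translation_move(t: int, sigma_idx: int, z_slice: slice):
        # theta_global += delta, z -= delta / sigma: likelihood-invariant.
        # For t in {1, 2} the global lives on a log scale in chain
        # coordinates, hence the log-Jacobian corrections.
        def move(x, rng, scale):
            delta = scale * rng.standard_normal()
            sigma = x[sigma_idx]
            if sigma <= 1e-12:
                return None
            xp = x.copy()
            corr = 0.0
            if t == 0:
                xp[0] = x[0] + delta
            elif t == 1:  # natural S shifts; both limb slopes move
                s1, s2 = math.exp(x[1]), math.exp(x[2])
                if s1 + delta <= 0 or s2 + delta <= 0:
                    return None
                xp[1] = math.log(s1 + delta)
                xp[2] = math.log(s2 + delta)
                corr = (x[1] - xp[1]) + (x[2] - xp[2])
            else:  # natural deltaS shifts; only the upper limb moves
                s2 = math.exp(x[2])
                if s2 + delta <= 0:
                    return None
                xp[2] = math.log(s2 + delta)
                corr = x[2] - xp[2]
            xp[z_slice] = x[z_slice] - delta / sigma
            return xp, corr

        return move

    @staticmethod
    def _rescale_move(sigma_idx: int, z_slice: slice, ng: int):
        # sigma *= e^eps, z *= e^-eps: group effects sigma*z unchanged;
        # |Jacobian| = e^{eps (1 - ng)}.
        def move(x, rng, scale):
            eps = scale * rng.standard_normal()
            xp = x.copy()
            xp[sigma_idx] = x[sigma_idx] * math.exp(eps)
            xp[z_slice] = x[z_slice] * math.exp(-eps)
            return xp, eps * (1.0 - ng)

        return move

    def n_free_params(self) -> int:
        """Parameter count for information criteria: the 3 global
        parameters plus one per estimated random-effect SD."""
        return 3 + 3 * len(self.re_spec.levels)


def fit_tsd(
    data: list[SexCountRecord],
    re_spec: RandomEffectSpec | str = "1",
    priors: TsdPriors | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
    intersex: str = "exclude",
) -> PosteriorDraws:
    """Posterior of flexit* parameters (and random effects) from counts.

    The hierarchical model places independent additive group deviations on
    each of P, S and deltaS: for a clutch c within study i within RMU r,
    ``theta_c = theta_global + u_r + u_{i(r)} + u_{c(i)}`` with
    ``u ~ Normal(0, sigma_level)`` and half-normal priors on the level SDs.
    Records with zero sexed hatchlings (e.g. an incubation condition where
    nothing could be sexed) are dropped before fitting.
    """
    if isinstance(re_spec, str):
        re_spec = RandomEffectSpec.parse(re_spec)
    priors = priors or TsdPriors()
    settings = settings or McmcSettings()
    model = _TsdModel(data, re_spec, priors, intersex)
    rng = np.random.default_rng(seed)

    def draw_start() -> np.ndarray:
        x = np.zeros(model.dim)
        x[0] = rng.uniform(*priors.P)
        x[1] = rng.uniform(priors.S[0], 5.0)
        x[2] = rng.uniform(max(priors.s_min - x[1], -1.0), 1.0)
        pos = 3
        for groups in model.level_groups:
            x[pos: pos + 3] = rng.uniform(0.01, 0.3, size=3)
            pos += 3
            ng = 3 * len(groups)
            x[pos: pos + ng] = 0.1 * rng.standard_normal(ng)
            pos += ng
        return x

    x0 = model.to_chain(_init_from_prior(model.logpost, draw_start))
    step0 = np.full(model.dim, 0.3)
    step0[0] = 0.1  # P
    chain = adaptive_mwg(model.logpost_chain, x0, step0, settings, rng,
                         joint_idx=(0, 1, 2),
                         extra_moves=model.interweaving_moves() or None)
    natural = np.apply_along_axis(model.to_natural, 1, chain.draws)
    df = pd.DataFrame(natural, columns=model.columns)
    meta = {
        "model": "flexit*",
        "re_structure": str(re_spec),
        "seed": int(seed),
        "n_burn": settings.n_burn,
        "n_iter": settings.n_iter,
        "thin": settings.thin,
        "intersex": intersex,
        "accept_rate": chain.accept_rate.tolist(),
        "logpost": chain.logpost,
        "k": model.n_free_params(),
        "n_records": len(model.records),
        "n_sexed": float(np.sum(model.tot)),
    }
    return PosteriorDraws(draws=df, meta=meta)


def tsd_loglik_fn(
    data: list[SexCountRecord],
    re_spec: RandomEffectSpec | str = "1",
    priors: TsdPriors | None = None,
    intersex: str = "exclude",
):
    """Per-draw log-likelihood function for model comparison.

    Returns ``f(row) -> float`` evaluating the binomial log-likelihood of
    ``data`` at one posterior draw (a row of :attr:`PosteriorDraws.draws`),
    conditional on the drawn random effects.
    """
    if isinstance(re_spec, str):
        re_spec = RandomEffectSpec.parse(re_spec)
    model = _TsdModel(data, re_spec, priors or TsdPriors(), intersex)

    def fn(row: pd.Series) -> float:
        x = np.array([row[c] for c in model.columns])
        return model.loglik(x)

    return fn


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

_SUMMARY_STATS = ("median", "mean", "se", "q2.5", "q97.5")


def _resolve_functional(df: pd.DataFrame, functional, l: float = 0.05) -> np.ndarray:
    if callable(functional):
        return np.asarray(functional(df), dtype=float)
    if isinstance(functional, str):
        if functional in df.columns:
            return df[functional].to_numpy()
        if functional in ("trt_lower", "trt_upper", "trt_width"):
            vals = np.empty(len(df))
            for i, (_, row) in enumerate(df.iterrows()):
                lim = trt_limits(
                    FlexitParams(P=row["P"], S=row["S"], deltaS=row["dS"], l=l)
                )
                vals[i] = getattr(lim, functional.removeprefix("trt_"))
            return vals
        if functional.startswith("sr@"):
            T = float(functional[3:])
            q = expit(100.0 * (T - df["P"].to_numpy()))
            slope = 4.0 * (df["S"].to_numpy() + df["dS"].to_numpy() * q)
            return expit(slope * (T - df["P"].to_numpy()))
        raise KeyError(
            f"unknown functional {functional!r}: not a draw column and not "
            "one of trt_lower/trt_upper/trt_width/sr@<T>"
        )
    raise TypeError("functional must be a column name, registered name or callable")


def posterior_summary(
    draws: PosteriorDraws | pd.DataFrame, functional, l: float = 0.05
) -> pd.Series:
    """Median, mean, SE and 95% credible bounds of a posterior functional.

    ``functional`` may be a draw column name (``"P"``), a registered
    derived quantity (``"trt_lower"``, ``"trt_upper"``, ``"trt_width"``,
    ``"sr@30.0"``) or a callable mapping the draws DataFrame to one value
    per draw.  ``se`` is the posterior standard deviation of the
    functional.
    """
    df = draws.draws if isinstance(draws, PosteriorDraws) else draws
    if len(df) == 0:
        raise ValueError("empty posterior draws")
    vals = _resolve_functional(df, functional, l=l)
    return pd.Series(
        {
            "median": float(np.median(vals)),
            "mean": float(np.mean(vals)),
            "se": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "q2.5": float(np.percentile(vals, 2.5)),
            "q97.5": float(np.percentile(vals, 97.5)),
        }
    )
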