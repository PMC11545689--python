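import numpy as np
import pytest

from tsdnorm import (
    FlexitParams,
    McmcSettings,
    SchoolfieldParams,
    SimConfig,
    TemperatureSeries,
    fit_tsd,
    gen_sexcounts,
)
from tsdnorm.datasets import east_pacific_counts, pooled_counts
from tsdnorm.hierfit import tsd_loglik_fn
from tsdnorm.model_select import posterior_model_weights


@pytest.fixture
def flexit_default() -> FlexitParams:
    """Leatherback-like TSD curve: pivot 29.49 degC, nearly symmetric."""
    return FlexitParams(P=29.49, S=2.34, deltaS=0.49)


@pytest.fixture
def growth_default() -> SchoolfieldParams:
    """Growth norm giving realistic tropical incubation durations."""
    return SchoolfieldParams(rho25=2.8e-5, dHA=7.0e4, dHL=-1.4e5, T12L=285.0)


@pytest.fixture
def short_mcmc() -> McmcSettings:
    """Reduced chain lengths for fast unit tests."""
    return McmcSettings(n_burn=500, n_iter=2000, thin=10)


@pytest.fixture
def constant_series():
    def make(temp: float, days: float = 90.0, step_min: float = 1440.0):
        times = np.arange(0.0, days * 1440.0 + 1.0, step_min)
        return TemperatureSeries(times=times, temps=np.full(times.size, temp))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20_240)


# ---------------------------------------------------------------------------
# expensive shared fits (session-scoped so each runs once)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def ep_fit_default():
    """flexit* fit (no random effects, default chain settings) to the
    packaged East Pacific constant-temperature counts."""
    return fit_tsd(east_pacific_counts(), re_spec="1", seed=1)


@pytest.fixture(scope="session")
def pooled_fit_default():
    """flexit* fit (no random effects, default chain settings) to all
    packaged sexed counts (East Pacific + Malaysian CTE records)."""
    return fit_tsd(pooled_counts(), re_spec="1", seed=1)


@pytest.fixture(scope="session")
def clutch_re_replicates():
    """Replicated clutch-effect study: simulate 12 clutches with an
    among-clutch pivotal-temperature SD of 0.3 degC (15 eggs each, spread
    across the transitional range), fit the model with and without the
    clutch random effect, and compare by posterior AICc weight.

    Returns a list of dicts with the RE-model weight and the posterior
    median of sigma_clutch_P per replicate.  Chains are shortened relative
    to the defaults to keep the 20 replicates tractable.
    """
    short = McmcSettings(n_burn=500, n_iter=2000, thin=10)
    temps = tuple(np.linspace(29.1, 29.9, 12))
    results = []
    for rep in range(20):
        cfg = SimConfig(
            n_clutches_per_study=12, eggs_per_clutch=15,
            re_sd={("clutch", "P"): 0.3}, temperatures=temps,
            seed=100 + rep,
        )
        recs = gen_sexcounts(cfg)
        n = int(sum(r.males + r.females for r in recs))
        no_re = fit_tsd(recs, re_spec="1", settings=short, seed=rep)
        with_re = fit_tsd(recs, re_spec="1|RMU/ID/Clutch", settings=short,
                          seed=rep)
        scores = posterior_model_weights(
            {
                "1": (no_re, tsd_loglik_fn(recs, "1"), no_re.meta["k"]),
                "1|RMU/ID/Clutch": (
                    with_re,
                    tsd_loglik_fn(recs, "1|RMU/ID/Clutch"),
                    with_re.meta["k"],
                ),
            },
            n=n,
        )
        results.append(
            {
                "re_weight": float(scores.loc["1|RMU/ID/Clutch", "weight_mean"]),
                "sigma_clutch_P": float(
                    np.median(with_re.draws["sigma_clutch_P"])
                ),
            }
        )
    return results
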