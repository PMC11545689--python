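"""AICc and Akaike weights, computed per posterior draw.

Models fitted to the same data are compared by the small-sample-corrected
Akaike information criterion

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)

and by Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2), the
probability that model i is the best of the compared set.  Rather than a
single plug-in value, both are evaluated at every retained MCMC draw (each
model at its own draw, paired by draw index) and reported as posterior
predictive means with across-draw standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ModelScore", "aicc", "akaike_weights", "posterior_model_weights"]


@dataclass(frozen=True)
class ModelScore:
    """Posterior-predictive AICc and Akaike weight of one model."""

    name: str
    k: int
    n: int
    aicc_mean: float
    aicc_se: float
    weight_mean: float
    weight_se: float


class SmallSampleError(ValueError):
    """n <= k + 1: the AICc small-sample correction is undefined."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise SmallSampleError(
            f"AICc requires n > k + 1 (got n={n}, k={k})"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights of a compared model set (sum to 1; overflow-safe)."""
    a = np.asarray(aiccs, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 models to compute Akaike weights")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite AICc values")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def posterior_model_weights(
    models: dict, n: int
) -> pd.DataFrame:
    """Posterior-predictive AICc and Akaike weights across models.

    Parameters
    ----------
    models : dict
        ``name -> (draws, loglik_fn, k)`` where ``draws`` is a DataFrame
        (or :class:`~tsdnorm.hierfit.PosteriorDraws`) of retained MCMC
        draws, ``loglik_fn(row) -> float`` evaluates the model's
        log-likelihood of the shared data at one draw, and ``k`` is the
        parameter count.  All models must have the same number of retained
        draws; draws are paired across models by index.
    n : int
        Sample size entering the AICc correction (number of binomial
        trials for TSD models, number of duration observations for growth
        models).

    Returns
    -------
    DataFrame indexed by model name with columns
    ``k, n, aicc_mean, aicc_se, weight_mean, weight_se``.
    """
    if len(models) < 1:
        raise ValueError("no models supplied")
    frames = {}
    for name, (draws, loglik_fn, k) in models.items():
        df = getattr(draws, "draws", draws)
        frames[name] = (df, loglik_fn, int(k))
    counts = {name: len(df) for name, (df, _, _) in frames.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"models have mismatched draw counts: {counts}")
    n_draws = next(iter(counts.values()))
    names = list(frames)

    aiccs = np.empty((n_draws, len(names)))
    for j, name in enumerate(names):
        df, loglik_fn, k = frames[name]
        for d in range(n_draws):
            aiccs[d, j] = aicc(loglik_fn(df.iloc[d]), k, n)

    if len(names) == 1:
        weights = np.ones_like(aiccs)
    else:
        delta = aiccs - aiccs.min(axis=1, keepdims=True)
        w = np.exp(-0.5 * delta)
        weights = w / w.sum(axis=1, keepdims=True)

    sem = lambda a: float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0
    rows = []
    for j, name in enumerate(names):
        rows.append(
            {
                "model": name,
                "k": frames[name][2],
                "n": int(n),
                "aicc_mean": float(aiccs[:, j].mean()),
                "aicc_se": sem(aiccs[:, j]),
                "weight_mean": float(weights[:, j].mean()),
                "weight_se": sem(weights[:, j]),
            }
        )
    return pd.DataFrame(rows).set_index("model")
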