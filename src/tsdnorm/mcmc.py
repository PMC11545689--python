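"""Adaptive Metropolis-within-Gibbs sampler.

A deliberately simple, fully seeded component-wise random-walk Metropolis
sampler.  Proposal standard deviations are adapted in batches during
burn-in only (Roberts & Rosenthal style diminishing adaptation towards the
0.44 component-wise acceptance optimum); after burn-in the scales are
frozen, so the retained chain is a valid time-homogeneous Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["McmcSettings", "ChainResult", "adaptive_mwg"]


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length settings: defaults are 1000 burn-in iterations,
    10,000 sampling iterations and a thinning of 10 (1000 retained draws),
    which keeps autocorrelation in the retained chain low."""

    n_burn: int = 1000
    n_iter: int = 10000
    thin: int = 10
    adapt_batch: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_burn < 0 or self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("invalid MCMC settings")
        if self.n_iter % self.thin != 0:
            raise ValueError("n_iter must be a multiple of thin")


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_iter // thin, d)
    accept_rate: np.ndarray  # per-component, post-burn-in
    logpost: np.ndarray  # log-posterior at each retained draw
    step_sizes: np.ndarray  # frozen proposal SDs


def adaptive_mwg(
    logpost,
    x0: np.ndarray,
    step0: np.ndarray,
    settings: McmcSettings,
    rng: np.random.Generator,
    joint_idx=None,
    extra_moves=None,
) -> ChainResult:
    """Run one component-wise adaptive Metropolis chain.

    ``logpost`` must return ``-inf`` outside the support (hard priors are
    handled by rejection).  Fully deterministic given ``rng``'s state.

    ``joint_idx`` optionally names a block of components (e.g. the global
    curve parameters) that additionally receives one joint
    multivariate-normal proposal per sweep, with covariance estimated from
    the burn-in history and frozen afterwards; this speeds mixing when the
    block is correlated in the posterior.

    ``extra_moves`` is an optional list of ``(propose, init_scale)`` pairs
    for specialised Metropolis-Hastings kernels (e.g. interweaving moves
    along hierarchical-model ridges).  ``propose(x, rng, scale)`` returns
    ``(x_proposed, log_correction)`` — the correction being the log of the
    proposal-asymmetry/Jacobian factor entering the acceptance ratio — or
    ``None`` for an immediate rejection.  Each move's scale is adapted
    during burn-in like the component steps.
    """
    x = np.array(x0, dtype=float)
    d = x.size
    step = np.array(step0, dtype=float)
    if step.size != d or np.any(step <= 0):
        raise ValueError("step0 must be positive and match x0 in length")
    log_step = np.log(step)
    lp = float(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the start point")

    if joint_idx is not None:
        joint_idx = np.asarray(joint_idx, dtype=int)
        dj = joint_idx.size
        joint_hist = []
        joint_chol = None
        joint_scale = 2.38 / np.sqrt(dj)

    n_extra = len(extra_moves) if extra_moves else 0
    if n_extra:
        extra_fns = [m[0] for m in extra_moves]
        extra_log_scale = np.log([m[1] for m in extra_moves])
        extra_batch_acc = np.zeros(n_extra)

    n_keep = settings.n_iter // settings.thin
    draws = np.empty((n_keep, d))
    lps = np.empty(n_keep)
    batch_acc = np.zeros(d)
    batch_n = 0
    batch_idx = 0
    post_acc = np.zeros(d)
    post_n = 0
    keep_row = 0

    total = settings.n_burn + settings.n_iter
    for it in range(total):
        burn = it < settings.n_burn
        for j in range(d):
            prop = x[j] + np.exp(log_step[j]) * rng.standard_normal()
            old = x[j]
            x[j] = prop
            lp_prop = float(logpost(x))
            if np.log(rng.uniform()) < lp_prop - lp:
                lp = lp_prop
                if burn:
                    batch_acc[j] += 1
                else:
                    post_acc[j] += 1
            else:
                x[j] = old
        if joint_idx is not None:
            if burn:
                joint_hist.append(x[joint_idx].copy())
            if joint_chol is not None:
                prop = x.copy()
                prop[joint_idx] = x[joint_idx] + joint_scale * (
                    joint_chol @ rng.standard_normal(dj)
                )
                lp_prop = float(logpost(prop))
                if np.log(rng.uniform()) < lp_prop - lp:
                    x = prop
                    lp = lp_prop
        for m in range(n_extra):
            out = extra_fns[m](x, rng, np.exp(extra_log_scale[m]))
            if out is None:
                continue
            prop, log_corr = out
            lp_prop = float(logpost(prop))
            if np.log(rng.uniform()) < lp_prop - lp + log_corr:
                x = prop
                lp = lp_prop
                if burn:
                    extra_batch_acc[m] += 1
        if burn:
            batch_n += 1
            if batch_n == settings.adapt_batch:
                batch_idx += 1
                delta = min(0.25, 1.0 / np.sqrt(batch_idx))
                rate = batch_acc / settings.adapt_batch
                log_step += np.where(rate > settings.target_accept, delta, -delta)
                batch_acc[:] = 0.0
                batch_n = 0
                if n_extra:
                    extra_rate = extra_batch_acc / settings.adapt_batch
                    extra_log_scale += np.where(
                        extra_rate > 0.3, delta, -delta
                    )
                    extra_batch_acc[:] = 0.0
                if joint_idx is not None and len(joint_hist) >= 10 * dj:
                    cov = np.cov(np.asarray(joint_hist[len(joint_hist) // 2:]).T)
                    cov = np.atleast_2d(cov) + 1e-10 * np.eye(dj)
                    try:
                        joint_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        joint_chol = None
        else:
            post_n += 1
            if (it - settings.n_burn + 1) % settings.thin == 0:
                draws[keep_row] = x
                lps[keep_row] = lp
                keep_row += 1

    return ChainResult(
        draws=draws,
        accept_rate=post_acc / max(post_n, 1),
        logpost=lps,
        step_sizes=np.exp(log_step),
    )
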