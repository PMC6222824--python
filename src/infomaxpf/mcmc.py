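"""Semiadaptive Metropolis–Hastings sampling of the posterior.

A Gaussian random-walk MH chain targets exp(log posterior) over the free
parameter vector.  In the closed-loop setting the proposal covariance is
adapted *between trials only* — never within a chain — by scaling the
previous trial's sample covariance with the classic Haario factor
s_d = 2.38²/d (plus a small jitter).  Adapting between trials is sound
because the posterior changes by only a single-trial likelihood term per
trial, so last trial's samples are a good template for this trial's scale.

The flat box prior over the lapse parameters is enforced for free: a
proposal outside the box has log posterior −inf and is always rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import Dataset, ModelParams, ParamLayout, PriorSpec, log_posterior

__all__ = [
    "SampleSet",
    "mh_chain",
    "adapt_proposal",
    "posterior_expectation",
    "HAARIO_FACTOR",
]

HAARIO_FACTOR = 2.38 ** 2
_FALLBACK_SCALE = 0.1  # SD of the scaled-identity fallback proposal
_JITTER = 1e-6


@dataclass(frozen=True)
class SampleSet:
    """Post-burn-in MH samples of the free parameter vector."""

    samples: np.ndarray  # (M, n_free)
    log_post_values: np.ndarray  # (M,)
    acceptance_rate: float
    proposal_cov_used: np.ndarray
    layout: ParamLayout | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def cov(self) -> np.ndarray:
        return np.cov(self.samples, rowvar=False, ddof=1)

    def params_iter(self):
        if self.layout is None:
            raise ValueError("SampleSet has no parameter layout attached")
        for row in self.samples:
            yield self.layout.unpack(row)


def mh_chain(
    log_density: Callable[[np.ndarray], float],
    init: np.ndarray,
    proposal_cov: np.ndarray,
    n_samples: int = 1000,
    burn_in: int | None = None,
    seed: int | np.random.Generator = 0,
    layout: ParamLayout | None = None,
) -> SampleSet:
    """Gaussian random-walk Metropolis–Hastings chain.

    Parameters
    ----------
    log_density : callable
        Unnormalized log target density of the free parameter vector; may
        return −inf to signal zero support.
    init : array
        Starting point; must have finite log density.
    proposal_cov : array
        PSD covariance of the Gaussian proposal.
    n_samples : int
        Number of post-burn-in samples returned (default 1,000).
    burn_in : int, optional
        Fresh draws discarded before recording; defaults to n_samples // 2.
    seed : int or numpy Generator
        Randomness source; the chain is deterministic given the seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in is None:
        burn_in = n_samples // 2
    init = np.asarray(init, dtype=float)
    dim = init.shape[0]
    lp0 = float(log_density(init))
    if not np.isfinite(lp0):
        raise ValueError("MH chain initialized outside the target support")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proposal_cov = np.asarray(proposal_cov, dtype=float)
    try:
        chol = np.linalg.cholesky(proposal_cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(proposal_cov + _JITTER * np.eye(dim))

    total = burn_in + n_samples
    # draw all proposal innovations and uniforms up front (deterministic)
    steps = rng.standard_normal((total, dim)) @ chol.T
    log_us = np.log(rng.random(total))

    samples = np.empty((n_samples, dim))
    log_posts = np.empty(n_samples)
    current, lp_cur = init.copy(), lp0
    accepted = 0
    for i in range(total):
        prop = current + steps[i]
        lp_prop = float(log_density(prop))
        if log_us[i] < lp_prop - lp_cur:
            current, lp_cur = prop, lp_prop
            accepted += 1
        if i >= burn_in:
            samples[i - burn_in] = current
            log_posts[i - burn_in] = lp_cur
    return SampleSet(
        samples=samples,
        log_post_values=log_posts,
        acceptance_rate=accepted / total,
        proposal_cov_used=proposal_cov,
        layout=layout,
    )


def posterior_log_density(
    data: Dataset, prior: PriorSpec, layout: ParamLayout
) -> Callable[[np.ndarray], float]:
    """Log posterior over the free parameter vector, for use as an MH target.

    A lean closure equivalent to ``log_posterior(layout.unpack(vec), ...)``
    but without per-call parameter-object construction: the MH chain calls
    this tens of thousands of times per experiment.
    """
    phi = data.phi
    y = data.y
    t = y.shape[0]
    rows = np.arange(t)
    k, m = layout.n_categories, layout.n_features
    nw = layout.n_weights
    free = layout.free_categories
    nu = layout.n_lapse
    lo, hi = prior.lapse_lower, prior.lapse_upper
    sd2 = prior.weight_sd ** 2
    prior_const = -0.5 * nw * np.log(2 * np.pi * sd2)

    def log_density(vec: np.ndarray) -> float:
        w = vec[:nw]
        lp = prior_const - 0.5 * (w @ w) / sd2
        if nu:
            u = vec[nw:]
            if np.any(u < lo) or np.any(u > hi):
                return -np.inf
        if t == 0:
            return float(lp)
        v = np.zeros((t, k))
        v[:, free] = phi @ w.reshape(k - 1, m).T
        vmax = v.max(axis=1)
        log_z = vmax + np.log(np.exp(v - vmax[:, None]).sum(axis=1))
        log_q_y = v[rows, y] - log_z
        if nu:
            u_full = np.full(k, u[0]) if nu == 1 else u
            e_sum = np.exp(u_full).sum()
            ll = np.logaddexp(log_q_y, u_full[y]).sum() - t * np.log1p(e_sum)
        else:
            ll = log_q_y.sum()
        return float(lp + ll)

    return log_density


def sample_posterior(
    data: Dataset,
    prior: PriorSpec,
    layout: ParamLayout,
    init: ModelParams | None = None,
    proposal_cov: np.ndarray | None = None,
    n_samples: int = 1000,
    burn_in: int | None = None,
    seed: int | np.random.Generator = 0,
) -> SampleSet:
    """Convenience wrapper: MH chain targeting the model posterior."""
    if init is None:
        init = layout.default_params()
    if proposal_cov is None:
        proposal_cov = default_proposal(layout.n_free)
    return mh_chain(
        posterior_log_density(data, prior, layout),
        layout.pack(init),
        proposal_cov,
        n_samples=n_samples,
        burn_in=burn_in,
        seed=seed,
        layout=layout,
    )


def default_proposal(dim: int) -> np.ndarray:
    return _FALLBACK_SCALE ** 2 * np.eye(dim) + _JITTER * np.eye(dim)


def adapt_proposal(previous: SampleSet, dim: int | None = None) -> np.ndarray:
    """Between-trial proposal adaptation: s_d·Cov(previous samples) + εI
    with the Haario scaling s_d = 2.38²/d.

    Falls back to a scaled identity when the previous samples are too few or
    degenerate (near-zero covariance).
    """
    if dim is None:
        dim = previous.samples.shape[1]
    if previous.n_samples <= dim or np.unique(
        previous.samples, axis=0
    ).shape[0] <= dim:
        return default_proposal(dim)
    cov = previous.cov()
    cov = np.atleast_2d(cov)
    if not np.all(np.isfinite(cov)) or np.trace(cov) <= 1e-12:
        return default_proposal(dim)
    return (HAARIO_FACTOR / dim) * cov + _JITTER * np.eye(dim)


def posterior_expectation(samples: SampleSet, f: Callable[[np.ndarray], np.ndarray]):
    """Monte-Carlo posterior expectation (1/M) Σ f(θ_m) over free vectors."""
    if samples.n_samples == 0:
        raise ValueError("empty sample set")
    vals = np.asarray([f(row) for row in samples.samples], dtype=float)
    return vals.mean(axis=0)
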