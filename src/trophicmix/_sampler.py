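"""Adaptive component-wise Metropolis sampler, vectorized over chains.

All Bayesian models in this package are low-dimensional (≤ 16 free
parameters) with cheap likelihoods expressed through sufficient
statistics, so a random-walk Metropolis scheme with per-parameter
proposal scales mixes well.  Scales adapt toward a target acceptance
rate during an initial adaptation window (diminishing-adaptation
schedule) and are frozen before any retained draw, keeping the retained
portion of each chain Markovian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MCMCSettings:
    """Chain geometry: ``chains × (iterations − burn_in)/thin`` retained draws."""

    chains: int = 3
    adapt: int = 10_000
    iterations: int = 500_000
    burn_in: int = 100_000
    thin: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")
        if self.chains < 2:
            raise ValueError("need ≥ 2 chains for convergence diagnostics")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin

    def with_seed(self, seed: int | None) -> "MCMCSettings":
        return MCMCSettings(self.chains, self.adapt, self.iterations,
                            self.burn_in, self.thin, seed)


#: Settings mirroring the published trophic-position runs (3 × 500k).
PUBLISHED_TP_PROFILE = MCMCSettings(chains=3, adapt=10_000,
                                    iterations=500_000, burn_in=100_000,
                                    thin=100)
#: Settings mirroring the published mixing-model runs (3 × 100k).
PUBLISHED_MIX_PROFILE = MCMCSettings(chains=3, adapt=10_000,
                                     iterations=100_000, burn_in=50_000,
                                     thin=50)
#: Desk-scale profile for tests and quick exploration.
FAST_PROFILE = MCMCSettings(chains=3, adapt=5_000, iterations=20_000,
                            burn_in=5_000, thin=10)

PROFILES = {"published": PUBLISHED_TP_PROFILE,
            "published-mix": PUBLISHED_MIX_PROFILE,
            "fast": FAST_PROFILE}


def run_metropolis(
    logpost,
    init: np.ndarray,
    settings: MCMCSettings,
    rng: np.random.Generator,
    step0: float | np.ndarray = 0.1,
    target_accept: float = 0.25,
    blocks: list[list[int]] | None = None,
):
    """Sample ``logpost`` starting from per-chain states ``init`` (C × D).

    ``logpost`` must map a (C, D) state matrix to a length-C vector of
    unnormalized log posterior densities (−inf outside the support).
    Parameters are updated jointly within each block of ``blocks``
    (default: one block per parameter), each block carrying a per-chain
    adaptive scale multiplying per-parameter base steps.

    Returns ``(draws, info)`` where ``draws`` has shape
    (chains, n_kept, D) and ``info`` carries acceptance rates and the
    final proposal scales.
    """
    X = np.array(init, dtype=float)
    if X.ndim != 2:
        raise ValueError("init must be (chains, dim)")
    C, D = X.shape
    if C != settings.chains:
        raise ValueError("init rows must equal settings.chains")
    lp = np.asarray(logpost(X), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial state has non-finite log posterior")

    if blocks is None:
        blocks = [[d] for d in range(D)]
    base_step = np.broadcast_to(np.asarray(step0, float), (D,)).copy() \
        if not np.isscalar(step0) else np.full(D, float(step0))
    nb = len(blocks)
    log_scale = np.zeros((C, nb))
    adapt_until = min(settings.adapt, settings.burn_in)

    n_keep = settings.n_draws_per_chain
    draws = np.empty((C, n_keep, D))
    acc_count = np.zeros((C, nb))
    k = 0
    # pre-drawn innovations per iteration, consumed block by block
    for t in range(settings.iterations):
        adapting = t < adapt_until
        gamma = 0.5 / (1.0 + t) ** 0.6 if adapting else 0.0
        noise = rng.standard_normal((D, C))
        log_u = np.log(rng.random((nb, C)))
        for b, cols in enumerate(blocks):
            prop = X.copy()
            scale = np.exp(log_scale[:, b])
            for d in cols:
                prop[:, d] += base_step[d] * scale * noise[d]
            lp_prop = np.asarray(logpost(prop), dtype=float)
            accept = log_u[b] < lp_prop - lp
            if accept.any():
                X[accept] = prop[accept]
                lp = np.where(accept, lp_prop, lp)
            if adapting:
                log_scale[:, b] += gamma * (accept - target_accept)
            else:
                acc_count[:, b] += accept
        if t >= settings.burn_in and (t - settings.burn_in) % settings.thin == 0:
            draws[:, k, :] = X
            k += 1
    assert k == n_keep
    post_adapt = settings.iterations - adapt_until
    info = {
        "accept_rate": acc_count / max(post_adapt, 1),
        "scales": np.exp(log_scale),
        "blocks": blocks,
    }
    return draws, info


def normal_suffstats(x: np.ndarray) -> tuple[int, float, float]:
    """(n, Σx, Σx²) for O(1) Normal log-likelihood evaluation."""
    x = np.asarray(x, dtype=float)
    return len(x), float(x.sum()), float(np.sum(x * x))


def normal_loglik(n, s1, s2, mu, sigma, include_const: bool = False):
    """Σᵢ log N(xᵢ; μ, σ) from sufficient statistics (vectorized in μ, σ)."""
    ll = -n * np.log(sigma) - (s2 - 2.0 * mu * s1 + n * mu * mu) / (2.0 * sigma**2)
    if include_const:
        ll = ll - 0.5 * n * np.log(2.0 * np.pi)
    return ll
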