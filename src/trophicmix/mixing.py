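"""Bayesian diet mixing model with process and residual error.

A consumer's tracer values are a proportion-weighted combination of
source signatures shifted by trophic discrimination:

    δ_jt ~ Normal(Σₖ pₖ(μ_kt + μΔ_kt), √(ε_t·Σₖ pₖ²(σ_kt² + σΔ_kt²)))

with diet proportions p on the simplex under a Dirichlet(1,…,1) prior
and a per-tracer residual multiplier ε_t ≥ 1 (Uniform(1, 25)) inflating
the process variance, so the process-only model is nested at ε = 1.
Models are compared by the deviance information criterion (DIC) and
consumers are screened against the mixing polygon (convex hull of
TDF-corrected source means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPoint, Point

from ._sampler import (FAST_PROFILE, MCMCSettings, normal_loglik,
                       normal_suffstats, run_metropolis)
from .baselines import TDFSpec
from .dataset import IsotopeSample
from .diagnostics import RHAT_LIMIT, diagnose, gelman_rubin

EPS_LO, EPS_HI = 1.0, 25.0  # residual-multiplier prior support


@dataclass(frozen=True)
class SourceSpec:
    """One food source: tracer moments plus the TDF reaching the consumer."""

    source_id: str
    mean_dC: float
    sd_dC: float
    mean_dN: float
    sd_dN: float
    n: int
    tdf: TDFSpec

    def __post_init__(self) -> None:
        if self.sd_dC < 0 or self.sd_dN < 0:
            raise ValueError("source SDs must be ≥ 0")
        if self.n < 1:
            raise ValueError("source n must be ≥ 1")


@dataclass(frozen=True)
class DietSources:
    sources: tuple[SourceSpec, ...]

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("need ≥ 2 sources")
        ids = [s.source_id for s in self.sources]
        if len(set(ids)) != len(ids):
            raise ValueError("source ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [s.source_id for s in self.sources]

    def __len__(self) -> int:
        return len(self.sources)

    def corrected_means(self) -> np.ndarray:
        """Source means shifted by their TDF means, shape (K, 2)."""
        return np.array([
            [s.mean_dC + s.tdf.mean_dC, s.mean_dN + s.tdf.mean_dN]
            for s in self.sources
        ])


@dataclass(frozen=True)
class DietPosterior:
    """Posterior draws of diet proportions with summaries and DIC."""

    consumer_id: str
    source_ids: tuple[str, ...]
    p_chains: np.ndarray = field(repr=False)      # (chains, n_kept, K)
    eps_chains: np.ndarray = field(repr=False)    # (chains, n_kept, 2)
    deviance_draws: np.ndarray = field(repr=False)
    deviance_at_mean: float
    rhat_max: float
    converged: bool
    diagnostics: pd.DataFrame = field(repr=False)
    warnings: tuple[str, ...] = ()

    @property
    def p_draws(self) -> np.ndarray:
        """Merged draws, (n_total, K); every row sums to 1."""
        return self.p_chains.reshape(-1, self.p_chains.shape[-1])

    @property
    def resid_draws(self) -> np.ndarray:
        return self.eps_chains.reshape(-1, 2)

    @property
    def dic(self) -> float:
        mean_dev = float(self.deviance_draws.mean())
        pd_eff = mean_dev - self.deviance_at_mean
        return mean_dev + pd_eff

    def summary(self) -> pd.DataFrame:
        """Per-source mean, KDE mode, and equal-tailed 95 % CI."""
        rows = []
        p = self.p_draws
        for k, sid in enumerate(self.source_ids):
            d = p[:, k]
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({"source": sid, "mean": float(d.mean()),
                         "mode": _kde_mode(d), "ci_lo": float(lo),
                         "ci_hi": float(hi)})
        return pd.DataFrame(rows)

    def proportion(self, source_id: str, stat: str = "mean") -> float:
        row = self.summary().set_index("source").loc[source_id]
        return float(row[stat])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table (consumer, draw, source, p)."""
        p = self.p_draws
        n, K = p.shape
        return pd.DataFrame({
            "consumer": self.consumer_id,
            "draw": np.repeat(np.arange(n), K),
            "source": np.tile(np.array(self.source_ids), n),
            "p": p.ravel(),
        })


def _kde_mode(draws: np.ndarray) -> float:
    """Density peak over [0, 1] using a Silverman-bandwidth Gaussian KDE."""
    if np.std(draws) < 1e-9:
        return float(np.mean(draws))
    kde = gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, 512)
    return float(grid[int(np.argmax(kde(grid)))])


def _softmax_simplex(z: np.ndarray) -> np.ndarray:
    """Map (C, K−1) unconstrained coordinates to (C, K) simplex points."""
    full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def fit_mixing(
    consumer: list[IsotopeSample],
    sources: DietSources,
    mcmc: MCMCSettings = FAST_PROFILE,
    seed: int | np.random.Generator | None = None,
    consumer_id: str | None = None,
) -> DietPosterior:
    """Sample diet proportions and residual multipliers by MCMC."""
    if len(consumer) < 2:
        raise ValueError("need ≥ 2 consumer individuals")
    rng = np.random.default_rng(mcmc.seed if seed is None else seed)
    K = len(sources)
    cC = np.array([s.d13C for s in consumer])
    cN = np.array([s.d15N for s in consumer])
    stats = {"C": normal_suffstats(cC), "N": normal_suffstats(cN)}
    mu = sources.corrected_means()                      # (K, 2) TDF-corrected
    var = np.array([
        [s.sd_dC**2 + s.tdf.sd_dC**2, s.sd_dN**2 + s.tdf.sd_dN**2]
        for s in sources.sources
    ])                                                   # (K, 2) process var
    var = np.maximum(var, 1e-12)

    warnings: list[str] = []
    consumer_mean = (float(cC.mean()), float(cN.mean()))
    if not polygon_check(consumer_mean, sources):
        warnings.append(
            "consumer mean lies outside the mixing polygon of TDF-corrected "
            "source means; some important source may be missing"
        )

    def unpack(theta: np.ndarray):
        p = _softmax_simplex(theta[:, : K - 1])
        eps = theta[:, K - 1: K + 1]
        return p, eps

    def loglik(p: np.ndarray, eps: np.ndarray, include_const: bool):
        m = p @ mu                                   # (C, 2) mixture means
        process = (p * p) @ var                       # (C, 2)
        lp = normal_loglik(*stats["C"], m[:, 0],
                           np.sqrt(eps[:, 0] * process[:, 0]), include_const)
        lp = lp + normal_loglik(*stats["N"], m[:, 1],
                                np.sqrt(eps[:, 1] * process[:, 1]), include_const)
        return lp

    def logpost(theta: np.ndarray) -> np.ndarray:
        p, eps = unpack(theta)
        ok = np.all((eps >= EPS_LO) & (eps <= EPS_HI), axis=1)
        eps_safe = np.clip(eps, EPS_LO, EPS_HI)
        log_jac = np.sum(np.log(np.maximum(p, 1e-300)), axis=1)
        lp = log_jac + loglik(p, eps_safe, include_const=False)
        return np.where(ok, lp, -np.inf)

    C = mcmc.chains
    init = np.zeros((C, K + 1))
    init[:, : K - 1] = 0.3 * rng.standard_normal((C, K - 1))
    init[:, K - 1] = np.linspace(1.2, 4.0, C)
    init[:, K] = np.linspace(1.2, 4.0, C)[::-1]
    step0 = np.concatenate([np.full(K - 1, 0.3), [0.3, 0.3]])
    blocks = [list(range(K - 1)), [K - 1, K]]
    draws, _ = run_metropolis(logpost, init, mcmc, rng, step0=step0,
                              blocks=blocks)

    n_kept = draws.shape[1]
    p_chains = np.empty((C, n_kept, K))
    eps_chains = draws[:, :, K - 1: K + 1].copy()
    for c in range(C):
        p_chains[c] = _softmax_simplex(draws[c, :, : K - 1])

    # per-draw deviance (with constants) for DIC
    p_flat = p_chains.reshape(-1, K)
    eps_flat = eps_chains.reshape(-1, 2)
    dev = -2.0 * loglik(p_flat, eps_flat, include_const=True)
    p_bar = p_flat.mean(axis=0)[None, :]
    eps_bar = eps_flat.mean(axis=0)[None, :]
    dev_at_mean = float(-2.0 * loglik(p_bar, eps_bar, include_const=True)[0])

    diag_params = {f"p[{sid}]": p_chains[:, :, k]
                   for k, sid in enumerate(sources.ids)}
    diag = diagnose(diag_params, model=f"mix:{consumer_id or 'consumer'}")
    rhat_max = max(gelman_rubin(p_chains[:, :, k]) for k in range(K))
    return DietPosterior(
        consumer_id or consumer[0].taxon_id, tuple(sources.ids),
        p_chains, eps_chains, dev, dev_at_mean, rhat_max,
        bool(rhat_max < RHAT_LIMIT), diag, tuple(warnings),
    )


def dic(post: DietPosterior) -> float:
    """DIC = mean deviance + pD, pD = mean deviance − deviance at the mean."""
    return post.dic


def _pooled_moments(vals: list[tuple[float, float, int]]):
    ns = np.array([n for _, _, n in vals], float)
    m = np.array([mu for mu, _, _ in vals])
    sd = np.array([s for _, s, _ in vals])
    N = ns.sum()
    mbar = float(np.sum(ns * m) / N)
    if N > 1:
        ss = np.sum((ns - 1) * sd**2) + np.sum(ns * (m - mbar) ** 2)
        sbar = float(np.sqrt(ss / (N - 1)))
    else:
        sbar = 0.0
    return mbar, sbar, int(N)


def pool_source_specs(specs: list[SourceSpec], new_id: str) -> SourceSpec:
    """n-weighted pooled moments (within + between variance) of sources."""
    mC, sC, N = _pooled_moments([(s.mean_dC, s.sd_dC, s.n) for s in specs])
    mN, sN, _ = _pooled_moments([(s.mean_dN, s.sd_dN, s.n) for s in specs])
    tC, tsC, _ = _pooled_moments([(s.tdf.mean_dC, s.tdf.sd_dC, s.n) for s in specs])
    tN, tsN, _ = _pooled_moments([(s.tdf.mean_dN, s.tdf.sd_dN, s.n) for s in specs])
    return SourceSpec(new_id, mC, sC, mN, sN, N,
                      TDFSpec(tC, tsC, tN, tsN, "pooled"))


def pool_sources(sources: DietSources, merge_spec: dict[str, list[str]]) -> DietSources:
    """Merge guild sources a priori into pooled sources.

    Pooled tracer moments are the n-weighted pooled moments of the members
    (within + between variance); the pooled TDF combines member TDFs the
    same way.  Sources not named in ``merge_spec`` pass through unchanged.
    """
    claimed: list[str] = [m for members in merge_spec.values() for m in members]
    if len(claimed) != len(set(claimed)):
        raise ValueError("merge groups overlap")
    by_id = {s.source_id: s for s in sources.sources}
    unknown = [m for m in claimed if m not in by_id]
    if unknown:
        raise KeyError(f"unknown source(s) in merge_spec: {unknown}")
    out: list[SourceSpec] = []
    merged_members = set(claimed)
    for new_id, members in merge_spec.items():
        out.append(pool_source_specs([by_id[m] for m in members], new_id))
    for s in sources.sources:
        if s.source_id not in merged_members:
            out.append(s)
    return DietSources(tuple(out))


def combine_posterior(post: DietPosterior, groups: dict[str, list[str]]) -> DietPosterior:
    """Sum member proportions draw-wise under a partition of the sources."""
    claimed = [m for members in groups.values() for m in members]
    if sorted(claimed) != sorted(post.source_ids):
        raise ValueError("groups must partition the fitted source list exactly")
    idx = {sid: k for k, sid in enumerate(post.source_ids)}
    K_new = len(groups)
    C, n_kept, _ = post.p_chains.shape
    p_new = np.zeros((C, n_kept, K_new))
    for j, (_, members) in enumerate(groups.items()):
        cols = [idx[m] for m in members]
        p_new[:, :, j] = post.p_chains[:, :, cols].sum(axis=2)
    diag_params = {f"p[{gid}]": p_new[:, :, j]
                   for j, gid in enumerate(groups)}
    diag = diagnose(diag_params, model=f"mix:{post.consumer_id}(combined)")
    return DietPosterior(
        post.consumer_id, tuple(groups), p_new, post.eps_chains,
        post.deviance_draws, post.deviance_at_mean, post.rhat_max,
        post.converged, diag, post.warnings,
    )


def polygon_check(
    consumer_mean: tuple[float, float], sources: DietSources
) -> bool:
    """True iff the consumer mean lies in the TDF-corrected source hull.

    With ≥ 3 sources the test is point-in-convex-hull (closed: boundary
    counts as inside).  With 2 sources it degenerates to per-tracer
    interval containment.
    """
    pts = sources.corrected_means()
    x, y = consumer_mean
    if len(pts) < 3:
        return bool(
            pts[:, 0].min() - 1e-9 <= x <= pts[:, 0].max() + 1e-9
            and pts[:, 1].min() - 1e-9 <= y <= pts[:, 1].max() + 1e-9
        )
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    return bool(hull.buffer(1e-9).covers(Point(x, y)))
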