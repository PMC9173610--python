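# Methods

## Scope and data model

The package models a coastal food web from per-individual δ13C and δ15N
measurements (‰ vs VPDB and atmospheric N2). The community container is a
flat table of individuals (taxon, taxonomic class, tracers, %C, %N); all
summaries use the sample SD (n−1). The C/N < 4 lipid screen is reported as a
warning, never applied as a correction or exclusion — the surveyed samples
all passed it, and lipid-normalization models are out of scope.

Because the study's raw individuals are not public, `study.py` encodes the
published per-taxon means ± SD with sample sizes, the guild summaries, and
literature trophic levels. Individuals are *reconstituted* from those
moments by moment-matched Normal draws: a seeded Normal sample rescaled so
its sample mean and SD equal the printed values exactly. The printed summary
is the entirety of the available information, so matching it exactly keeps
emulation results from depending on reconstitution noise; the shape
assumption (normality) is the same one the models make. The scallop sample
size (n = 21) is derived from the published totals (216 individuals, 195 in
the consumer rows).

## Trophic-position model

Likelihood and priors are given in the README. Choices the source material
left open, fixed here:

- TP prior Uniform(λ, 10): wide enough for tertiary consumers, bounded for
  sampler stability. α ~ Beta(1, 1).
- Baseline means get Normal priors centred on the observed baseline means
  with SD 10 ‰ (effectively data-driven); all SDs (four baseline, two
  consumer) get half-Normal(0, 5 ‰) priors.
- A TDF with zero SD pins the corresponding Δ at its mean, which together
  with `fix_alpha` exposes the closed-form degenerate limit
  TP = λ + (δ15N − α·μN_b − (1−α)·μN_p)/ΔN used as a test oracle.

The pelagic baseline is retro-calculated from sprat (a strictly
zooplanktivorous fish): each of 50 pseudo-individuals is one value resampled
(with replacement, via a per-replicate subsample of 7) from the sprat sample
minus one draw from the Actinopterygii TDF distribution. This reproduces the
published pelagic-baseline means (−20.4, 8.6 ‰). Its SD is
√(sd_consumer² + sd_TDF²) ≈ 0.6–0.7 ‰, larger than the published ±0.2/0.3 —
the original tool's resampling semantics are underdocumented, and this
interpretation is recorded as a choice, not as the original authors' intent.
One visible consequence: posterior TP credible intervals here are somewhat
wider than the published ones, while posterior means match.

## Guild clustering

Per replicate: resample m = 4 individuals with replacement per taxon (the
minimum sample size in the emulated community), use the resample mean as the
taxon's 2-D coordinate, z-score both coordinates across taxa (ddof = 1)
*within the replicate*, and compute Euclidean distances; B = 500 matrices
are averaged element-wise. Using the resample mean (rather than the four raw
points) gives an order-invariant fixed-dimension representation;
standardizing per replicate treats each replicate as a complete
re-realization of the procedure. Both choices are parameterized (m, B).
UPGMA is scipy's average linkage; cutting at k = 6 reproduces the published
six guilds exactly on the emulated community. `k="auto"` picks the largest
relative jump between successive merge heights and exposes the height
profile for inspection. The averaged matrix is a dissimilarity (symmetric,
zero diagonal, non-negative); the triangle inequality is not asserted, since
averaging need not preserve it.

## Diet mixing model

Dirichlet(1,…,1) prior on p, sampled through a softmax transform of K−1
unconstrained coordinates (log-Jacobian Σ log p_k), so every retained draw
is exactly on the simplex. Residual error enters as per-tracer multipliers
ε_t on the process variance with Uniform(1, 25) priors: multiplicative form
keeps the variance positive and nests the process-only model at ε = 1.
Summaries report the posterior mean, the KDE mode (Gaussian kernel,
Silverman bandwidth, 512-point grid on [0, 1]) and the equal-tailed 95 % CI
per source — the published tables label the central value a mode while the
text calls the same numbers means; both are emitted and the headline
comparisons use the mean. DIC = D̄ + pD with pD = D̄ − D(θ̄), θ̄ the
posterior-mean parameters.

Two pooling modes exist and are deliberately distinct: `pool_sources`
merges sources *a priori* by n-weighted pooled moments (within + between
variance), while `combine_posterior` sums member proportions draw-wise
*after* fitting. For the squid model the two pelagic sources are kept
separate in the fit and combined draw-wise, which is how the published
pooled pelagic contribution is reproduced; pooling them a priori with
n-weights lets the 50 retro-calculated baseline values dominate the pooled
moments and understates the contribution by ~15 points.

The mixing-polygon screen tests whether the consumer mean lies in the
closed convex hull of TDF-corrected source means (per-tracer interval test
when only two sources). In the pipeline a failed check attaches a warning
rather than excluding the consumer: the study's exclusions were decided a
priori from diet knowledge, and the emulated guild moments place two modeled
consumers marginally (≲ 0.3 ‰) outside the strict hull.

## MCMC

All samplers are adaptive random-walk Metropolis, vectorized across chains,
with parameters updated in small blocks (TP and α separately — their
posterior ridge mixes poorly under joint isotropic proposals — then TDFs,
baseline means, and SDs). Proposal scales adapt toward ~25 % acceptance on a
diminishing schedule during an adaptation window contained in the burn-in,
and are frozen before any retained draw. Retained draws number
chains × (iterations − burn-in)/thin.

Profiles: `published` mirrors the original runs (3 chains, 500k/100k/100 for
trophic position; 100k/50k/50 for mixing); `fast` (3 chains, 20k/5k/10) is
the default for tests and the acceptance script and reproduces posterior
means to well within the stated tolerances in ~6 s per trophic-position fit
on one CPU. Recovery suites use a shorter 8k/2k/6 profile; those problem
sizes (20 synthetic consumers, 10 mixing seeds, B = 500, 10 clustering
seeds) were chosen so the whole suite runs at desk scale.

Convergence: Gelman–Rubin R̂ as √(((n−1)/n·W + B/n)/W) — when chains agree
exactly this equals √((n−1)/n), approaching 1 from below — flagged at 1.1;
Geweke z from spectral-density-at-zero standard errors with a
Bartlett-windowed autocovariance sum (window √n), flagged at |z| = 2. The
stationarity half of the Heidelberger–Welch procedure is intentionally not
implemented: at these chain lengths it adds little beyond R̂ + Geweke, and
leaving it out keeps the diagnostic surface explicit. Non-convergent fits
are returned with `converged=False`, never discarded.

## Synthetic generator

`synthetic.py` inverts the two models: trophic-position consumers get
per-individual TDF draws (matching how TDF variance enters the likelihood)
plus 0.4 ‰ observation noise by default; mixture consumers are drawn from
the mixing likelihood itself. Defaults emulate the surveyed community
(31 taxa, n ∈ [4, 9], baselines at the published values, λ = 2). The
generator reproduces closed-form expectations as n grows and fixes every
downstream draw given a seed.

What passing recovery tests therefore show: the samplers invert the exact
data-generating models at realistic noise. What they do not show: robustness
to non-Normal tracer distributions, temporally varying baselines, tissue
turnover, concentration dependence, or body-size effects — none of which the
generator simulates (and which are out of scope).

## Known limitations

- Posterior TP intervals are wider than the published ones (see the
  retro-calculation note above); means agree.
- With two tracers and four sources the mixing posterior is prior-influenced;
  CIs are wide by construction, as in the original analysis.
- The Geweke spectral estimator uses a fixed √n window; no automatic window
  selection.
- `reference_tl_from_diet` assumes uniform Dirichlet weights over diet
  items, the convention used for literature trophic levels when proportions
  are unavailable.
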