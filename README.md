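# trophicmix

Bayesian stable-isotope food-web modelling for coastal communities:
two-baseline trophic-position estimation, bootstrap-averaged trophic-guild
clustering, and Dirichlet diet mixing models — the toolchain needed to ask
whether fisheries discards subsidize the diet of benthic and demersal
consumers in a fishing ground.

It is written for trophic ecologists working with per-individual δ13C/δ15N
measurements of a sampled community (here: 31 marine taxa from a bottom-trawl
survey of the Bay of Bourgneuf, northeast Atlantic), and reproduces that
study's full analysis from its published per-taxon summaries.

## Models

**Trophic position.** Each consumer's tracers mix a benthic and a pelagic
baseline (both at trophic level λ = 2) and climb TP − λ discrimination steps:

```
δ13C ~ Normal(α·μC_b + (1−α)·μC_p + ΔC·(TP−λ), σ_C)
δ15N ~ Normal(α·μN_b + (1−α)·μN_p + ΔN·(TP−λ), σ_N)
```

with TP ~ Uniform(λ, 10), α ~ Beta(1,1), and informative Normal priors on the
trophic discrimination factors (ΔC = 1 ± 0.5 ‰ for fishes; ΔN = 3.4 ± 0.5 ‰
for Actinopterygii, 2.3 ± 0.5 ‰ for Chondrichthyes; invertebrates
0.5 ± 0.13 / 2.3 ± 0.18 ‰). Baseline observations inform μ and σ of each
end-member. The benthic baseline is the scallop *Pecten maximus* (TL = 2); the
pelagic primary consumer is retro-calculated from sprat by subtracting one TDF
step.

**Trophic guilds.** Taxa are clustered by UPGMA on the element-wise average of
500 bootstrap distance matrices: each replicate resamples 4 individuals per
taxon, takes mean (δ13C, δ15N) coordinates, z-scores them across taxa and
computes Euclidean distances — removing sample-size bias from the dissimilarity.

**Diet proportions.** A consumer's tracers are a proportion-weighted mixture of
guild-level sources with process and residual error:

```
δ_jt ~ Normal(Σ_k p_k·(μ_kt + μΔ_kt), sqrt(ε_t · Σ_k p_k²·(σ_kt² + σΔ_kt²)))
```

with p ~ Dirichlet(1, …, 1) and per-tracer residual multipliers ε_t ≥ 1.
Models are compared by DIC and consumers screened against the mixing polygon.

All posteriors are sampled by an in-package adaptive Metropolis MCMC (3 chains,
burn-in, thinning) and checked with Gelman–Rubin R̂ and Geweke diagnostics.

## Worked example

```python
from trophicmix import study
from trophicmix.baselines import TDF_REGISTRY
from trophicmix.tp_model import TPModelSpec, fit_tp, summarize_tp
from trophicmix._sampler import FAST_PROFILE

pair = study.build_study_baselines(seed=1)       # scallop + retro-calculated PPC
whiting = study.reconstitute_taxon("Mmerla", 11)  # n = 6, from printed moments
spec = TPModelSpec(tdf=TDF_REGISTRY["Actinopterygii"], mcmc=FAST_PROFILE)
post = fit_tp(whiting, pair, spec, seed=7)
mean, (lo, hi) = summarize_tp(post)
print(f"TP = {mean:.2f} (95% CI {lo:.2f}-{hi:.2f}), Rhat = {post.rhat_tp:.3f}")
```

prints

```
TP = 4.24 (95% CI 3.64-5.20), Rhat = 1.005
```

i.e. whiting sits a touch above trophic level 4 — a tertiary consumer — with α
(the benthic share of its baseline signal) available in `post.alpha_draws`.
The published community emulation is also runnable end-to-end from the shell:

```
trophicmix run-all --seed 1 --mcmc-profile fast --out results/run
```

which writes the community table, guild partition (six guilds: BPC, PPC, PSC,
SBF, BIF, DFC), per-taxon trophic positions with literature comparisons, diet
posteriors with DIC, and MCMC diagnostics, plus a manifest sufficient to rerun
the pipeline bit-identically.

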