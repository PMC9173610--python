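"""End-to-end orchestration: data → baselines → guilds → TP → diet.

A :class:`PipelineConfig` (YAML-loadable) names the data source, the
baseline construction, the clustering parameters, the consumers to model
and the MCMC profile.  All randomness flows from one master seed through
per-stage spawned generators, so stage-level reruns reproduce the
monolithic run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._sampler import FAST_PROFILE, PUBLISHED_MIX_PROFILE, PUBLISHED_TP_PROFILE
from . import study
from .baselines import (TDF_REGISTRY, build_baseline_pair,
                        retrocalculate_baseline, tdf_for_class)
from .clustering import bootstrap_distances, select_clusters, upgma
from .dataset import (CommunityDataset, read_samples, summarize_taxa,
                      validate, write_samples)
from .diagnostics import diagnose
from .mixing import fit_mixing, combine_posterior, polygon_check
from .synthetic import default_config, simulate_community
from .tp_model import TPModelSpec, compare_to_reference, fit_tp, summarize_tp


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage, self.code = stage, code


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    source: str = "study"            # "study" | "synthetic" | "csv"
    data_path: str | None = None     # for source == "csv"
    n_taxa: int = 5                  # for source == "synthetic"
    benthic_taxon: str = "Pmax"
    pelagic_from: str = "Sspr"
    retro_n_sim: int = 50
    retro_resample_k: int = 7
    lam: float = 2.0
    cluster_m: int = 4
    cluster_B: int = 500
    cluster_k: int | str = 6
    tp_taxa: list[str] | str = "all"
    mix_consumers: list[str] | str = "study"
    mcmc_profile: str = "fast"
    seed: int = 0
    out_dir: str = "trophicmix_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", "unknown-key",
                                f"unrecognized config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _profiles(name: str):
    if name == "published":
        return PUBLISHED_TP_PROFILE, PUBLISHED_MIX_PROFILE
    if name == "fast":
        return FAST_PROFILE, FAST_PROFILE
    raise PipelineError("config", "bad-profile",
                        f"unknown MCMC profile {name!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tp_profile, mix_profile = _profiles(config.mcmc_profile)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(child) for name, child in zip(
        ("data", "baseline", "cluster", "tp", "mix"), ss.spawn(5))}

    def taxon_rng(stage: int, tid: str) -> np.random.Generator:
        # keyed by taxon, not iteration order: stage subcommands on a
        # subset reproduce the monolithic run taxon for taxon
        import zlib

        return np.random.default_rng(
            np.random.SeedSequence((config.seed, stage,
                                    zlib.crc32(tid.encode()))))

    artifacts: dict[str, str] = {}

    # -- stage: data -------------------------------------------------------
    truth = None
    if config.source == "study":
        dataset = study.emulated_community(seeds["data"])
    elif config.source == "synthetic":
        cfg = default_config(config.n_taxa)
        dataset, pair, truth = simulate_community(cfg, seeds["data"])
    elif config.source == "csv":
        if not config.data_path:
            raise PipelineError("data", "missing-path",
                                "source 'csv' requires data_path")
        dataset = read_samples(config.data_path)
    else:
        raise PipelineError("data", "bad-source",
                            f"unknown source {config.source!r}")
    write_samples(dataset, out / "community.csv")
    artifacts["community"] = "community.csv"
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
        artifacts["truth"] = "truth.csv"

    # -- stage: validate ---------------------------------------------------
    report = validate(dataset)
    pd.DataFrame(
        [{"row": f.row, "taxon_id": f.taxon_id, "kind": f.kind,
          "message": f.message} for f in report.flags]
    ).to_csv(out / "validation.csv", index=False)
    artifacts["validation"] = "validation.csv"

    # -- stage: summarize --------------------------------------------------
    summaries = summarize_taxa(dataset)
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "taxon_summary.csv", index=False)
    artifacts["taxon_summary"] = "taxon_summary.csv"

    # -- stage: baseline ---------------------------------------------------
    ppc_summary = None
    if config.source == "synthetic":
        baselines = pair  # simulated alongside the data
    else:
        try:
            benthic = dataset.samples(config.benthic_taxon)
            sprat_like = dataset.samples(config.pelagic_from)
        except KeyError as exc:
            raise PipelineError("baseline", "unknown-taxon", str(exc)) from exc
        cls = sprat_like[0].tax_class
        ppc, ppc_summary = retrocalculate_baseline(
            sprat_like, tdf_for_class(cls), n_sim=config.retro_n_sim,
            resample_k=config.retro_resample_k, seed=seeds["baseline"],
        )
        baselines = build_baseline_pair(benthic, ppc, config.lam)
        pd.DataFrame([{
            "taxon_id": ppc_summary.taxon_id, "n": ppc_summary.n,
            "mean_d13C": ppc_summary.mean_d13C, "sd_d13C": ppc_summary.sd_d13C,
            "mean_d15N": ppc_summary.mean_d15N, "sd_d15N": ppc_summary.sd_d15N,
        }]).to_csv(out / "ppc_baseline.csv", index=False)
        artifacts["ppc_baseline"] = "ppc_baseline.csv"

    # -- stage: cluster ----------------------------------------------------
    cluster_data = dataset
    if config.source == "study":
        # guilds are defined over consumers plus both baselines
        extra = CommunityDataset.from_samples(
            dataset.samples() + list(baselines.pelagic))
        cluster_data = extra
    ensemble = bootstrap_distances(
        cluster_data, m=config.cluster_m, B=config.cluster_B,
        seed=seeds["cluster"])
    ensemble.to_frame().to_csv(out / "distance_matrix.csv")
    tree = upgma(ensemble)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    k_eff = config.cluster_k if config.cluster_k == "auto" \
        else min(int(config.cluster_k), len(cluster_data.taxa))
    partition = select_clusters(tree, k_eff)
    partition.to_frame().to_csv(out / "guilds.csv", index=False)
    artifacts.update({"distance_matrix": "distance_matrix.csv",
                      "dendrogram": "dendrogram.nwk", "guilds": "guilds.csv"})

    # -- stage: tp ---------------------------------------------------------
    benthic_id = {s.taxon_id for s in baselines.benthic}
    tp_taxa = [t for t in dataset.taxa if t not in benthic_id] \
        if config.tp_taxa == "all" else list(config.tp_taxa)
    ref = study.reference_table().set_index("taxon_id") \
        if config.source == "study" else None
    tp_rows, tp_draw_frames, diag_frames = [], [], []
    for tid in tp_taxa:
        consumer = dataset.samples(tid)
        tdf = tdf_for_class(consumer[0].tax_class)
        spec = TPModelSpec(tdf=tdf, lam=config.lam, mcmc=tp_profile)
        post = fit_tp(consumer, baselines, spec, seed=taxon_rng(1, tid),
                      taxon_id=tid)
        mean, (lo, hi) = summarize_tp(post)
        row = {"taxon_id": tid, "n": len(consumer), "mean_tp": mean,
               "ci_lo": lo, "ci_hi": hi, "rhat": post.rhat_tp,
               "converged": post.converged}
        if ref is not None and tid in ref.index:
            r = ref.loc[tid]
            cmp_ = compare_to_reference(post, float(r.lit_tl_mean),
                                        None if pd.isna(r.lit_tl_se)
                                        else float(r.lit_tl_se))
            row.update(ref_mean=cmp_.ref_mean, ref_se=cmp_.ref_se,
                       direction=cmp_.direction, overlap=cmp_.overlap)
        tp_rows.append(row)
        tp_draw_frames.append(post.to_frame())
        diag_frames.append(post.diagnostics)
    if tp_rows:
        pd.DataFrame(tp_rows).to_csv(out / "tp_summary.csv", index=False)
        pd.concat(tp_draw_frames).to_csv(out / "tp_draws.csv", index=False)
        artifacts.update({"tp_summary": "tp_summary.csv",
                          "tp_draws": "tp_draws.csv"})

    # -- stage: mix --------------------------------------------------------
    mix_rows, mix_draw_frames, polygon_rows = [], [], []
    consumers = study.MIXING_CONSUMERS if config.mix_consumers == "study" \
        else list(config.mix_consumers)
    if config.source != "study":
        consumers = [] if config.mix_consumers == "study" else consumers
    for cid in consumers:
        setup = study.mixing_setup(cid, ppc_summary)
        consumer = dataset.samples(cid)
        cmean = (float(np.mean([s.d13C for s in consumer])),
                 float(np.mean([s.d15N for s in consumer])))
        inside = polygon_check(cmean, setup.sources)
        polygon_rows.append({"taxon_id": cid, "inside_polygon": inside})
        post = fit_mixing(consumer, setup.sources, mix_profile,
                          seed=taxon_rng(2, cid), consumer_id=cid)
        if setup.combine:
            post = combine_posterior(post, setup.combine)
        summ = post.summary()
        summ.insert(0, "consumer", cid)
        summ["dic"] = post.dic
        summ["converged"] = post.converged
        mix_rows.append(summ)
        mix_draw_frames.append(post.to_frame())
        diag_frames.append(post.diagnostics)
    if polygon_rows:
        pd.DataFrame(polygon_rows).to_csv(out / "polygon.csv", index=False)
        artifacts["polygon"] = "polygon.csv"
    if mix_rows:
        pd.concat(mix_rows).to_csv(out / "diet_summary.csv", index=False)
        pd.concat(mix_draw_frames).to_csv(out / "diet_draws.csv", index=False)
        artifacts["diet_summary"] = "diet_summary.csv"
        artifacts["diet_draws"] = "diet_draws.csv"

    # -- stage: diagnostics ------------------------------------------------
    if diag_frames:
        pd.concat(diag_frames).to_csv(out / "diagnostics.csv", index=False)
        artifacts["diagnostics"] = "diagnostics.csv"

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"trophicmix": __version__, "numpy": np.__version__},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def biplot(dataset: CommunityDataset, partition=None, path=None):
    """Basic δ13C–δ15N biplot of taxon means, colored by guild."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summaries = summarize_taxa(dataset)
    fig, ax = plt.subplots(figsize=(6, 5))
    guilds = {s.taxon_id: (partition.guild_of(s.taxon_id)
                           if partition and s.taxon_id in partition.assignments
                           else 0)
              for s in summaries}
    cmap = plt.get_cmap("tab10")
    for s in summaries:
        ax.errorbar(s.mean_d13C, s.mean_d15N, xerr=s.sd_d13C, yerr=s.sd_d15N,
                    fmt="o", color=cmap(guilds[s.taxon_id] % 10), ms=4, lw=1)
        ax.annotate(s.taxon_id, (s.mean_d13C, s.mean_d15N), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("δ13C (‰)")
    ax.set_ylabel("δ15N (‰)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
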