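"""Bay of Bourgneuf study emulation from published per-taxon summaries.

The raw per-individual isotope data of the surveyed fishing-ground
community is not public, but the published per-taxon means ± SD and
sample sizes, the guild summaries, and the baseline values are enough to
reconstitute every model input at desk scale.  This module encodes those
printed summaries and builds the emulated datasets, baselines and
mixing-model source sets used by the pipeline, tests and acceptance
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import (BaselinePair, TDF_REGISTRY, build_baseline_pair,
                        retrocalculate_baseline, tdf_for_class)
from .dataset import CommunityDataset, GroupSummary, IsotopeSample, TaxonSummary
from .mixing import DietSources, SourceSpec
from .tp_model import reconstitute_samples

LAMBDA = 2.0  # trophic level shared by both baselines

# Published per-taxon summaries: code -> (name, class, n, guild,
# mean_d13C, sd_d13C, mean_d15N, sd_d15N, lit_TL_mean, lit_TL_se,
# modeled_TL_mean, ci_lo, ci_hi).  lit_TL_se is None when unavailable.
TAXON_TABLE: dict[str, tuple] = {
    "Clyr": ("Callionymus lyra", "Actinopterygii", 7, "BIF", -17.4, 0.2, 12.6, 0.6, 3.3, 0.4, 2.8, 2.6, 3.1),
    "Cluc": ("Chelidonichthys lucerna", "Actinopterygii", 7, "SBF", -15.7, 0.9, 15.3, 0.3, 4.0, 0.1, 3.6, 3.4, 3.8),
    "Ccon": ("Conger conger", "Actinopterygii", 6, "DFC", -16.8, 0.5, 15.3, 0.7, 4.3, 0.4, 3.6, 3.3, 4.0),
    "Eenc": ("Engraulis encrasicolus", "Actinopterygii", 7, "PSC", -18.2, 0.2, 13.0, 0.6, 3.1, 0.4, 3.1, 2.8, 3.4),
    "Spil": ("Sardina pilchardus", "Actinopterygii", 6, "PSC", -18.3, 0.6, 12.8, 0.7, 3.1, 0.1, 3.0, 2.7, 3.4),
    "Sspr": ("Sprattus sprattus", "Actinopterygii", 7, "PSC", -19.3, 0.3, 12.0, 0.5, 3.0, 0.1, 2.9, 2.7, 3.1),
    "Ssco": ("Scomber scombrus", "Actinopterygii", 7, "PSC", -18.5, 0.5, 12.1, 0.8, 3.6, 0.2, 2.8, 2.5, 3.2),
    "Oepe": ("Osmerus eperlanus", "Actinopterygii", 7, "DFC", -17.4, 0.6, 15.5, 0.5, 3.5, 0.4, 3.8, 3.6, 4.1),
    "Bbel": ("Belone belone", "Actinopterygii", 4, "BIF", -17.4, 0.6, 13.4, 1.5, 4.2, 0.4, 3.2, 2.5, 4.2),
    "Ttra": ("Trachurus trachurus", "Actinopterygii", 7, "DFC", -18.1, 0.4, 15.0, 0.6, 3.7, 0.0, 3.8, 3.5, 4.0),
    "Ppol": ("Pollachius pollachius", "Actinopterygii", 7, "DFC", -17.2, 1.0, 15.2, 0.6, 4.3, 0.3, 3.7, 3.4, 4.0),
    "Tlus": ("Trisopterus luscus", "Actinopterygii", 7, "DFC", -16.7, 0.7, 15.7, 0.9, 3.7, 0.1, 3.8, 3.4, 4.2),
    "Mmerla": ("Merlangius merlangus", "Actinopterygii", 6, "DFC", -17.5, 0.3, 16.7, 0.6, 4.4, 0.2, 4.2, 3.9, 4.5),
    "Mmerlu": ("Merluccius merluccius", "Actinopterygii", 7, "DFC", -18.0, 0.4, 14.5, 0.7, 4.4, 0.0, 3.6, 3.3, 3.9),
    "Ppag": ("Pagrus pagrus", "Actinopterygii", 7, "DFC", -16.6, 0.5, 15.8, 0.5, 3.9, 0.2, 3.8, 3.5, 4.0),
    "Scant": ("Spondyliosoma cantharus", "Actinopterygii", 7, "DFC", -17.0, 0.6, 15.3, 0.5, 3.3, 0.2, 3.7, 3.4, 4.0),
    "Lber": ("Labrus bergylta", "Actinopterygii", 4, "BIF", -17.4, 1.0, 13.8, 0.6, 3.2, 0.0, 3.3, 2.8, 3.8),
    "Ssol": ("Solea solea", "Actinopterygii", 7, "BIF", -17.2, 1.4, 14.1, 0.4, 3.2, 0.2, 3.3, 3.1, 3.6),
    "Rund": ("Raja undulata", "Chondrichthyes", 7, "SBF", -16.0, 0.6, 14.6, 0.4, 3.5, 0.4, 4.1, 3.8, 4.5),
    "Scani": ("Scyliorhinus canicula", "Chondrichthyes", 7, "DFC", -16.8, 0.3, 14.6, 0.4, 3.8, 0.3, 4.3, 3.9, 4.7),
    "Allo": ("Alloteuthis spp.", "Cephalopoda", 7, "DFC", -18.6, 0.5, 14.6, 1.3, 3.5, 0.4, 4.4, 3.7, 5.2),
    "Soff": ("Sepia officinalis", "Cephalopoda", 7, "DFC", -17.3, 0.2, 14.7, 0.4, 4.3, 0.7, 4.2, 3.7, 4.8),
    "Aund": ("Atelecyclus undecimdentatus", "Decapoda", 9, "BIF", -17.1, 0.8, 12.5, 0.5, 2.8, None, 3.2, 2.9, 3.6),
    "Cpag": ("Cancer pagurus", "Decapoda", 7, "BIF", -17.3, 0.5, 13.9, 0.7, 3.1, None, 3.8, 3.4, 4.4),
    "Npub": ("Necora puber", "Decapoda", 7, "BIF", -16.9, 0.3, 12.9, 0.6, 2.6, None, 3.5, 3.1, 4.0),
    "Mbra": ("Maja brachydactyla", "Decapoda", 7, "BIF", -16.8, 0.4, 13.3, 0.7, 3.2, 0.2, 3.6, 3.2, 4.2),
    "Pagu": ("Pagurus spp.", "Decapoda", 7, "BIF", -16.2, 0.5, 12.9, 0.3, 3.6, 0.2, 3.4, 3.1, 3.9),
    "Cran": ("Crangon spp.", "Decapoda", 7, "SBF", -15.3, 1.2, 13.9, 0.2, 3.2, 0.5, 3.8, 3.5, 4.4),
    "Bund": ("Buccinum undatum", "Gasteropoda", 7, "BIF", -16.4, 0.5, 13.4, 0.7, 3.4, 0.4, 3.7, 3.3, 4.4),
    "Aacu": ("Aphrodita aculeata", "Polychaeta", 6, "BIF", -16.6, 0.7, 13.7, 0.7, 3.2, 0.4, 3.8, 3.3, 4.5),
}

#: Benthic baseline: scallop, trophic level 2.  n = 21 derived from the
#: published totals (216 individuals over 31 taxa; consumers sum to 195).
SCALLOP = ("Pmax", "Pecten maximus", "Bivalvia", 21, "BPC", -17.9, 0.2, 10.1, 0.4)

#: Published guild summaries (mean ± SD over pooled individuals).
GROUP_TABLE: dict[str, tuple[float, float, float, float]] = {
    "BPC": (-17.9, 0.2, 10.1, 0.4),
    "PPC": (-20.4, 0.2, 8.6, 0.3),
    "PSC": (-18.6, 0.6, 12.5, 0.8),
    "BIF": (-16.9, 0.7, 13.2, 0.8),
    "SBF": (-15.7, 0.9, 14.6, 0.7),
    "DFC": (-17.3, 0.8, 15.2, 0.9),
}

#: Member n totals for pooling printed group summaries.
GROUP_N = {"BPC": 21, "PPC": 50, "PSC": 27, "BIF": 72, "SBF": 21, "DFC": 82}

#: Ten consumers screened into the mixing-model stage (inside the mixing
#: polygon with prior evidence of discard ingestion); shrimps and hermit
#: crabs are excluded for lack of important sources.
MIXING_CONSUMERS = ["Rund", "Scani", "Allo", "Soff", "Aund", "Cpag",
                    "Npub", "Mbra", "Aacu", "Bund"]
EXCLUDED_CONSUMERS = ["Cran", "Pagu"]


def guild_members(guild: str) -> list[str]:
    if guild == "BPC":
        return ["Pmax"]
    return [code for code, row in TAXON_TABLE.items() if row[3] == guild]


def taxon_summary(code: str) -> TaxonSummary:
    if code == "Pmax":
        _, _, _, n, _, mC, sC, mN, sN = SCALLOP
        return TaxonSummary("Pmax", n, mC, sC, mN, sN)
    name, cls, n, guild, mC, sC, mN, sN, *_ = TAXON_TABLE[code]
    return TaxonSummary(code, n, mC, sC, mN, sN)


def taxon_summaries() -> list[TaxonSummary]:
    return [taxon_summary(code) for code in TAXON_TABLE]


def reference_table() -> pd.DataFrame:
    rows = []
    for code, row in TAXON_TABLE.items():
        rows.append({
            "taxon_id": code, "taxon_name": row[0], "tax_class": row[1],
            "n": row[2], "cluster": row[3], "mean_d13C": row[4],
            "sd_d13C": row[5], "mean_d15N": row[6], "sd_d15N": row[7],
            "lit_tl_mean": row[8], "lit_tl_se": row[9],
            "modeled_tl_mean": row[10], "modeled_tl_lo": row[11],
            "modeled_tl_hi": row[12],
        })
    return pd.DataFrame(rows)


def reconstitute_taxon(code: str, seed) -> list[IsotopeSample]:
    """Emulated individuals of one published taxon (moment-matched)."""
    if code == "Pmax":
        tid, name, cls, n, _, mC, sC, mN, sN = SCALLOP
        return reconstitute_samples(tid, name, cls, mC, sC, mN, sN, n, seed)
    name, cls, n, _, mC, sC, mN, sN, *_ = TAXON_TABLE[code]
    return reconstitute_samples(code, name, cls, mC, sC, mN, sN, n, seed)


def emulated_community(
    seed: int | np.random.Generator | None = None, include_scallop: bool = True
) -> CommunityDataset:
    """The whole published community reconstituted from printed moments."""
    rng = np.random.default_rng(seed)
    samples: list[IsotopeSample] = []
    for code in TAXON_TABLE:
        samples.extend(reconstitute_taxon(code, rng))
    if include_scallop:
        samples.extend(reconstitute_taxon("Pmax", rng))
    return CommunityDataset.from_samples(samples)


def build_study_baselines(
    seed: int | np.random.Generator | None = None,
    n_sim: int = 50, resample_k: int = 7,
) -> BaselinePair:
    """Scallop benthic baseline + PPC retro-calculated from sprat at λ = 2."""
    rng = np.random.default_rng(seed)
    scallop = reconstitute_taxon("Pmax", rng)
    sprat = reconstitute_taxon("Sspr", rng)
    ppc, _ = retrocalculate_baseline(
        sprat, TDF_REGISTRY["Actinopterygii"], n_sim=n_sim,
        resample_k=resample_k, seed=rng,
    )
    return build_baseline_pair(scallop, ppc, LAMBDA)


@dataclass(frozen=True)
class MixingSetup:
    """Source set and posterior pooling for one mixing-model consumer."""

    consumer: str
    sources: DietSources
    combine: dict[str, list[str]] | None = None


def group_source(
    guild: str, tax_class: str, ppc_summary: TaxonSummary | None = None
) -> SourceSpec:
    """A guild as a mixing-model source, with the consumer-class TDF.

    ``PPC`` uses the retro-calculated baseline summary when supplied,
    otherwise the published PPC values.
    """
    tdf = tdf_for_class(tax_class)
    if guild == "PPC" and ppc_summary is not None:
        return SourceSpec("PPC", ppc_summary.mean_d13C, ppc_summary.sd_d13C,
                          ppc_summary.mean_d15N, ppc_summary.sd_d15N,
                          ppc_summary.n, tdf)
    mC, sC, mN, sN = GROUP_TABLE[guild]
    return SourceSpec(guild, mC, sC, mN, sN, GROUP_N[guild], tdf)


def sbf_bif_pooled(tax_class: str) -> SourceSpec:
    """The SBF and BIF guilds pooled a priori (as in every fitted model)."""
    from .mixing import pool_source_specs

    return pool_source_specs(
        [group_source("SBF", tax_class), group_source("BIF", tax_class)],
        "SBF-BIF")


def mixing_setup(
    consumer: str, ppc_summary: TaxonSummary | None = None,
    pool_pelagic: bool | None = None,
) -> MixingSetup:
    """Published source selection for one mixing-model consumer.

    All models use BPC, pooled SBF-BIF, DFC and PSC; the squid model
    drops BPC and pools the two pelagic sources (PPC + PSC) a priori.
    """
    cls = TAXON_TABLE[consumer][1]
    if pool_pelagic is None:
        pool_pelagic = consumer == "Allo"
    if pool_pelagic:
        # squid model: no benthic primary source; the two pelagic sources
        # stay separate in the fit and are summed draw-wise afterwards
        sources = DietSources((
            sbf_bif_pooled(cls), group_source("DFC", cls),
            group_source("PPC", cls, ppc_summary), group_source("PSC", cls),
        ))
        combine = {"SBF-BIF": ["SBF-BIF"], "DFC": ["DFC"],
                   "PPC-PSC": ["PPC", "PSC"]}
        return MixingSetup(consumer, sources, combine)
    sources = DietSources((
        group_source("BPC", cls), sbf_bif_pooled(cls),
        group_source("DFC", cls), group_source("PSC", cls),
    ))
    return MixingSetup(consumer, sources)
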