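"""Per-individual stable-isotope records and their summaries.

The fundamental record is one individual animal with its carbon and
nitrogen isotope ratios (δ13C vs VPDB, δ15N vs atmospheric N2, both in
per mil) plus elemental %C and %N, from which the C/N ratio — a proxy
for lipid content — is derived.  A :class:`CommunityDataset` holds the
records of a whole sampled community, grouped by taxon.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomic classes accepted by the validator.
KNOWN_CLASSES = frozenset(
    {
        "Actinopterygii",
        "Chondrichthyes",
        "Cephalopoda",
        "Decapoda",
        "Gasteropoda",
        "Polychaeta",
        "Bivalvia",
        "Baseline",
    }
)

#: CSV schema, in column order.  ``cn_ratio`` is derived, never stored.
CSV_COLUMNS = ["taxon_id", "taxon_name", "tax_class", "d13C", "d15N", "pctC", "pctN"]

_NUMERIC = ["d13C", "d15N", "pctC", "pctN"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell that must be numeric could not be parsed."""


@dataclass(frozen=True)
class IsotopeSample:
    """A single individual's isotope measurement."""

    taxon_id: str
    taxon_name: str
    tax_class: str
    d13C: float
    d15N: float
    pctC: float | None = None
    pctN: float | None = None

    @property
    def cn_ratio(self) -> float | None:
        if self.pctC is None or self.pctN is None:
            return None
        if np.isnan(self.pctC) or np.isnan(self.pctN):
            return None
        return self.pctC / self.pctN


@dataclass(frozen=True)
class TaxonSummary:
    """Mean ± sample SD (n−1 denominator) of one taxon's tracers."""

    taxon_id: str
    n: int
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float


@dataclass(frozen=True)
class GroupSummary:
    """Pooled-individual moments of a multi-taxon group."""

    group_id: str
    member_taxa: tuple[str, ...]
    n_total: int
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float


@dataclass(frozen=True)
class ValidationFlag:
    row: int | None
    taxon_id: str
    kind: str  # "cn_ratio" | "d13C_range" | "d15N_range" | "small_n" | "class"
    message: str


@dataclass(frozen=True)
class ValidationReport:
    flags: tuple[ValidationFlag, ...]

    @property
    def ok(self) -> bool:
        return not self.flags

    def of_kind(self, kind: str) -> list[ValidationFlag]:
        return [f for f in self.flags if f.kind == kind]


@dataclass
class CommunityDataset:
    """All individuals of a sampled community, row order preserved."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.df = self.df.reset_index(drop=True)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_samples(cls, samples: list[IsotopeSample]) -> "CommunityDataset":
        rows = [
            {
                "taxon_id": s.taxon_id,
                "taxon_name": s.taxon_name,
                "tax_class": s.tax_class,
                "d13C": s.d13C,
                "d15N": s.d15N,
                "pctC": np.nan if s.pctC is None else s.pctC,
                "pctN": np.nan if s.pctN is None else s.pctN,
            }
            for s in samples
        ]
        return cls(pd.DataFrame(rows, columns=CSV_COLUMNS))

    # -- access ------------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        """Taxon ids in first-appearance order."""
        return list(dict.fromkeys(self.df["taxon_id"]))

    def __len__(self) -> int:
        return len(self.df)

    def taxon(self, taxon_id: str) -> pd.DataFrame:
        sub = self.df[self.df["taxon_id"] == taxon_id]
        if sub.empty:
            raise KeyError(f"unknown taxon: {taxon_id!r}")
        return sub

    def samples(self, taxon_id: str | None = None) -> list[IsotopeSample]:
        df = self.df if taxon_id is None else self.taxon(taxon_id)
        return [
            IsotopeSample(
                r.taxon_id,
                r.taxon_name,
                r.tax_class,
                float(r.d13C),
                float(r.d15N),
                None if pd.isna(r.pctC) else float(r.pctC),
                None if pd.isna(r.pctN) else float(r.pctN),
            )
            for r in self.df.itertuples()
            if taxon_id is None or r.taxon_id == taxon_id
        ]

    def content_hash(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()


# -- I/O -------------------------------------------------------------------

def read_samples(path) -> CommunityDataset:
    """Read a community CSV (schema ``taxon_id,...,pctN``, UTF-8)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = parsed
    return CommunityDataset(df[CSV_COLUMNS])


def write_samples(dataset: CommunityDataset, path) -> None:
    """Write the dataset back out in the canonical CSV schema."""
    dataset.df[CSV_COLUMNS].to_csv(path, index=False)


# -- operations ------------------------------------------------------------

def validate(dataset: CommunityDataset, cn_max: float = 4.0) -> ValidationReport:
    """Quality screen: lipid proxy (C/N ≥ ``cn_max``), δ ranges, classes.

    Reporting only — the dataset is never mutated.  Rows with missing
    %C/%N are skipped by the C/N screen.
    """
    if len(dataset) == 0:
        raise ValueError("cannot validate an empty dataset")
    flags: list[ValidationFlag] = []
    for i, r in enumerate(dataset.df.itertuples()):
        if not (pd.isna(r.pctC) or pd.isna(r.pctN)):
            cn = r.pctC / r.pctN
            if cn >= cn_max:
                flags.append(
                    ValidationFlag(
                        i, r.taxon_id, "cn_ratio",
                        f"C/N = {cn:.2f} ≥ {cn_max:g}: possible lipid bias, "
                        "consider lipid correction",
                    )
                )
        if not (-40.0 <= r.d13C <= 0.0):
            flags.append(
                ValidationFlag(i, r.taxon_id, "d13C_range",
                               f"δ13C = {r.d13C:g} ‰ outside [−40, 0]")
            )
        if not (0.0 <= r.d15N <= 30.0):
            flags.append(
                ValidationFlag(i, r.taxon_id, "d15N_range",
                               f"δ15N = {r.d15N:g} ‰ outside [0, 30]")
            )
        if r.tax_class not in KNOWN_CLASSES:
            flags.append(
                ValidationFlag(i, r.taxon_id, "class",
                               f"unknown taxonomic class {r.tax_class!r}")
            )
    return ValidationReport(tuple(flags))


def summarize_taxa(dataset: CommunityDataset) -> list[TaxonSummary]:
    """Per-taxon mean and sample SD (ddof=1; SD = 0 when n = 1)."""
    out = []
    for tid in dataset.taxa:
        sub = dataset.taxon(tid)
        n = len(sub)
        sd13 = float(sub["d13C"].std(ddof=1)) if n > 1 else 0.0
        sd15 = float(sub["d15N"].std(ddof=1)) if n > 1 else 0.0
        out.append(
            TaxonSummary(
                tid, n,
                float(sub["d13C"].mean()), sd13,
                float(sub["d15N"].mean()), sd15,
            )
        )
    return out


def pool_group(
    dataset: CommunityDataset, member_taxa: list[str], group_id: str = "group"
) -> GroupSummary:
    """Moments of the pooled individuals of several taxa."""
    for tid in member_taxa:
        if tid not in dataset.taxa:
            raise KeyError(f"unknown member taxon: {tid!r}")
    sub = dataset.df[dataset.df["taxon_id"].isin(member_taxa)]
    n = len(sub)
    return GroupSummary(
        group_id, tuple(member_taxa), n,
        float(sub["d13C"].mean()),
        float(sub["d13C"].std(ddof=1)) if n > 1 else 0.0,
        float(sub["d15N"].mean()),
        float(sub["d15N"].std(ddof=1)) if n > 1 else 0.0,
    )


def pool_group_moments(
    summaries: list[TaxonSummary] | list[GroupSummary], group_id: str = "group"
) -> GroupSummary:
    """Pool per-taxon (mean, SD, n) into group moments without raw rows.

    mean = Σ nᵢ·mᵢ / Σ nᵢ; variance combines within-taxon (Σ (nᵢ−1)sᵢ²)
    and between-taxon (Σ nᵢ(mᵢ−m̄)²) contributions over N−1, exactly the
    moments of the concatenated individuals.
    """
    ns = np.array([getattr(s, "n", getattr(s, "n_total", None)) for s in summaries], float)
    if np.any(ns < 1):
        raise ValueError("every member needs n ≥ 1")
    N = ns.sum()
    out: dict[str, float] = {}
    for tracer in ("d13C", "d15N"):
        m = np.array([getattr(s, f"mean_{tracer}") for s in summaries])
        sd = np.array([getattr(s, f"sd_{tracer}") for s in summaries])
        mbar = float(np.sum(ns * m) / N)
        if N > 1:
            ss = np.sum((ns - 1) * sd**2) + np.sum(ns * (m - mbar) ** 2)
            out[f"sd_{tracer}"] = float(np.sqrt(ss / (N - 1)))
        else:
            out[f"sd_{tracer}"] = 0.0
        out[f"mean_{tracer}"] = mbar
    members = tuple(
        getattr(s, "taxon_id", getattr(s, "group_id", "?")) for s in summaries
    )
    return GroupSummary(group_id, members, int(N), out["mean_d13C"],
                        out["sd_d13C"], out["mean_d15N"], out["sd_d15N"])
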