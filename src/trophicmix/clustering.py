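"""Trophic-guild clustering on a bootstrap-averaged distance matrix.

To avoid biasing between-taxon distances by unequal sample sizes, each
bootstrap replicate resamples the same number m of individuals per taxon
(with replacement), represents each taxon by the mean δ13C/δ15N of its
resample, z-scores both coordinates across taxa, and computes Euclidean
distances.  Averaging B such matrices gives a stabilized dissimilarity
which is then clustered by UPGMA (average linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .dataset import CommunityDataset


@dataclass(frozen=True)
class DistanceMatrixEnsemble:
    """Element-wise average of B bootstrap distance matrices."""

    taxa: tuple[str, ...]
    avg_matrix: np.ndarray = field(repr=False)
    B: int
    m: int
    seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.avg_matrix, dtype=float)
        if a.shape != (len(self.taxa),) * 2:
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("averaged matrix must be symmetric")
        if np.any(np.diag(a) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(a < 0.0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "avg_matrix", a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.avg_matrix, index=list(self.taxa),
                            columns=list(self.taxa))


@dataclass(frozen=True)
class MergeTree:
    """Agglomeration history: scipy linkage matrix plus taxon labels."""

    taxa: tuple[str, ...]
    linkage: np.ndarray = field(repr=False)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick text with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.taxa[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
        return inner


@dataclass(frozen=True)
class GuildPartition:
    """Taxon → guild assignment cut from a merge tree."""

    assignments: dict[str, int]
    k: int
    merge_tree: MergeTree
    height_profile: tuple[float, ...] = ()

    def members(self, guild: int) -> list[str]:
        return [t for t, g in self.assignments.items() if g == guild]

    def guild_of(self, taxon: str) -> int:
        return self.assignments[taxon]

    def guild_sets(self) -> list[frozenset[str]]:
        return [frozenset(self.members(g))
                for g in sorted(set(self.assignments.values()))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": list(self.assignments), "guild": list(self.assignments.values())}
        )


def bootstrap_distances(
    dataset: CommunityDataset, m: int = 4, B: int = 500,
    seed: int | np.random.Generator | None = None,
) -> DistanceMatrixEnsemble:
    """Bootstrap-averaged standardized Euclidean distance matrix.

    Per replicate: resample m individuals with replacement per taxon; the
    taxon coordinate is the mean (δ13C, δ15N) of its resample; z-score
    each coordinate across taxa (ddof=1) and average the B distance
    matrices element-wise.
    """
    if B < 1 or m < 1:
        raise ValueError("B and m must be ≥ 1")
    rng = np.random.default_rng(seed)
    taxa = dataset.taxa
    T = len(taxa)
    values = [dataset.taxon(t)[["d13C", "d15N"]].to_numpy() for t in taxa]

    total = np.zeros((T, T))
    coords = np.empty((T, 2))
    for _ in range(B):
        for i, v in enumerate(values):
            idx = rng.integers(0, len(v), size=m)
            coords[i] = v[idx].mean(axis=0)
        sd = coords.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)  # degenerate coordinate: no scaling
        z = (coords - coords.mean(axis=0)) / sd
        diff = z[:, None, :] - z[None, :, :]
        total += np.sqrt(np.sum(diff * diff, axis=2))
    avg = total / B
    avg = 0.5 * (avg + avg.T)
    np.fill_diagonal(avg, 0.0)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return DistanceMatrixEnsemble(tuple(taxa), avg, B, m,
                                  None if seed_val is None else int(seed_val))


def upgma(ensemble: DistanceMatrixEnsemble) -> MergeTree:
    """Average-linkage (UPGMA) agglomeration of the averaged matrix."""
    from scipy.spatial.distance import squareform

    condensed = squareform(ensemble.avg_matrix, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return MergeTree(ensemble.taxa, Z)


def select_clusters(tree: MergeTree, k: int | str = "auto") -> GuildPartition:
    """Cut the merge tree into k guilds.

    ``k="auto"`` picks the cut at the largest relative jump between
    successive merge heights (fusion-level heuristic) and records the
    height profile so the choice can be inspected.
    """
    n = len(tree.taxa)
    heights = tuple(float(h) for h in tree.heights)
    if k == "auto":
        h = np.asarray(heights)
        with np.errstate(divide="ignore", invalid="ignore"):
            jumps = np.where(h[:-1] > 0, h[1:] / h[:-1], np.inf)
        # merge i -> i+1 leaves n-1-i clusters above the gap
        k_num = int(n - 1 - int(np.argmax(jumps)))
        k_num = max(k_num, 2)
    else:
        k_num = int(k)
        if k_num > n:
            raise ValueError(f"k = {k_num} exceeds taxon count {n}")
        if k_num < 1:
            raise ValueError("k must be ≥ 1")
    labels = hierarchy.fcluster(tree.linkage, t=k_num, criterion="maxclust")
    assignments = {t: int(g) for t, g in zip(tree.taxa, labels)}
    return GuildPartition(assignments, len(set(labels)), tree, heights)
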