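"""Phenotypic and phylogenetic distances between species.

Species are profiled by growth (OD600) across carbon sources and across
antibiotics; profiles are normalized (carbon: to the best source;
antibiotic: to drug-free growth) and compared by Euclidean distance.
Phylogenetic distance is the patristic distance — summed branch lengths —
on a supplied newick tree.  Distances can then be rank-correlated with
effect sizes to ask whether similar species affect each other's growth
more or less strongly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "TraitProfile",
    "DistanceMatrix",
    "normalize_carbon",
    "normalize_antibiotic",
    "euclidean_matrix",
    "patristic_distance",
    "patristic_matrix",
    "correlate_trait_effect",
]


@dataclass(frozen=True)
class TraitProfile:
    species_id: str
    kind: str  # "carbon" or "antibiotic"
    values: tuple[float, ...]
    exceeds_unity: bool = False  # antibiotic growth above the drug-free control


@dataclass(frozen=True)
class DistanceMatrix:
    species: tuple[str, ...]
    matrix: np.ndarray
    metric: str  # "carbon", "antibiotic", "phylogenetic"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(m, m.T, atol=1e-12) or np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)

    def get(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.matrix[i, j])


def normalize_carbon(od_by_source: Sequence[float], species_id: str = "?") -> TraitProfile:
    """Normalize a carbon-utilization profile to its best source (max = 1)."""
    arr = np.asarray(od_by_source, dtype=float)
    top = arr.max(initial=0.0)
    if top <= 0:
        raise ValueError(f"{species_id}: no growth on any carbon source")
    return TraitProfile(species_id=species_id, kind="carbon", values=tuple(arr / top))


def normalize_antibiotic(
    od_by_drug: Sequence[float],
    control_od: float,
    species_id: str = "?",
) -> TraitProfile:
    """Normalize an antibiotic-resistance profile to drug-free growth.

    Values above 1 (better growth with the drug) are retained, not
    clamped, and flagged via ``exceeds_unity``.
    """
    if control_od <= 0:
        raise ValueError(f"{species_id}: drug-free control OD must be > 0")
    arr = np.asarray(od_by_drug, dtype=float) / control_od
    return TraitProfile(
        species_id=species_id,
        kind="antibiotic",
        values=tuple(arr),
        exceeds_unity=bool(np.any(arr > 1)),
    )


def euclidean_matrix(profiles: Sequence[TraitProfile]) -> DistanceMatrix:
    """Pairwise Euclidean distances between same-kind trait profiles."""
    if not profiles:
        raise ValueError("no profiles given")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise ValueError(f"mixed profile kinds: {sorted(kinds)}")
    lengths = {len(p.values) for p in profiles}
    if len(lengths) > 1:
        raise ValueError("profiles have unequal lengths")
    x = np.array([p.values for p in profiles], dtype=float)
    from scipy.spatial.distance import pdist, squareform

    m = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(
        species=tuple(p.species_id for p in profiles), matrix=m, metric=kinds.pop()
    )


def _pdm(tree: dendropy.Tree) -> dendropy.PhylogeneticDistanceMatrix:
    return tree.phylogenetic_distance_matrix()


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Summed branch lengths along the tree path between taxa ``a`` and ``b``."""
    taxa = {t.label: t for t in tree.taxon_namespace}
    for name in (a, b):
        if name not in taxa:
            raise KeyError(f"taxon {name!r} not in tree")
    if a == b:
        return 0.0
    return float(_pdm(tree).patristic_distance(taxa[a], taxa[b]))


def patristic_matrix(tree: dendropy.Tree, species: Sequence[str] | None = None) -> DistanceMatrix:
    """All pairwise patristic distances, for the given species or every taxon."""
    labels = tuple(species) if species is not None else tuple(
        sorted(t.label for t in tree.taxon_namespace)
    )
    pdm = _pdm(tree)
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in labels if s not in taxa]
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(species=labels, matrix=m, metric="phylogenetic")


def correlate_trait_effect(
    trait_values: Sequence[float],
    effects: Sequence[float],
) -> tuple[float, float]:
    """Spearman rank correlation between a trait (or distance) and effects.

    Ties are mid-ranked; the p-value is the standard two-sided
    approximation.  A constant input vector has no defined rank
    correlation and raises.
    """
    x = np.asarray(trait_values, dtype=float)
    y = np.asarray(effects, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
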