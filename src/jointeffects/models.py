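"""Combination models: predicting joint effects from lower-order effects.

Four rules turn the measured effects of individual affecting species into
a predicted joint effect of the set:

additive
    Effects accumulate independently: the prediction is their sum.
mean
    The joint effect is the arithmetic mean of the single effects.
weighted_mean
    Mean weighted by each affecting species' carrying capacity (maximum
    OD600 from its growth curve), so denser species count for more.
strongest
    The species with the largest single effect in absolute value sets the
    joint effect on its own (e.g. singles -3 and +1 predict -3).

For trios the same rules can alternatively be applied to the three
measured pair effects (AB, AC, BC) instead of the three singles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import CommunityKey
from .effects import EffectEstimate

__all__ = [
    "MODELS",
    "ModelPrediction",
    "SpeciesRecord",
    "predict_additive",
    "predict_mean",
    "predict_weighted_mean",
    "predict_strongest",
    "predict_trio_from_pairs",
    "predict_all",
]

MODELS = ("additive", "mean", "weighted_mean", "strongest")


@dataclass(frozen=True)
class ModelPrediction:
    community: CommunityKey
    model: str
    basis: str  # "singles" or "pairs"
    value: float  # predicted natural-log effect
    censored: bool = False  # any contributing effect was censored
    tie: bool = False  # strongest-model tie broken toward negative


@dataclass(frozen=True)
class SpeciesRecord:
    """Per-species metadata used by models and filters."""

    species_id: str
    max_od: float = np.nan  # carrying capacity (OD600)
    autofluorescence: float = 0.0
    growth_rate: float = np.nan  # 1/h, optional
    carbon_profile: tuple[float, ...] = ()
    antibiotic_profile: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.max_od) and self.max_od < 0:
            raise ValueError(f"{self.species_id}: max_od must be >= 0")
        if self.autofluorescence < 0:
            raise ValueError(f"{self.species_id}: autofluorescence must be >= 0")


def _check(effects: Sequence[float]) -> np.ndarray:
    arr = np.asarray(effects, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one effect")
    if not np.all(np.isfinite(arr)):
        raise ValueError("effects must be finite")
    return arr


def predict_additive(effects: Sequence[float]) -> float:
    """Sum of the effects."""
    return float(_check(effects).sum())


def predict_mean(effects: Sequence[float]) -> float:
    """Arithmetic mean of the effects."""
    return float(_check(effects).mean())


def predict_weighted_mean(effects: Sequence[float], max_ods: Sequence[float]) -> float:
    """Mean of effects weighted by the species' maximum OD600."""
    arr = _check(effects)
    w = np.asarray(max_ods, dtype=float)
    if w.shape != arr.shape:
        raise ValueError("effects and max_ods must have equal length")
    if np.any(w < 0):
        raise ValueError("max OD weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("all max OD weights are zero")
    return float((arr * w).sum() / total)


def predict_strongest(effects: Sequence[float]) -> tuple[float, bool]:
    """The effect with the largest absolute value.

    A tie between equal magnitudes of opposite sign is broken toward the
    negative value (negative effects dominate the screen); the returned
    flag marks that a tie occurred.
    """
    arr = _check(effects)
    top = np.abs(arr).max()
    at_top = arr[np.abs(arr) == top]
    tie = bool(np.unique(at_top).size > 1)
    return float(at_top.min()), tie


def _apply(model: str, effects: Sequence[float], max_ods: Sequence[float] | None = None):
    if model == "additive":
        return predict_additive(effects), False
    if model == "mean":
        return predict_mean(effects), False
    if model == "weighted_mean":
        if max_ods is None:
            raise ValueError("weighted_mean requires max OD weights")
        return predict_weighted_mean(effects, max_ods), False
    if model == "strongest":
        return predict_strongest(effects)
    raise ValueError(f"unknown model {model!r}")


def predict_trio_from_pairs(
    pair_effects: Mapping[frozenset[str], float],
    model: str,
) -> float:
    """Apply a combination model to a trio's three pair effects.

    ``pair_effects`` maps each 2-subset of the trio to its measured joint
    effect; all three pairs must be present.
    """
    species = sorted(set().union(*pair_effects))
    if len(species) != 3 or len(pair_effects) != 3:
        raise ValueError("need exactly the three pair effects of one trio")
    from itertools import combinations

    missing = [set(p) for p in combinations(species, 2) if frozenset(p) not in pair_effects]
    if missing:
        raise ValueError(f"missing pair effect(s): {missing}")
    value, _ = _apply(model, [pair_effects[frozenset(p)] for p in combinations(species, 2)])
    return value


def predict_all(
    effect_table: Sequence[EffectEstimate] | Mapping[CommunityKey, float],
    communities: Iterable[CommunityKey],
    models: Sequence[str] = MODELS,
    basis: str = "singles",
    species: Mapping[str, SpeciesRecord] | None = None,
    allow_censored: bool = True,
) -> tuple[list[ModelPrediction], list[tuple[CommunityKey, str]]]:
    """Predict joint effects for many communities under several models.

    basis="singles" combines the single-species effects of each member;
    basis="pairs" (trios only) combines the three measured pair effects.
    Communities whose required lower-order effects are missing are skipped
    and logged.  Neutral-classified effects contribute their point
    estimates — neutrality is a reporting category, not a zeroing rule.
    """
    if basis not in ("singles", "pairs"):
        raise ValueError(f"unknown basis {basis!r}")
    unknown = [m for m in models if m not in MODELS]
    if unknown:
        raise ValueError(f"unknown model(s): {unknown}")

    if isinstance(effect_table, Mapping):
        lookup = dict(effect_table)
        censored: set[CommunityKey] = set()
    else:
        lookup = {e.community: e.effect for e in effect_table}
        censored = {e.community for e in effect_table if e.censored}

    out: list[ModelPrediction] = []
    skipped: list[tuple[CommunityKey, str]] = []
    for comm in communities:
        if basis == "pairs":
            if comm.order != 3:
                skipped.append((comm, "pairs basis requires a trio"))
                continue
            from itertools import combinations

            needed = {
                frozenset(p): CommunityKey(comm.focal_id, frozenset(p))
                for p in combinations(sorted(comm.affecting_set), 2)
            }
            missing = [k for k, ck in needed.items() if ck not in lookup]
            if missing:
                skipped.append((comm, f"missing pair(s): {[sorted(m) for m in missing]}"))
                continue
            parts = {ck for ck in needed.values()}
            inputs = [lookup[ck] for ck in sorted(parts)]
            weights = None  # max-OD weights undefined for pair effects
            use_models = [m for m in models if m != "weighted_mean"]
        else:
            members = sorted(comm.affecting_set)
            singles = [CommunityKey(comm.focal_id, frozenset([s])) for s in members]
            missing_s = [s for s, ck in zip(members, singles) if ck not in lookup]
            if missing_s:
                skipped.append((comm, f"missing single(s): {missing_s}"))
                continue
            parts = set(singles)
            inputs = [lookup[ck] for ck in singles]
            weights = None
            if species is not None and "weighted_mean" in models:
                weights = [species[s].max_od for s in members if s in species]
                if len(weights) != len(members) or not np.all(np.isfinite(weights)):
                    weights = None
            use_models = [m for m in models if m != "weighted_mean" or weights is not None]
        if not allow_censored and parts & censored:
            skipped.append((comm, "censored lower-order effect"))
            continue
        is_censored = bool(parts & censored)
        for model in use_models:
            value, tie = _apply(model, inputs, weights)
            out.append(
                ModelPrediction(
                    community=comm,
                    model=model,
                    basis=basis,
                    value=value,
                    censored=is_censored,
                    tie=tie,
                )
            )
    return out, skipped
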