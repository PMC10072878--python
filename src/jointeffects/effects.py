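"""Effect-size estimation from well-level fluorescence.

The effect of a community of affecting species on its fluorescent focal is
the natural-log ratio of the focal's median growth in coculture to its
median growth in monoculture,

    effect = ln( median(coculture growth) / median(monoculture growth) ),

where growth is the analysis-timepoint fluorescence reading minus the
well's own t=0 reading.  Uncertainty comes from an independent bootstrap of
the two well groups (B=100 by default); effects whose bootstrap standard
deviation exceeds their absolute value are classified as neutral.

Filtering follows the screen's rules: communities with fewer than three
replicate wells are dropped, and an affecting species is only used with
focals whose monoculture signal is at least five times the affecting
species' autofluorescence — which bounds measurable negative effects at
ln(1/5) = -1.61.  Coculture medians at or below the autofluorescence floor
yield censored estimates clamped at the floor.
"""

from __future__ import annotations

import sys
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import CommunityKey

__all__ = [
    "WellRecord",
    "FilterConfig",
    "EffectEstimate",
    "baseline_normalize",
    "filter_replicates",
    "filter_autofluorescence",
    "effect_estimate",
    "bootstrap_se",
    "classify_sign",
    "summarize_distribution",
    "growth_by_community",
    "estimate_effects",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class WellRecord:
    """One well: community identity plus its fluorescence timecourse."""

    well_id: str
    community: CommunityKey
    readings: Mapping[float, float]  # timepoint (h) -> fluorescence (a.u.)

    def __post_init__(self) -> None:
        if 0.0 not in self.readings:
            raise ValueError(f"well {self.well_id!r}: missing t=0 reading")
        if not all(np.isfinite(v) for v in self.readings.values()):
            raise ValueError(f"well {self.well_id!r}: non-finite reading")


@dataclass(frozen=True)
class FilterConfig:
    """Filtering and normalization parameters.

    min_replicates
        Minimum wells per community (after dosage pooling); default 3.
    autofluorescence_factor
        Monoculture median must be at least this multiple of each affecting
        species' autofluorescence (inclusive boundary); default 5.
    analysis_timepoint_h
        Timepoint used for effect estimation; default 24 h, by which
        focal monocultures have saturated.
    """

    min_replicates: int = 3
    autofluorescence_factor: float = 5.0
    analysis_timepoint_h: float = 24.0
    bootstrap_b: int = 100

    def __post_init__(self) -> None:
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.autofluorescence_factor <= 0:
            raise ValueError("autofluorescence_factor must be > 0")


@dataclass(frozen=True)
class EffectEstimate:
    """A community's estimated effect on its focal species."""

    community: CommunityKey
    effect: float  # natural-log ratio
    se: float  # bootstrap standard deviation
    n_wells: int
    sign: str = field(default=NEUTRAL)
    censored: bool = False


def baseline_normalize(readings: Mapping[float, float]) -> tuple[dict[float, float], bool]:
    """Subtract each well's own t=0 reading from every timepoint.

    Returns the growth timecourse and a flag marking wells where any
    post-baseline growth value is negative (signal below its own start).
    Negative values are retained, not truncated.
    """
    if 0.0 not in readings:
        raise ValueError("timecourse lacks a t=0 reading")
    t0 = readings[0.0]
    growth = {t: v - t0 for t, v in readings.items()}
    flagged = any(v < 0 for t, v in growth.items() if t > 0)
    return growth, flagged


def filter_replicates(
    wells_by_community: Mapping[CommunityKey, Sequence],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[dict[CommunityKey, Sequence], list[tuple[CommunityKey, str]]]:
    """Drop communities with fewer than ``cfg.min_replicates`` wells.

    Returns the retained mapping and a drop log of (community, reason).
    """
    kept: dict[CommunityKey, Sequence] = {}
    dropped: list[tuple[CommunityKey, str]] = []
    for key, wells in wells_by_community.items():
        n = len(wells)
        if n < cfg.min_replicates:
            dropped.append((key, f"{n} replicates < {cfg.min_replicates}"))
        else:
            kept[key] = wells
    return kept, dropped


def filter_autofluorescence(
    mono_growth_median: float,
    affecting_autofluorescence: float,
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Keep an affecting/focal combination iff the focal's monoculture
    median is at least ``factor`` times the affecting autofluorescence
    (boundary inclusive)."""
    if mono_growth_median < 0 or affecting_autofluorescence < 0:
        raise ValueError("signals must be non-negative")
    return mono_growth_median >= cfg.autofluorescence_factor * affecting_autofluorescence


def _median(values: Sequence[float] | np.ndarray) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def effect_estimate(
    co_wells: Sequence[float] | np.ndarray,
    mono_wells: Sequence[float] | np.ndarray,
    community: CommunityKey | None = None,
    detection_floor: float = sys.float_info.epsilon,
) -> EffectEstimate:
    """Point estimate of a community's effect on its focal.

    ``co_wells`` and ``mono_wells`` are growth values at the analysis
    timepoint.  If the coculture median falls at or below
    ``detection_floor`` (normally the affecting autofluorescence), the
    effect is clamped at ln(floor / mono median) and flagged censored:
    signal below autofluorescence is unidentifiable.
    """
    med_mono = _median(mono_wells)
    if med_mono <= 0:
        raise ValueError("monoculture median <= 0: focal failed to grow")
    med_co = _median(co_wells)
    floor = max(detection_floor, sys.float_info.epsilon)
    if med_co <= floor:
        return EffectEstimate(
            community=community or _ANON,
            effect=float(np.log(floor / med_mono)),
            se=np.nan,
            n_wells=len(co_wells),
            censored=True,
        )
    return EffectEstimate(
        community=community or _ANON,
        effect=float(np.log(med_co / med_mono)),
        se=np.nan,
        n_wells=len(co_wells),
    )


_ANON = CommunityKey(focal_id="?", affecting_set=frozenset())


def bootstrap_se(
    co_wells: Sequence[float] | np.ndarray,
    mono_wells: Sequence[float] | np.ndarray,
    b: int = 100,
    rng: np.random.Generator | int | None = None,
    detection_floor: float = sys.float_info.epsilon,
) -> float:
    """Bootstrap standard deviation of the log-ratio effect.

    Both groups are resampled with replacement independently, ``b`` times;
    the SD over the resulting log-ratio effects is returned.  Resampled
    coculture medians at or below the detection floor are clamped at the
    floor (matching the censoring rule) so the SD stays finite.
    """
    co = np.asarray(co_wells, dtype=float)
    mono = np.asarray(mono_wells, dtype=float)
    if co.size == 0 or mono.size == 0:
        raise ValueError("both well groups must be nonempty")
    rng = np.random.default_rng(rng)
    co_idx = rng.integers(0, co.size, size=(b, co.size))
    mono_idx = rng.integers(0, mono.size, size=(b, mono.size))
    med_co = np.median(co[co_idx], axis=1)
    med_mono = np.median(mono[mono_idx], axis=1)
    floor = max(detection_floor, sys.float_info.epsilon)
    med_co = np.maximum(med_co, floor)
    med_mono = np.maximum(med_mono, sys.float_info.epsilon)
    eff = np.log(med_co / med_mono)
    if np.ptp(eff) == 0.0:  # degenerate groups: exactly zero, no float residue
        return 0.0
    return float(np.std(eff))


def classify_sign(effect: float, se: float) -> str:
    """Neutral iff the bootstrap SD exceeds |effect|; else the point sign.

    A zero effect that is not neutral is treated as positive (consistent
    with sign stratification downstream).
    """
    if se > abs(effect):
        return NEUTRAL
    return NEGATIVE if effect < 0 else POSITIVE


def summarize_distribution(
    effects: Sequence[EffectEstimate] | Sequence[float],
) -> dict[str, float]:
    """Median, IQR and sign fractions of a set of effects.

    Quantiles use linear interpolation (type 7).  Sign fractions come from
    the stored classification when :class:`EffectEstimate` objects are
    given, else from the point-estimate sign (zero counted positive, no
    neutral category).
    """
    if len(effects) == 0:
        raise ValueError("no effects to summarize")
    if isinstance(effects[0], EffectEstimate):
        values = np.array([e.effect for e in effects], dtype=float)
        signs = [e.sign for e in effects]
    else:
        values = np.asarray(effects, dtype=float)
        signs = [NEGATIVE if v < 0 else POSITIVE for v in values]
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    n = len(signs)
    return {
        "median": float(q50),
        "iqr": float(q75 - q25),
        "frac_positive": signs.count(POSITIVE) / n,
        "frac_negative": signs.count(NEGATIVE) / n,
        "frac_neutral": signs.count(NEUTRAL) / n,
        "n": n,
    }


def growth_by_community(
    wells: Iterable[WellRecord],
    cfg: FilterConfig = FilterConfig(),
) -> dict[CommunityKey, np.ndarray]:
    """Baseline-normalize wells and collect analysis-timepoint growth
    values per community (one value per well)."""
    t = cfg.analysis_timepoint_h
    grouped: dict[CommunityKey, list[float]] = {}
    for w in wells:
        growth, _ = baseline_normalize(w.readings)
        if t not in growth:
            raise ValueError(f"well {w.well_id!r}: no reading at t={t} h")
        grouped.setdefault(w.community, []).append(growth[t])
    return {k: np.asarray(v, dtype=float) for k, v in grouped.items()}


def _community_rng(seed: int, key: CommunityKey) -> np.random.Generator:
    # deterministic per-community substream: independent of iteration order
    crc = zlib.crc32(key.label().encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), crc]))


def estimate_effects(
    growth: Mapping[CommunityKey, np.ndarray],
    autofluorescence: Mapping[str, float] | None = None,
    cfg: FilterConfig = FilterConfig(),
    seed: int = 0,
) -> tuple[list[EffectEstimate], list[tuple[CommunityKey, str]]]:
    """Estimate effects for every non-monoculture community.

    ``growth`` maps each community (including the focal monocultures,
    i.e. keys with an empty affecting set) to its per-well growth values
    at the analysis timepoint.  Applies the replicate and autofluorescence
    filters, computes point estimates with censoring at the summed
    autofluorescence of the affecting members, bootstraps the SE, and
    classifies signs.  Returns estimates sorted by community plus a drop
    log.
    """
    autofluorescence = autofluorescence or {}
    kept, dropped = filter_replicates(growth, cfg)

    mono_medians: dict[str, float] = {}
    mono_values: dict[str, np.ndarray] = {}
    for key, vals in kept.items():
        if key.is_monoculture:
            mono_medians[key.focal_id] = _median(vals)
            mono_values[key.focal_id] = vals

    estimates: list[EffectEstimate] = []
    for key in sorted(k for k in kept if not k.is_monoculture):
        if key.focal_id not in mono_values:
            dropped.append((key, "no monoculture wells for focal"))
            continue
        mono_med = mono_medians[key.focal_id]
        if mono_med <= 0:
            dropped.append((key, "monoculture median <= 0"))
            continue
        bad = [
            sp
            for sp in sorted(key.affecting_set)
            if sp in autofluorescence
            and not filter_autofluorescence(mono_med, autofluorescence[sp], cfg)
        ]
        if bad:
            dropped.append((key, f"autofluorescence filter: {','.join(bad)}"))
            continue
        floor = sum(autofluorescence.get(sp, 0.0) for sp in key.affecting_set)
        floor = max(floor, sys.float_info.epsilon)
        est = effect_estimate(kept[key], mono_values[key.focal_id], key, floor)
        se = bootstrap_se(
            kept[key],
            mono_values[key.focal_id],
            b=cfg.bootstrap_b,
            rng=_community_rng(seed, key),
            detection_floor=floor,
        )
        estimates.append(
            EffectEstimate(
                community=key,
                effect=est.effect,
                se=se,
                n_wells=est.n_wells,
                sign=classify_sign(est.effect, se),
                censored=est.censored,
            )
        )
    return estimates, dropped
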