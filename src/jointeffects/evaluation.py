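"""Model accuracy: IQR-normalized RMSE with a well-level bootstrap.

A model's accuracy over a set of communities is the root-mean-square
difference between predicted and observed joint effects, normalized to the
interquartile range of the observed effects of that same set (nRMSE).
Uncertainty comes from a well-level bootstrap: within each focal species'
dataset, the wells of every community (monocultures included) are
resampled with replacement; median growth, single/pair/trio effects, and
model predictions are all recomputed from the resampled wells; the
per-focal resamples are assembled into a full dataset from which one nRMSE
per model is computed.  The summary over B such replicates is the median
and IQR of the nRMSE values.

Pair communities can further be stratified by the point-estimate signs of
their members' single effects (neg-neg / neg-pos / pos-pos); each stratum
is normalized to its own observed IQR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import CommunityKey
from .effects import EffectEstimate, FilterConfig
from .models import MODELS, ModelPrediction, SpeciesRecord

__all__ = [
    "EvalConfig",
    "EvaluationSummary",
    "nrmse",
    "stratify_by_sign",
    "bootstrap_nrmse",
    "error_distribution",
    "model_ranking",
]

STRATA = ("neg-neg", "neg-pos", "pos-pos")


@dataclass(frozen=True)
class EvalConfig:
    """Bootstrap-evaluation parameters (B=1000 matches the screen)."""

    n_bootstrap: int = 1000
    seed: int = 0
    stratify: bool = False
    basis: str = "singles"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.basis not in ("singles", "pairs"):
            raise ValueError(f"unknown basis {self.basis!r}")


@dataclass(frozen=True)
class EvaluationSummary:
    stratum: str  # "all", "neg-neg", "neg-pos", "pos-pos"
    model: str
    basis: str
    nrmse_median: float
    nrmse_iqr: float
    n_communities: int
    n_bootstrap: int
    n_missing: int = 0  # replicates where the stratum degenerated


def nrmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """RMSE of predictions divided by the IQR of the observed values."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    iqr = float(np.quantile(obs, 0.75) - np.quantile(obs, 0.25))
    if iqr <= 0:
        raise ValueError("observed IQR is zero: degenerate evaluation set")
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / iqr)


def stratify_by_sign(
    pair_communities: Iterable[CommunityKey],
    single_effects: Mapping[CommunityKey, float] | Sequence[EffectEstimate],
) -> tuple[dict[CommunityKey, str], list[tuple[CommunityKey, str]]]:
    """Assign each community a stratum from its members' single-effect signs.

    Uses point-estimate signs (zero counts as positive); communities with
    any unmeasured single are excluded and logged.  Mixed-sign sets of any
    size map to "neg-pos".
    """
    if not isinstance(single_effects, Mapping):
        single_effects = {e.community: e.effect for e in single_effects}
    strata: dict[CommunityKey, str] = {}
    excluded: list[tuple[CommunityKey, str]] = []
    for comm in pair_communities:
        singles = [CommunityKey(comm.focal_id, frozenset([s])) for s in sorted(comm.affecting_set)]
        missing = [sorted(ck.affecting_set)[0] for ck in singles if ck not in single_effects]
        if missing:
            excluded.append((comm, f"missing single(s): {missing}"))
            continue
        n_neg = sum(single_effects[ck] < 0 for ck in singles)
        if n_neg == 0:
            strata[comm] = "pos-pos"
        elif n_neg == len(singles):
            strata[comm] = "neg-neg"
        else:
            strata[comm] = "neg-pos"
    return strata, excluded


def _strongest_rows(arr: np.ndarray) -> np.ndarray:
    """Row-wise max-abs element with ties broken toward the negative."""
    top = np.max(np.abs(arr), axis=1, keepdims=True)
    masked = np.where(np.abs(arr) == top, arr, np.inf)
    return masked.min(axis=1)


def _resampled_medians(
    growth: Mapping[CommunityKey, np.ndarray],
    b: int,
    rng: np.random.Generator,
    resample: bool,
) -> dict[CommunityKey, np.ndarray]:
    med: dict[CommunityKey, np.ndarray] = {}
    for key in sorted(growth):  # sorted: reproducible rng consumption
        vals = np.asarray(growth[key], dtype=float)
        if resample:
            idx = rng.integers(0, vals.size, size=(b, vals.size))
            med[key] = np.median(vals[idx], axis=1)
        else:
            med[key] = np.full(b, np.median(vals))
    return med


def _log_effects(
    med: Mapping[CommunityKey, np.ndarray],
    keys: Iterable[CommunityKey],
    mono: Mapping[str, np.ndarray],
) -> dict[CommunityKey, np.ndarray]:
    out: dict[CommunityKey, np.ndarray] = {}
    for key in keys:
        m = mono.get(key.focal_id)
        if m is None:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = med[key] / m
            eff = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), np.nan)
        out[key] = eff
    return out


def _predictions_matrix(
    targets: Sequence[CommunityKey],
    effects_b: Mapping[CommunityKey, np.ndarray],
    model: str,
    basis: str,
    species: Mapping[str, SpeciesRecord] | None,
    b: int,
) -> np.ndarray:
    """(B, n_targets) matrix of model predictions from resampled effects."""
    pred = np.full((b, len(targets)), np.nan)
    for j, comm in enumerate(targets):
        if basis == "pairs":
            parts = [
                CommunityKey(comm.focal_id, frozenset(p))
                for p in combinations(sorted(comm.affecting_set), 2)
            ]
        else:
            parts = [CommunityKey(comm.focal_id, frozenset([s])) for s in sorted(comm.affecting_set)]
        if any(p not in effects_b for p in parts):
            continue
        arr = np.column_stack([effects_b[p] for p in parts])  # (B, k)
        if model == "additive":
            pred[:, j] = arr.sum(axis=1)
        elif model == "mean":
            pred[:, j] = arr.mean(axis=1)
        elif model == "strongest":
            pred[:, j] = _strongest_rows(arr)
        elif model == "weighted_mean":
            if basis == "pairs" or species is None:
                continue
            w = np.array([species[s].max_od for s in sorted(comm.affecting_set) if s in species])
            if w.size != comm.order or not np.all(np.isfinite(w)) or w.sum() <= 0:
                continue
            pred[:, j] = arr @ w / w.sum()
        else:
            raise ValueError(f"unknown model {model!r}")
    return pred


def bootstrap_nrmse(
    growth: Mapping[CommunityKey, np.ndarray],
    models: Sequence[str] = ("additive", "mean", "strongest"),
    cfg: EvalConfig = EvalConfig(),
    species: Mapping[str, SpeciesRecord] | None = None,
    target_order: int = 2,
    filter_cfg: FilterConfig | None = FilterConfig(),
    resample: bool = True,
) -> list[EvaluationSummary]:
    """Bootstrap nRMSE summaries for each model (and stratum if configured).

    ``growth`` maps every community — focal monocultures included — to its
    per-well growth values at the analysis timepoint.  ``target_order``
    selects the communities being predicted (2 = pairs, 3 = trios);
    ``cfg.basis`` selects whether trio predictions combine singles or the
    measured pair effects.  With ``resample=False`` the "bootstrap"
    degenerates to the point estimates (useful as a fast noise-free check).
    """
    unknown = [m for m in models if m not in MODELS]
    if unknown:
        raise ValueError(f"unknown model(s): {unknown}")
    if cfg.basis == "pairs" and target_order != 3:
        raise ValueError("pairs basis only applies to trio targets")

    if filter_cfg is not None:
        growth = {k: v for k, v in growth.items() if len(v) >= filter_cfg.min_replicates}

    monos = {k for k in growth if k.is_monoculture}
    targets_all = sorted(k for k in growth if k.order == target_order)
    if cfg.basis == "pairs":
        needed_order = 2
    else:
        needed_order = 1
    lower = {k for k in growth if k.order in (needed_order, 1)}

    def parts_of(comm: CommunityKey) -> list[CommunityKey]:
        if cfg.basis == "pairs":
            return [
                CommunityKey(comm.focal_id, frozenset(p))
                for p in combinations(sorted(comm.affecting_set), 2)
            ]
        return [CommunityKey(comm.focal_id, frozenset([s])) for s in sorted(comm.affecting_set)]

    targets = [
        t
        for t in targets_all
        if CommunityKey(t.focal_id, frozenset()) in monos
        and all(p in growth for p in parts_of(t))
    ]
    if len(targets) < 2:
        raise ValueError("fewer than two evaluable communities")

    b = cfg.n_bootstrap
    rng = np.random.default_rng(cfg.seed)
    needed_keys = set(targets) | {p for t in targets for p in parts_of(t)}
    needed_keys |= {CommunityKey(t.focal_id, frozenset()) for t in targets}
    if cfg.stratify and target_order == 2:
        # strata need single point estimates even under the pairs basis
        needed_keys |= {
            CommunityKey(t.focal_id, frozenset([s])) for t in targets for s in t.affecting_set
        } & set(growth)
    med = _resampled_medians({k: growth[k] for k in needed_keys if k in growth}, b, rng, resample)

    mono_med = {k.focal_id: med[k] for k in med if k.is_monoculture}
    effects_b = _log_effects(med, [k for k in med if not k.is_monoculture], mono_med)
    obs = np.column_stack([effects_b[t] for t in targets])  # (B, n)

    # strata from full-data point estimates of the singles
    strata_names: list[str] = ["all"]
    membership: dict[str, np.ndarray] = {"all": np.ones(len(targets), dtype=bool)}
    if cfg.stratify and target_order == 2:
        point_singles = {
            k: float(np.log(np.median(growth[k]) / np.median(growth[CommunityKey(k.focal_id, frozenset())])))
            for k in growth
            if k.order == 1 and np.median(growth[k]) > 0
            and np.median(growth[CommunityKey(k.focal_id, frozenset())]) > 0
        }
        strat_map, _ = stratify_by_sign(targets, point_singles)
        for name in STRATA:
            mask = np.array([strat_map.get(t) == name for t in targets])
            if mask.sum() >= 2:
                membership[name] = mask
                strata_names.append(name)

    summaries: list[EvaluationSummary] = []
    for model in models:
        pred = _predictions_matrix(targets, effects_b, model, cfg.basis, species, b)
        for stratum in strata_names:
            mask = membership[stratum]
            o = obs[:, mask]
            p = pred[:, mask]
            valid = np.isfinite(o) & np.isfinite(p)
            nrmse_b = np.full(b, np.nan)
            for i in range(b):
                v = valid[i]
                if v.sum() < 2:
                    continue
                iqr = np.quantile(o[i, v], 0.75) - np.quantile(o[i, v], 0.25)
                if iqr <= 0:
                    continue
                nrmse_b[i] = np.sqrt(np.mean((p[i, v] - o[i, v]) ** 2)) / iqr
            ok = np.isfinite(nrmse_b)
            if ok.any():
                q25, q50, q75 = np.quantile(nrmse_b[ok], [0.25, 0.5, 0.75])
            else:
                q25 = q50 = q75 = np.nan
            summaries.append(
                EvaluationSummary(
                    stratum=stratum,
                    model=model,
                    basis=cfg.basis,
                    nrmse_median=float(q50),
                    nrmse_iqr=float(q75 - q25),
                    n_communities=int(mask.sum()),
                    n_bootstrap=b,
                    n_missing=int(b - ok.sum()),
                )
            )
    return summaries


def error_distribution(
    predictions: Sequence[ModelPrediction],
    observations: Mapping[CommunityKey, float],
    stratum_communities: Iterable[CommunityKey] | None = None,
) -> dict[str, dict[str, object]]:
    """Signed prediction errors (predicted - observed) per model.

    A positive error means the prediction exceeds the observation on the
    log scale (for negative joint effects: the model underestimated the
    magnitude).  Returns, per model, the error vector with its median and
    IQR, restricted to ``stratum_communities`` when given.
    """
    keep = None if stratum_communities is None else set(stratum_communities)
    by_model: dict[str, list[float]] = {}
    for p in predictions:
        if p.community not in observations:
            continue
        if keep is not None and p.community not in keep:
            continue
        by_model.setdefault(p.model, []).append(p.value - observations[p.community])
    out: dict[str, dict[str, object]] = {}
    for model, errs in by_model.items():
        arr = np.asarray(errs, dtype=float)
        q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
        out[model] = {"errors": arr, "median": float(q50), "iqr": float(q75 - q25), "n": arr.size}
    return out


def model_ranking(
    summaries: Sequence[EvaluationSummary],
) -> dict[str, dict[str, object]]:
    """Order models by ascending median nRMSE within each stratum."""
    by_stratum: dict[str, list[EvaluationSummary]] = {}
    for s in summaries:
        by_stratum.setdefault(s.stratum, []).append(s)
    out: dict[str, dict[str, object]] = {}
    for stratum, rows in by_stratum.items():
        rows = sorted(rows, key=lambda r: (r.nrmse_median, r.model))
        medians = [r.nrmse_median for r in rows]
        out[stratum] = {
            "ranking": [r.model for r in rows],
            "tie": len(set(medians)) < len(medians),
        }
    return out
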