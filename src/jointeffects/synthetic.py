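"""Synthetic kChip-style datasets with known ground truth.

The generator emulates the structure of a droplet coculture screen: a
panel of affecting species with heterogeneous single effects on each
focal (negative-skewed, roughly one third positive), joint effects built
from a chosen combination rule plus lognormal measurement noise on the
fluorescence signal, stochastic replicate counts per community, per-species
autofluorescence, and per-well baseline offsets removed by t=0
subtraction.  Because the generating rule and every effect are recorded,
the full pipeline (estimate -> predict -> evaluate) can be validated
end to end: with all noise switched off the estimates recover the truth
exactly, and with realistic noise the evaluation should rank the
generating rule's model first.

Single effects are drawn from a two-sided exponential mixture whose rates
are solved in closed form so that the population median, IQR and positive
fraction match the configured targets (defaults: median -0.15, IQR 0.94,
33% positive).  Replicate counts follow a discretized lognormal (sigma=1)
truncated to the configured range, with its location solved numerically so
the truncated mean matches the target (default 19, range 1-285) — a
right-skewed law consistent with random droplet pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .composition import CommunityKey, InputCulture
from .effects import WellRecord
from .models import SpeciesRecord, predict_additive, predict_mean, predict_strongest, predict_weighted_mean

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "draw_single_effects",
    "make_joint_effects",
    "simulate_wells",
    "generate_scenario",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate the screen's conditions."""

    n_affecting: int = 30
    n_focal: int = 2
    effect_median: float = -0.15  # log units
    effect_iqr: float = 0.94
    frac_positive: float = 0.33
    truth_rule: str = "strongest"
    joint_noise_sd: float = 0.15  # log units, on joint effects
    replicate_mean: float = 19.0
    replicate_range: tuple[int, int] = (1, 285)
    mono_replicates: int = 50  # focal monocultures are heavily replicated
    autofluorescence_scale: float = 20.0  # a.u.; exponential scale per species
    mono_signal_mean: float = 1000.0  # a.u.; median monoculture growth
    measurement_cv: float = 0.1  # lognormal CV on growth signal
    timepoints_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    include_pairs: bool = True
    include_trios: bool = False
    dosage_variants: bool = False  # literal droplet-pooling mode
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_positive <= 1:
            raise ValueError("frac_positive must be in [0, 1]")
        if self.n_affecting < 1 or self.n_focal < 1:
            raise ValueError("species counts must be positive")
        lo, hi = self.replicate_range
        if lo > hi or lo < 1:
            raise ValueError("replicate_range must be ordered with lower bound >= 1")
        if self.truth_rule not in ("additive", "mean", "weighted_mean", "strongest"):
            raise ValueError(f"unknown truth_rule {self.truth_rule!r}")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated scenario."""

    single_effects: dict[CommunityKey, float]
    joint_effects: dict[CommunityKey, float]
    noise_draws: dict[CommunityKey, float]
    species: dict[str, SpeciesRecord]
    focal_ids: tuple[str, ...]
    config: SyntheticConfig


def _exp_mixture_rates(median: float, iqr: float, frac_positive: float) -> tuple[float, float]:
    """Closed-form rates of the two-sided exponential mixture.

    Negative side ~ -Exp(scale lam_n) with weight q = 1 - frac_positive,
    positive side ~ +Exp(scale lam_p).  In the supported regime
    (0.5 < q < 0.75 and median < 0) the quartiles give both scales
    analytically; the degenerate one-sided cases fit the median only.
    """
    p, q = frac_positive, 1.0 - frac_positive
    if p == 0:
        if median >= 0:
            raise ValueError("all-negative mixture needs a negative median")
        return -median / np.log(2.0), 1.0
    if p == 1:
        if median <= 0:
            raise ValueError("all-positive mixture needs a positive median")
        return 1.0, median / np.log(2.0)
    if not (0.5 < q < 0.75) or median >= 0:
        raise ValueError(
            "supported regime: negative median with positive fraction in (0.25, 0.5)"
        )
    lam_n = median / np.log(0.5 / q)
    q25 = lam_n * np.log(0.25 / q)
    q75 = iqr + q25
    if q75 <= 0:
        raise ValueError("IQR too small for the requested median / positive fraction")
    lam_p = q75 / (-np.log(1.0 - (0.75 - q) / p))
    return lam_n, lam_p


def draw_single_effects(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    focal_ids: tuple[str, ...] | None = None,
    affecting_ids: tuple[str, ...] | None = None,
) -> dict[CommunityKey, float]:
    """Draw a ground-truth single effect for every (focal, affecting) pair."""
    focal_ids = focal_ids or tuple(f"F{i:02d}" for i in range(cfg.n_focal))
    affecting_ids = affecting_ids or tuple(f"A{i:03d}" for i in range(cfg.n_affecting))
    lam_n, lam_p = _exp_mixture_rates(cfg.effect_median, cfg.effect_iqr, cfg.frac_positive)
    out: dict[CommunityKey, float] = {}
    for focal in focal_ids:
        for sp in affecting_ids:
            positive = rng.random() < cfg.frac_positive
            mag = rng.exponential(lam_p if positive else lam_n)
            out[CommunityKey(focal, frozenset([sp]))] = mag if positive else -mag
    return out


def _rule_value(rule: str, effects: list[float], max_ods: list[float]) -> float:
    if rule == "additive":
        return predict_additive(effects)
    if rule == "mean":
        return predict_mean(effects)
    if rule == "weighted_mean":
        return predict_weighted_mean(effects, max_ods)
    if rule == "strongest":
        return predict_strongest(effects)[0]
    raise ValueError(f"unknown rule {rule!r}")


def make_joint_effects(
    singles: Mapping[CommunityKey, float],
    truth_rule: str,
    joint_noise_sd: float,
    rng: np.random.Generator,
    species: Mapping[str, SpeciesRecord] | None = None,
    orders: tuple[int, ...] = (2,),
) -> tuple[dict[CommunityKey, float], dict[CommunityKey, float]]:
    """Joint effects = rule(member singles) + Normal(0, sd) noise.

    Returns (joint effects, recorded noise draws).  Trio joints (order 3)
    are built from the three member singles, not from pair joints.
    """
    by_focal: dict[str, list[str]] = {}
    for key in singles:
        by_focal.setdefault(key.focal_id, []).append(sorted(key.affecting_set)[0])
    joints: dict[CommunityKey, float] = {}
    noise: dict[CommunityKey, float] = {}
    for focal in sorted(by_focal):
        members = sorted(by_focal[focal])
        for order in orders:
            for combo in combinations(members, order):
                effs = [singles[CommunityKey(focal, frozenset([s]))] for s in combo]
                ods = [species[s].max_od for s in combo] if species else [1.0] * order
                base = _rule_value(truth_rule, effs, ods)
                eps = rng.normal(0.0, joint_noise_sd) if joint_noise_sd > 0 else 0.0
                key = CommunityKey(focal, frozenset(combo))
                joints[key] = base + eps
                noise[key] = eps
    return joints, noise


def _replicate_law_mu(mean: float, lo: int, hi: int, sigma: float = 1.0) -> float:
    """Location of the lognormal replicate law so the discretized,
    range-truncated mean hits the target."""
    ks = np.arange(lo, hi + 1, dtype=float)
    upper = np.log(ks + 0.5)
    lower = np.log(np.maximum(ks - 0.5, 1e-12))

    def truncated_mean(mu: float) -> float:
        prob = norm.cdf((upper - mu) / sigma) - norm.cdf((lower - mu) / sigma)
        prob[0] = norm.cdf((upper[0] - mu) / sigma)  # everything below rounds up to lo
        prob[-1] = 1.0 - norm.cdf((lower[-1] - mu) / sigma)  # and above clips to hi
        return float((ks * prob).sum())

    return brentq(lambda mu: truncated_mean(mu) - mean, -3.0, 10.0, xtol=1e-10)


def draw_replicate_counts(
    n: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    sigma: float = 1.0,
) -> np.ndarray:
    lo, hi = cfg.replicate_range
    if lo == hi:
        return np.full(n, lo, dtype=int)
    mu = _replicate_law_mu(cfg.replicate_mean, lo, hi, sigma)
    raw = rng.lognormal(mu, sigma, size=n)
    return np.clip(np.round(raw), lo, hi).astype(int)


def _species_records(
    cfg: SyntheticConfig, rng: np.random.Generator, affecting_ids: tuple[str, ...]
) -> dict[str, SpeciesRecord]:
    recs: dict[str, SpeciesRecord] = {}
    for sp in affecting_ids:
        recs[sp] = SpeciesRecord(
            species_id=sp,
            max_od=float(rng.uniform(0.1, 1.0)),
            autofluorescence=float(rng.exponential(cfg.autofluorescence_scale))
            if cfg.autofluorescence_scale > 0
            else 0.0,
        )
    return recs


def _growth_draw(
    median_signal: float, cv: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if cv <= 0:
        return np.full(n, median_signal)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    # median-parameterized so zero-noise and noisy runs share the median
    return median_signal * rng.lognormal(0.0, sigma, size=n)


def _compositions(
    key: CommunityKey, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, ...]:
    """Droplet input ids for one well of this community."""
    focal = key.focal_id
    mono = f"{focal}.mono"
    mixes = [f"{focal}+{sp}" for sp in sorted(key.affecting_set)]
    if key.is_monoculture:
        return (mono, mono)
    if key.order == 1:
        a = mixes[0]
        if cfg.dosage_variants:
            options = [(a, mono), (a, "blank"), (a, a, mono)]
            return options[int(rng.integers(len(options)))]
        return (a, mono)
    if key.order == 2:
        a, b = mixes
        if cfg.dosage_variants:
            options = [(a, b), (a, a, b), (a, b, b), (a, b, "blank")]
            return options[int(rng.integers(len(options)))]
        return (a, b)
    return tuple(mixes)  # trio: one droplet per affecting species


def simulate_wells(
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[WellRecord], dict[str, InputCulture]]:
    """Simulate well fluorescence timecourses for every community.

    Per well: reading(0) = a baseline offset; reading(t>=24) = baseline +
    the summed autofluorescence of the affecting species present + the
    focal's growth signal, saturating after the 24 h analysis timepoint.
    Coculture growth medians equal the monoculture median scaled by
    exp(true effect), with multiplicative lognormal measurement noise.
    """
    inputs: dict[str, InputCulture] = {"blank": InputCulture(input_id="blank")}
    for focal in truth.focal_ids:
        inputs[f"{focal}.mono"] = InputCulture(
            input_id=f"{focal}.mono", focal_id=focal, focal_od=0.01
        )
        for sp in truth.species:
            iid = f"{focal}+{sp}"
            inputs[iid] = InputCulture(
                input_id=iid, affecting_id=sp, focal_id=focal, affecting_od=0.02, focal_od=0.01
            )

    communities: list[tuple[CommunityKey, float]] = [
        (CommunityKey(f, frozenset()), 0.0) for f in truth.focal_ids
    ]
    communities += sorted(truth.single_effects.items())
    communities += sorted(truth.joint_effects.items())

    n_random = sum(1 for k, _ in communities if not k.is_monoculture)
    counts_iter = iter(draw_replicate_counts(n_random, cfg, rng))

    wells: list[WellRecord] = []
    post_t = [t for t in cfg.timepoints_h if t > 0]
    wid = 0
    for key, effect in communities:
        n_rep = cfg.mono_replicates if key.is_monoculture else int(next(counts_iter))
        med = cfg.mono_signal_mean * float(np.exp(effect))
        growth = _growth_draw(med, cfg.measurement_cv, n_rep, rng)
        autofluor = sum(truth.species[s].autofluorescence for s in key.affecting_set)
        baselines = rng.uniform(0.05, 0.15, size=n_rep) * cfg.mono_signal_mean
        for g, b in zip(growth, baselines):
            readings = {0.0: float(b)}
            for i, t in enumerate(post_t):
                sat = 1.0 if i == 0 else 1.05  # saturated past the analysis timepoint
                readings[float(t)] = float(b + autofluor + g * sat)
            wells.append(
                WellRecord(
                    well_id=f"w{wid:06d}",
                    community=key,
                    readings=readings,
                )
            )
            wid += 1
    # record droplet compositions alongside (same order as wells)
    return wells, inputs


def well_compositions(
    wells: list[WellRecord], cfg: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Droplet input ids for each well (dosage variants if configured)."""
    return [_compositions(w.community, cfg, rng) for w in wells]


def generate_scenario(
    cfg: SyntheticConfig,
    outdir: str | Path | None = None,
) -> dict[str, object]:
    """Generate a full scenario: truth, wells, species and input tables.

    Returns a bundle with keys ``truth``, ``wells`` (list of WellRecord),
    ``inputs``, ``compositions``, ``wells_df``, ``species_df``,
    ``inputs_df``; when ``outdir`` is given, also writes wells.csv,
    species.csv, inputs.csv and truth.json there.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    focal_ids = tuple(f"F{i:02d}" for i in range(cfg.n_focal))
    affecting_ids = tuple(f"A{i:03d}" for i in range(cfg.n_affecting))
    species = _species_records(cfg, rng, affecting_ids)
    singles = draw_single_effects(cfg, rng, focal_ids, affecting_ids)
    orders = tuple(o for o, on in ((2, cfg.include_pairs), (3, cfg.include_trios)) if on)
    joints, noise = make_joint_effects(
        singles, cfg.truth_rule, cfg.joint_noise_sd, rng, species, orders
    )
    truth = SyntheticTruth(
        single_effects=singles,
        joint_effects=joints,
        noise_draws=noise,
        species=species,
        focal_ids=focal_ids,
        config=cfg,
    )
    wells, inputs = simulate_wells(truth, cfg, rng)
    comps = well_compositions(wells, cfg, rng)

    rows = []
    for w, comp in zip(wells, comps):
        for t, v in sorted(w.readings.items()):
            rows.append(
                {
                    "well_id": w.well_id,
                    "chip_id": "chip1",
                    "focal_id": w.community.focal_id,
                    "droplet_inputs": ";".join(comp),
                    "timepoint_h": t,
                    "channel": "GFP",
                    "reading": round(v, 4),
                }
            )
    wells_df = pd.DataFrame(rows)
    species_df = pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "max_od": round(r.max_od, 6),
                "autofluorescence": round(r.autofluorescence, 4),
            }
            for r in species.values()
        ]
    )
    inputs_df = pd.DataFrame(
        [
            {
                "input_id": ic.input_id,
                "affecting_id": ic.affecting_id or "",
                "focal_id": ic.focal_id or "",
                "affecting_od": ic.affecting_od,
                "focal_od": ic.focal_od,
            }
            for ic in inputs.values()
        ]
    )

    bundle = {
        "truth": truth,
        "wells": wells,
        "inputs": inputs,
        "compositions": comps,
        "wells_df": wells_df,
        "species_df": species_df,
        "inputs_df": inputs_df,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wells_df.to_csv(outdir / "wells.csv", index=False)
        species_df.to_csv(outdir / "species.csv", index=False)
        inputs_df.to_csv(outdir / "inputs.csv", index=False)
        truth_json = {
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
            "seed": cfg.seed,
            "single_effects": {k.label(): v for k, v in sorted(singles.items())},
            "joint_effects": {k.label(): v for k, v in sorted(joints.items())},
            "noise_draws": {k.label(): v for k, v in sorted(noise.items())},
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_json, fh, indent=1)
    return bundle
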