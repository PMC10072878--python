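"""Readers and writers for the pipeline's tables.

Inputs are CSV (wells, species, droplet inputs) and newick (tree);
outputs are TSV with floats at 6 significant digits and deterministic,
key-sorted row order.  All tables are UTF-8 with a mandatory header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .composition import CommunityKey, InputCulture, community_key, resolve_well
from .effects import EffectEstimate, WellRecord
from .evaluation import EvaluationSummary
from .models import ModelPrediction, SpeciesRecord

WELL_COLUMNS = (
    "well_id",
    "chip_id",
    "focal_id",
    "droplet_inputs",
    "timepoint_h",
    "channel",
    "reading",
)


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def read_wells(path: str | Path) -> pd.DataFrame:
    """Read and validate the long-format well table.

    Non-numeric timepoints or readings are rejected with their line
    numbers (header = line 1).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, WELL_COLUMNS, path)
    for col in ("timepoint_h", "reading"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = numeric
    return df


def read_inputs(path: str | Path) -> dict[str, InputCulture]:
    df = pd.read_csv(path, dtype={"input_id": str, "affecting_id": str, "focal_id": str})
    _require_columns(df, ("input_id", "affecting_id", "focal_id", "affecting_od", "focal_od"), path)
    dup = df["input_id"][df["input_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate input id(s): {sorted(set(dup))}")
    out: dict[str, InputCulture] = {}
    for row in df.itertuples(index=False):
        aff = row.affecting_id if isinstance(row.affecting_id, str) and row.affecting_id else None
        foc = row.focal_id if isinstance(row.focal_id, str) and row.focal_id else None
        out[row.input_id] = InputCulture(
            input_id=row.input_id,
            affecting_id=aff,
            focal_id=foc,
            affecting_od=float(row.affecting_od),
            focal_od=float(row.focal_od),
        )
    return out


def wells_to_records(
    wells_df: pd.DataFrame,
    inputs: Mapping[str, InputCulture],
) -> list[WellRecord]:
    """Assemble WellRecords, resolving droplet compositions to communities.

    Dosage pooling happens here implicitly: wells whose droplet multisets
    differ but share a species set get the same community key.
    """
    records: list[WellRecord] = []
    grouped = wells_df.groupby(["well_id", "focal_id", "droplet_inputs"], sort=True)
    for (well_id, focal_id, droplet_inputs), grp in grouped:
        ids = [s for s in str(droplet_inputs).split(";") if s]
        comp = resolve_well(ids, inputs)
        key = community_key(comp, focal_id)
        readings = {float(t): float(v) for t, v in zip(grp["timepoint_h"], grp["reading"])}
        records.append(WellRecord(well_id=str(well_id), community=key, readings=readings))
    return records


def read_species(path: str | Path) -> dict[str, SpeciesRecord]:
    df = pd.read_csv(path, dtype={"species_id": str})
    _require_columns(df, ("species_id",), path)
    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate species id(s): {sorted(set(dup))}")
    out: dict[str, SpeciesRecord] = {}
    for row in df.to_dict("records"):
        out[row["species_id"]] = SpeciesRecord(
            species_id=row["species_id"],
            max_od=float(row.get("max_od", np.nan)),
            autofluorescence=float(row.get("autofluorescence", 0.0)),
            growth_rate=float(row.get("growth_rate", np.nan)),
        )
    return out


def read_tree(path: str | Path, species: Iterable[str] | None = None) -> dendropy.Tree:
    """Read a newick tree; warns (via returned tree only) about extra taxa.

    Taxa absent from ``species`` are tolerated and simply ignored by
    downstream distance queries.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if any(e.length is None for e in tree.edges() if e.head_node.parent_node is not None):
        raise ValueError(f"{path}: tree must have branch lengths on all edges")
    return tree


def _affecting_label(key: CommunityKey) -> str:
    return ";".join(sorted(key.affecting_set))


def write_effects(estimates: Sequence[EffectEstimate], path: str | Path) -> None:
    rows = [
        {
            "focal_id": e.community.focal_id,
            "affecting_set": _affecting_label(e.community),
            "effect": _fmt(e.effect),
            "se": _fmt(e.se),
            "n_wells": e.n_wells,
            "sign": e.sign,
            "censored": e.censored,
        }
        for e in sorted(estimates, key=lambda e: e.community)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_effects(path: str | Path) -> list[EffectEstimate]:
    df = pd.read_csv(path, sep="\t", dtype={"focal_id": str, "affecting_set": str})
    out = []
    for row in df.to_dict("records"):
        parts = [s for s in str(row["affecting_set"]).split(";") if s and s != "nan"]
        out.append(
            EffectEstimate(
                community=CommunityKey(row["focal_id"], frozenset(parts)),
                effect=float(row["effect"]),
                se=float(row["se"]),
                n_wells=int(row["n_wells"]),
                sign=row["sign"],
                censored=bool(row["censored"]),
            )
        )
    return out


def write_predictions(predictions: Sequence[ModelPrediction], path: str | Path) -> None:
    rows = [
        {
            "focal_id": p.community.focal_id,
            "affecting_set": _affecting_label(p.community),
            "model": p.model,
            "basis": p.basis,
            "predicted_effect": _fmt(p.value),
            "flags": ",".join(
                f for f, on in (("censored", p.censored), ("tie", p.tie)) if on
            ),
        }
        for p in sorted(predictions, key=lambda p: (p.community, p.model))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_evaluation(summaries: Sequence[EvaluationSummary], path: str | Path) -> None:
    rows = [
        {
            "stratum": s.stratum,
            "model": s.model,
            "basis": s.basis,
            "nrmse_median": _fmt(s.nrmse_median),
            "nrmse_iqr": _fmt(s.nrmse_iqr),
            "n_communities": s.n_communities,
            "n_bootstrap_used": s.n_bootstrap - s.n_missing,
        }
        for s in sorted(summaries, key=lambda s: (s.stratum, s.model))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_matrix(dm, path: str | Path) -> None:
    df = pd.DataFrame(dm.matrix, index=list(dm.species), columns=list(dm.species))
    df.round(6).to_csv(path, sep="\t", index_label="species_id")
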