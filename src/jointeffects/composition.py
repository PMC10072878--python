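"""Droplet and well composition arithmetic.

In a kChip screen, overnight cultures of an affecting species and a
fluorescent focal species are mixed into nanoliter droplets, and droplets
are grouped stochastically into wells of 1-3 droplets.  Because droplets
are uniform 1 nl volumes, the starting OD of each species in a well is
simply the mean of its per-droplet concentrations.  This module provides
that arithmetic plus the collapse of a physical well onto its community
identity (focal species + set of distinct affecting species), which is the
unit at which effects are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "InputCulture",
    "WellComposition",
    "CommunityKey",
    "droplet_mix",
    "well_start_odds",
    "community_key",
]


@dataclass(frozen=True)
class InputCulture:
    """One droplet-generator input: the per-droplet species concentrations.

    ``affecting_od`` and ``focal_od`` are the final per-droplet OD600 of
    each species (after 1:1 culture mixing), e.g. 0.02 affecting / 0.01
    focal in the standard setup.  A blank input has no species and zero OD;
    a focal-monoculture input has only the focal.
    """

    input_id: str
    affecting_id: Optional[str] = None
    focal_id: Optional[str] = None
    affecting_od: float = 0.0
    focal_od: float = 0.0

    def __post_init__(self) -> None:
        if self.affecting_od < 0 or self.focal_od < 0:
            raise ValueError(f"input {self.input_id!r}: ODs must be non-negative")
        if self.affecting_id is None and self.affecting_od > 0:
            raise ValueError(f"input {self.input_id!r}: OD without an affecting species")
        if self.focal_id is None and self.focal_od > 0:
            raise ValueError(f"input {self.input_id!r}: OD without a focal species")

    @property
    def is_blank(self) -> bool:
        return self.affecting_id is None and self.focal_id is None

    def droplet_ods(self) -> dict[str, float]:
        """Per-droplet OD map (species absent for blank inputs)."""
        ods: dict[str, float] = {}
        if self.affecting_id is not None:
            ods[self.affecting_id] = ods.get(self.affecting_id, 0.0) + self.affecting_od
        if self.focal_id is not None:
            ods[self.focal_id] = ods.get(self.focal_id, 0.0) + self.focal_od
        return ods


@dataclass(frozen=True)
class WellComposition:
    """A well's droplet multiset and derived starting ODs."""

    droplets: tuple[str, ...]  # input ids, order-insensitive
    start_od: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CommunityKey:
    """Community identity: focal species + unordered set of affecting species.

    An empty ``affecting_set`` denotes the focal monoculture.
    """

    focal_id: str
    affecting_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.focal_id in self.affecting_set:
            raise ValueError(f"focal {self.focal_id!r} cannot affect itself")
        object.__setattr__(self, "affecting_set", frozenset(self.affecting_set))

    @property
    def order(self) -> int:
        return len(self.affecting_set)

    @property
    def is_monoculture(self) -> bool:
        return not self.affecting_set

    def label(self) -> str:
        return f"{self.focal_id}|{';'.join(sorted(self.affecting_set))}"

    def __lt__(self, other: "CommunityKey") -> bool:  # stable table ordering
        return (self.focal_id, sorted(self.affecting_set)) < (
            other.focal_id,
            sorted(other.affecting_set),
        )


def droplet_mix(
    affecting_culture_od: float,
    focal_culture_od: float,
    ratio: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Per-droplet ODs after combining two cultures at a volume ratio.

    Each culture is diluted by its volume fraction: mixing 0.04 OD
    affecting with 0.02 OD focal at 1:1 yields droplets at 0.02 / 0.01.

    Parameters
    ----------
    affecting_culture_od, focal_culture_od
        OD600 of the normalized cultures before mixing.
    ratio
        Volume parts (affecting, focal); both must be >= 0 with a
        positive sum.
    """
    if affecting_culture_od < 0 or focal_culture_od < 0:
        raise ValueError("culture ODs must be non-negative")
    a_parts, f_parts = float(ratio[0]), float(ratio[1])
    if a_parts < 0 or f_parts < 0 or a_parts + f_parts <= 0:
        raise ValueError("ratio parts must be non-negative with a positive sum")
    total = a_parts + f_parts
    return (
        affecting_culture_od * a_parts / total,
        focal_culture_od * f_parts / total,
    )


def well_start_odds(droplets: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Starting OD of each species in a well of 1-3 equal-volume droplets.

    Each species' starting OD is the sum of its per-droplet ODs divided by
    the droplet count: a species confined to one of two droplets is diluted
    two-fold by the droplet it is absent from.  Species absent from every
    droplet do not appear in the output.
    """
    if not droplets:
        raise ValueError("a well must contain at least one droplet")
    k = len(droplets)
    if k > 3:
        raise ValueError(f"wells hold at most 3 droplets, got {k}")
    out: dict[str, float] = {}
    for drop in droplets:
        for sp, od in drop.items():
            if od < 0:
                raise ValueError(f"negative droplet OD for species {sp!r}")
            out[sp] = out.get(sp, 0.0) + od
    return {sp: tot / k for sp, tot in out.items() if tot > 0}


def community_key(
    well: WellComposition | Mapping[str, float],
    focal_id: str,
) -> CommunityKey:
    """Collapse a well onto its community identity.

    Wells whose droplet compositions differ only in dosage (AAB vs ABB vs
    AB+blank) map to the same key: initial fractions were found not to
    influence the measured effect, so communities are pooled by their
    distinct species sets.
    """
    start_od = well.start_od if isinstance(well, WellComposition) else well
    if start_od.get(focal_id, 0.0) <= 0:
        raise ValueError(f"focal {focal_id!r} absent from well")
    affecting = frozenset(sp for sp, od in start_od.items() if sp != focal_id and od > 0)
    return CommunityKey(focal_id=focal_id, affecting_set=affecting)


def resolve_well(
    droplet_input_ids: Iterable[str],
    inputs: Mapping[str, InputCulture],
) -> WellComposition:
    """Build a :class:`WellComposition` from droplet input ids.

    Raises ``KeyError`` naming any unknown input id.
    """
    ids = tuple(droplet_input_ids)
    missing = [i for i in ids if i not in inputs]
    if missing:
        raise KeyError(f"unknown droplet input ids: {missing}")
    ods = well_start_odds([inputs[i].droplet_ods() for i in ids])
    return WellComposition(droplets=ids, start_od=ods)
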