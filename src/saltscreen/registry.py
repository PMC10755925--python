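"""Closed registry of the measured phenotypic traits.

The screening design measures 22 traits per accession under control and
salt treatment: 7 at the germination stage (petri-dish assay) and 15 at
the seedling stage (sand-culture assay).  Trait names are canonical
snake_case identifiers; user tables with other spellings are mapped
through an alias dictionary at read time.  All traits are scored
higher-is-better, so the salt/control ratio (the salt-tolerance
coefficient) is directly a tolerance measure for every one of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

GERMINATION = "germination"
SEEDLING = "seedling"
STAGES = (GERMINATION, SEEDLING)

TREATMENT_CONTROL = "control"
TREATMENT_SALT = "salt"
TREATMENTS = (TREATMENT_CONTROL, TREATMENT_SALT)


@dataclass(frozen=True)
class Trait:
    """One entry of the trait registry."""

    name: str
    stage: str
    units: str
    direction: str = "higher_is_better"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r} for trait {self.name!r}")


_GERMINATION_TRAITS = [
    Trait("germination_vigor", GERMINATION, "%"),
    Trait("germination_rate", GERMINATION, "%"),
    Trait("radicle_length", GERMINATION, "cm"),
    Trait("embryo_length", GERMINATION, "cm"),
    Trait("root_bud_ratio", GERMINATION, "dimensionless"),
    Trait("germination_index", GERMINATION, "dimensionless"),
    Trait("vitality_index", GERMINATION, "cm"),
]

_SEEDLING_TRAITS = [
    Trait("plant_height", SEEDLING, "cm"),
    Trait("leaf_length", SEEDLING, "cm"),
    Trait("leaf_width", SEEDLING, "cm"),
    Trait("leaf_area", SEEDLING, "cm^2"),
    Trait("fresh_weight_above_ground", SEEDLING, "g"),
    Trait("fresh_weight_underground", SEEDLING, "g"),
    Trait("dry_weight_above_ground", SEEDLING, "g"),
    Trait("dry_weight_underground", SEEDLING, "g"),
    Trait("root_shoot_ratio", SEEDLING, "dimensionless"),
    Trait("root_length", SEEDLING, "cm"),
    Trait("root_project_area", SEEDLING, "cm^2"),
    Trait("root_surface_area", SEEDLING, "cm^2"),
    Trait("average_root_diameter", SEEDLING, "mm"),
    Trait("root_volume", SEEDLING, "cm^3"),
    Trait("root_tips", SEEDLING, "count"),
]

#: Common alternative spellings seen in hand-edited tables.
DEFAULT_ALIASES: dict[str, str] = {
    "germination_potential": "germination_vigor",
    "embryo_root_length": "radicle_length",
    "root_to_shoot_ratio": "root_shoot_ratio",
    "root_projected_area": "root_project_area",
    "average_diameter": "average_root_diameter",
    "aboveground_biomass": "dry_weight_above_ground",
}


class TraitRegistry:
    """Ordered, closed collection of :class:`Trait` entries.

    The default registry carries exactly the 22 measured traits.  A
    registry may be extended (e.g. the synthetic generator adds decoy
    traits) but names must stay unique.
    """

    def __init__(self, traits: Iterable[Trait], aliases: Mapping[str, str] | None = None):
        traits = list(traits)
        names = [t.name for t in traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in registry")
        self._traits: dict[str, Trait] = {t.name: t for t in traits}
        self.aliases: dict[str, str] = dict(DEFAULT_ALIASES if aliases is None else aliases)

    @property
    def names(self) -> list[str]:
        return list(self._traits)

    def stage_names(self, stage: str) -> list[str]:
        return [t.name for t in self._traits.values() if t.stage == stage]

    def __len__(self) -> int:
        return len(self._traits)

    def __contains__(self, name: str) -> bool:
        return name in self._traits

    def __getitem__(self, name: str) -> Trait:
        return self._traits[name]

    def __iter__(self):
        return iter(self._traits.values())

    def canonical(self, name: str) -> str:
        """Resolve ``name`` (possibly an alias) to a registry name.

        Raises ``KeyError`` if the name is unknown under both spellings.
        """
        if name in self._traits:
            return name
        if name in self.aliases and self.aliases[name] in self._traits:
            return self.aliases[name]
        raise KeyError(name)

    def extended(self, extra: Iterable[Trait]) -> "TraitRegistry":
        """A new registry with ``extra`` traits appended."""
        return TraitRegistry(list(self._traits.values()) + list(extra), self.aliases)


def default_registry() -> TraitRegistry:
    """The 22-trait registry of the screening design (7 germination + 15 seedling)."""
    return TraitRegistry(_GERMINATION_TRAITS + _SEEDLING_TRAITS)
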