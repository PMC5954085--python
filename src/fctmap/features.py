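"""Food-item data model, portion scaling, and the energy-difference feature."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = ["FoodItem", "EnergyDiffPct", "InvalidRecordError", "scale_to_100g", "energy_diff_pct"]

KJ_PER_KCAL = 4.184


class InvalidRecordError(ValueError):
    """A food item violates a structural invariant (e.g. portion_g <= 0)."""


@dataclass(frozen=True)
class FoodItem:
    """One food-composition-table or diary entry.

    Energy and nutrients are quantities per ``portion_g`` grams; missing
    energy is ``None``, never zero.  At least one of the two name variants
    must be present.
    """

    item_id: str
    source: str = "fct"  # "diary" or "fct"
    country: str = ""
    name_original: Optional[str] = None
    name_english: Optional[str] = None
    energy: Optional[float] = None  # kcal per portion
    portion_g: float = 100.0
    nutrients: Mapping[str, float] = field(default_factory=dict)
    food_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.name_original is None and self.name_english is None:
            raise InvalidRecordError(f"item {self.item_id!r}: no name in either variant")
        if self.portion_g <= 0:
            raise InvalidRecordError(f"item {self.item_id!r}: portion_g must be > 0")
        if self.energy is not None and self.energy < 0:
            raise InvalidRecordError(f"item {self.item_id!r}: negative energy")

    def name(self, variant: str) -> Optional[str]:
        """The name for a variant ("original" or "english")."""
        if variant == "original":
            return self.name_original
        if variant == "english":
            return self.name_english
        raise ValueError(f"unknown name variant {variant!r}")


@dataclass(frozen=True)
class EnergyDiffPct:
    """Percent energy difference; ``defined`` is False when unavailable."""

    value: float = math.nan
    defined: bool = True

    @classmethod
    def undefined(cls) -> "EnergyDiffPct":
        return cls(value=math.nan, defined=False)


def scale_to_100g(item: FoodItem) -> FoodItem:
    """Rescale energy and nutrients to a 100 g portion.

    Idempotent; raises :class:`InvalidRecordError` on non-positive portions
    (enforced at construction, re-checked here for defensive clarity).
    """
    if item.portion_g <= 0:  # pragma: no cover - blocked by __post_init__
        raise InvalidRecordError(f"item {item.item_id!r}: portion_g must be > 0")
    if item.portion_g == 100.0:
        return item
    factor = 100.0 / item.portion_g
    energy = None if item.energy is None else item.energy * factor
    nutrients = {k: v * factor for k, v in item.nutrients.items()}
    return replace(item, energy=energy, portion_g=100.0, nutrients=nutrients)


def energy_diff_pct(query: FoodItem, candidate: FoodItem) -> EnergyDiffPct:
    """Percent energy difference, denominated by the query's energy.

    ``100 * |(E_query - E_candidate) / E_query|`` on 100 g portions.
    Undefined (not zero, not an error) when either energy is missing or
    the query energy is zero; the downstream classifier tolerates missing
    values.  Asymmetric by construction.
    """
    eq, ec = query.energy, candidate.energy
    if eq is None or ec is None or eq == 0:
        return EnergyDiffPct.undefined()
    return EnergyDiffPct(value=100.0 * abs((eq - ec) / eq), defined=True)
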