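"""Instrument definition: items, scales, batteries, item pairs, conditions.

The codebook is the single source of truth for what the survey looks like:
which ordinal items exist and in what order, which belong to each multi-item
scale, which consecutive blocks share response categories (the substrate of
the straight-lining rules), which item pairs probe the same content, and which
entries of the condition checklist are fake. All quality-control modules take
a :class:`Codebook` rather than re-deriving structure from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ItemPair",
    "Battery",
    "ScaleDefinition",
    "Codebook",
    "load_codebook",
    "default_codebook",
]


@dataclass(frozen=True)
class ItemPair:
    """Two similar-topic items with identical response categories."""

    item_a: str
    item_b: str
    label: str


@dataclass(frozen=True)
class Battery:
    """An ordered set of items evaluated jointly for straight-lining.

    ``allowed_category`` is a response value exempt from flagging (a constant
    run of that value is plausible rather than careless). ``reverse_items``
    are asked in the opposite direction from the rest of the set.
    """

    name: str
    items: tuple[str, ...]
    allowed_category: int | None = None
    reverse_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise ValueError(f"battery {self.name!r} needs >=2 items")


@dataclass(frozen=True)
class ScaleDefinition:
    """A multi-item scale scored as the mean of its (recoded) items."""

    name: str
    items: tuple[str, ...]
    reverse_items: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return len(self.items)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"scale {self.name!r} needs >=2 items")
        unknown = set(self.reverse_items) - set(self.items)
        if unknown:
            raise ValueError(f"reverse items {sorted(unknown)} not in scale {self.name!r}")


@dataclass(frozen=True)
class Codebook:
    response_min: int
    response_max: int
    items: tuple[str, ...]
    reverse_items: tuple[str, ...]
    scales: dict[str, ScaleDefinition]
    extra_item_traits: dict[str, str]
    consecutive_sets: dict[str, Battery]
    special_batteries: dict[str, Battery]
    item_pairs: tuple[ItemPair, ...]
    conditions: dict[str, float]
    fake_conditions: tuple[str, ...]
    demographic_variables: dict[str, tuple[str, ...]]
    extra_assigned_items: int = 0

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item ids in codebook")
        known = set(self.items)
        seen_scale_items: set[str] = set()
        for sc in self.scales.values():
            missing = set(sc.items) - known
            if missing:
                raise ValueError(f"scale {sc.name!r} references unknown items {sorted(missing)}")
            overlap = seen_scale_items & set(sc.items)
            if overlap:
                raise ValueError(f"items {sorted(overlap)} appear in more than one scale")
            seen_scale_items |= set(sc.items)
        for bat in list(self.consecutive_sets.values()) + list(self.special_batteries.values()):
            missing = set(bat.items) - known
            if missing:
                raise ValueError(f"battery {bat.name!r} references unknown items {sorted(missing)}")
            if bat.allowed_category is not None and not (
                self.response_min <= bat.allowed_category <= self.response_max
            ):
                raise ValueError(f"battery {bat.name!r} allowed_category out of range")
        for pair in self.item_pairs:
            if pair.item_a not in known or pair.item_b not in known:
                raise ValueError(f"item pair {pair.label!r} references unknown items")
        overlap = set(self.fake_conditions) & set(self.conditions)
        if overlap:
            raise ValueError(f"fake conditions {sorted(overlap)} also listed as real")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def items_assigned(self) -> int:
        """Total items a respondent is assigned, including non-ordinal ones."""
        return self.n_items + self.extra_assigned_items

    @property
    def all_conditions(self) -> tuple[str, ...]:
        return tuple(self.conditions) + tuple(self.fake_conditions)

    def trait_of(self, item: str) -> str:
        """Latent domain an item draws on (its scale, or an explicit mapping)."""
        for sc in self.scales.values():
            if item in sc.items:
                return sc.name
        if item in self.extra_item_traits:
            return self.extra_item_traits[item]
        raise KeyError(f"item {item!r} has no trait assignment")


def _battery(name: str, spec: Mapping | Sequence) -> Battery:
    if isinstance(spec, Mapping):
        return Battery(
            name=name,
            items=tuple(spec["items"]),
            allowed_category=spec.get("allowed_category"),
            reverse_items=tuple(spec.get("reverse_items", ())),
        )
    return Battery(name=name, items=tuple(spec))


def load_codebook(source: str | Path | Mapping) -> Codebook:
    """Build a :class:`Codebook` from a YAML file path or a parsed mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    lo, hi = raw["response_range"]
    scales = {
        name: ScaleDefinition(
            name=name,
            items=tuple(spec["items"]),
            reverse_items=tuple(spec.get("reverse_items", ())),
        )
        for name, spec in raw["scales"].items()
    }
    return Codebook(
        response_min=int(lo),
        response_max=int(hi),
        items=tuple(raw["items"]),
        reverse_items=tuple(raw.get("reverse_items", ())),
        scales=scales,
        extra_item_traits=dict(raw.get("extra_item_traits", {})),
        consecutive_sets={n: _battery(n, s) for n, s in raw["consecutive_sets"].items()},
        special_batteries={n: _battery(n, s) for n, s in raw.get("special_batteries", {}).items()},
        item_pairs=tuple(ItemPair(**p) for p in raw.get("item_pairs", ())),
        conditions={k: float(v) for k, v in raw.get("conditions", {}).items()},
        fake_conditions=tuple(raw.get("fake_conditions", ())),
        demographic_variables={
            k: tuple(v) for k, v in raw.get("demographic_variables", {}).items()
        },
        extra_assigned_items=int(raw.get("extra_assigned_items", 0)),
    )


def packaged_path(name: str) -> Path:
    """Path to a YAML file shipped with the package."""
    return Path(str(resources.files("panelqc").joinpath("data", name)))


def default_codebook() -> Codebook:
    """The packaged synthetic general-health instrument."""
    return load_codebook(packaged_path("codebook.yaml"))
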