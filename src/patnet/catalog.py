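"""Item register for the Psychosocial Assessment Tool (PAT 2.0).

The PAT is a parent-reported screener of family psychosocial risk built from 15
item sets. Items are scored dichotomously (risk = 1, no risk = 0) and grouped
into seven subscales:

====================  ===============  ========
subscale              scored items     in network
====================  ===============  ========
structure_resources   8                5
social_support        4                4
child_problems        15               14
family_problems       8                8
caregiver_stress      3                3
family_beliefs        4                4
sibling_problems      15 (optional)    0
====================  ===============  ========

The 38 items with ``in_network=True`` are the nodes of the item-level
psychosocial network (the optional sibling scale and four further items are
excluded). Ids and labels of those 38 items follow the published instrument;
ids and labels of the remaining scored items are package-assigned placeholders
because the instrument itself is proprietary.

The generic variant (PAT 2.0_GEN, used outside oncology) removes items 9, 15g
and 15i; only item 9 appears among the scored items registered here, so the
variants differ by one structure_resources item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

#: canonical subscale order (appearance on the instrument)
SUBSCALES: tuple[str, ...] = (
    "structure_resources",
    "social_support",
    "child_problems",
    "family_problems",
    "caregiver_stress",
    "family_beliefs",
    "sibling_problems",
)

#: number of scored items per subscale on the full PAT 2.0
SUBSCALE_SIZES: dict[str, int] = {
    "structure_resources": 8,
    "social_support": 4,
    "child_problems": 15,
    "family_problems": 8,
    "caregiver_stress": 3,
    "family_beliefs": 4,
    "sibling_problems": 15,
}

#: items absent from the generic (non-oncology) variant
GEN_REMOVED_IDS: frozenset[str] = frozenset({"9", "15g", "15i"})

N_NETWORK_ITEMS = 38


@dataclass(frozen=True)
class Item:
    """One scored PAT item."""

    item_id: str
    label: str
    subscale: str
    in_network: bool

    def __post_init__(self) -> None:
        if self.subscale not in SUBSCALES:
            raise ValueError(f"unknown subscale {self.subscale!r}")


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered register of scored PAT items for one instrument variant.

    Instances are normally obtained from :func:`load_catalog`; the definition
    ships with the package as a JSON resource.
    """

    items: tuple[Item, ...]
    variant: str = "PAT2.0"
    _by_id: dict[str, Item] = field(init=False, repr=False, compare=False, default_factory=dict)
    _by_label: dict[str, Item] = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        for it in self.items:
            if it.item_id in self._by_id:
                raise ValueError(f"duplicate item id {it.item_id!r}")
            self._by_id[it.item_id] = it
            self._by_label[it.label] = it

    def __iter__(self) -> Iterator[Item]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def get(self, key: str) -> Item:
        """Look an item up by id or, failing that, by label."""
        if key in self._by_id:
            return self._by_id[key]
        if key in self._by_label:
            return self._by_label[key]
        raise KeyError(f"no PAT item with id or label {key!r}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def network_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.in_network)

    def subscale_items(self, subscale: str) -> tuple[Item, ...]:
        if subscale not in SUBSCALES:
            raise KeyError(f"unknown subscale {subscale!r}")
        return tuple(it for it in self.items if it.subscale == subscale)

    def subscales_present(self) -> tuple[str, ...]:
        present = {it.subscale for it in self.items}
        return tuple(s for s in SUBSCALES if s in present)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "items": [
                    {
                        "id": it.item_id,
                        "label": it.label,
                        "subscale": it.subscale,
                        "in_network": it.in_network,
                    }
                    for it in self.items
                ],
            },
            indent=2,
        )

    @classmethod
    def from_dict(cls, payload: dict) -> "ItemCatalog":
        items = tuple(
            Item(d["id"], d["label"], d["subscale"], bool(d["in_network"]))
            for d in payload["items"]
        )
        return cls(items=items, variant=payload.get("variant", "PAT2.0"))


def load_catalog(variant: str = "PAT2.0") -> ItemCatalog:
    """Load the shipped item register.

    Parameters
    ----------
    variant
        ``"PAT2.0"`` (oncology, 57 scored items) or ``"PAT2.0_GEN"`` (generic
        version; items 9/15g/15i removed).
    """
    if variant not in ("PAT2.0", "PAT2.0_GEN"):
        raise ValueError(f"unknown PAT variant {variant!r}")
    payload = json.loads(
        resources.files("patnet").joinpath("data/pat2_items.json").read_text()
    )
    catalog = ItemCatalog.from_dict(payload)
    if variant == "PAT2.0_GEN":
        kept = tuple(it for it in catalog.items if it.item_id not in GEN_REMOVED_IDS)
        catalog = ItemCatalog(items=kept, variant="PAT2.0_GEN")
    return catalog
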