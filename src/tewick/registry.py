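"""Wicker superfamily registry and the superfamily -> order roll-up.

The sixteen superfamilies follow the Wicker classification system: eight
class I (retrotransposon) groups -- the LTR superfamilies Copia, Gypsy,
Pao and ERV, the LINE superfamilies L1/L2, RTE and Jockey, and SINEs --
and eight class II ("cut-and-paste" / rolling-circle / self-synthesizing)
groups: Tc1/Mariner, hAT, Merlin, Transib, P, Crypton, Helitron and
Maverick.  Custom registries (other label sets, other roll-ups) are
supported for user-trained models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: Default sixteen superfamilies, in canonical (alphabetical) order.
#: This order fixes class indices, argmax tie-breaking and TSV columns.
WICKER_SUPERFAMILIES: tuple[str, ...] = (
    "Copia", "Crypton", "ERV", "Gypsy", "hAT", "Helitron", "Jockey",
    "L1/L2", "Maverick", "Merlin", "P", "Pao", "RTE", "SINE", "TcMar",
    "Transib",
)

#: Superfamily -> order roll-up (Wicker orders; TIR groups the classic
#: cut-and-paste DNA transposons).
SUPERFAMILY_TO_ORDER: dict[str, str] = {
    "Copia": "LTR",
    "Gypsy": "LTR",
    "Pao": "LTR",
    "ERV": "LTR",
    "L1/L2": "LINE",
    "RTE": "LINE",
    "Jockey": "LINE",
    "SINE": "SINE",
    "TcMar": "TIR",
    "hAT": "TIR",
    "Merlin": "TIR",
    "Transib": "TIR",
    "P": "TIR",
    "Crypton": "Crypton",
    "Helitron": "Helitron",
    "Maverick": "Maverick",
}


class RegistryError(ValueError):
    """Raised for invalid class registries or unknown class labels."""


@dataclass(frozen=True)
class ClassRegistry:
    """Ordered set of class names plus the superfamily -> order mapping.

    Parameters
    ----------
    class_names
        Ordered, unique class names.  The position of a name is its
        class index everywhere in the package (model head, confusion
        matrix, TSV columns, argmax tie-break).
    orders
        Mapping from each class name to its order.  Classes missing
        from the mapping roll up to ``"Unknown"``.
    """

    class_names: tuple[str, ...] = WICKER_SUPERFAMILIES
    orders: Mapping[str, str] = field(default_factory=lambda: dict(SUPERFAMILY_TO_ORDER))

    def __post_init__(self) -> None:
        if len(self.class_names) == 0:
            raise RegistryError("registry needs at least one class")
        if len(set(self.class_names)) != len(self.class_names):
            raise RegistryError("class names must be unique")

    def __len__(self) -> int:
        return len(self.class_names)

    def __contains__(self, name: str) -> bool:
        return name in self.class_names

    def index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise RegistryError(f"unknown class label: {name!r}") from None

    def order_of(self, name: str) -> str:
        """Roll a superfamily up to its order."""
        if name not in self.class_names:
            raise RegistryError(f"unknown class label: {name!r}")
        return self.orders.get(name, "Unknown")

    @classmethod
    def from_names(cls, names: Sequence[str],
                   orders: Mapping[str, str] | None = None) -> "ClassRegistry":
        return cls(tuple(names), dict(orders) if orders else {})


#: The default registry used when none is supplied.
DEFAULT_REGISTRY = ClassRegistry()
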