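"""Element registry for the wheat grain ionome.

The 15 elements quantified in the trial fall into four classes with a
breeding-relevant "favorable direction": macro- and micronutrients are
improved by raising grain concentration, whereas toxic trace metals and
the remaining trace elements are improved by lowering it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = ["ElementDef", "ElementRegistry", "default_registry"]

VALID_CLASSES = ("macro", "micro", "toxic_trace", "trace")


@dataclass(frozen=True)
class ElementDef:
    """One element: chemical symbol, class, favorable direction and unit."""

    code: str
    element_class: str
    favorable_direction: str
    unit: str = "µg/g dry weight"

    def __post_init__(self) -> None:
        if self.element_class not in VALID_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.favorable_direction not in ("high", "low"):
            raise ValueError(
                f"favorable_direction must be 'high' or 'low', got "
                f"{self.favorable_direction!r}"
            )


_DEFAULT_CLASSES: Mapping[str, tuple[str, ...]] = {
    "macro": ("Ca", "K", "Mg", "P", "S"),
    "micro": ("Fe", "Cu", "Mn", "Zn"),
    "toxic_trace": ("Cd", "Co", "Ni"),
    "trace": ("Mo", "Rb", "Sr"),
}

# high is favorable for nutrients, low for toxic and other trace elements
_DIRECTION_BY_CLASS = {
    "macro": "high",
    "micro": "high",
    "toxic_trace": "low",
    "trace": "low",
}


@dataclass(frozen=True)
class ElementRegistry:
    """Ordered collection of :class:`ElementDef`, keyed by symbol."""

    elements: tuple[ElementDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        codes = [e.code for e in self.elements]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate element codes in registry")

    def __iter__(self) -> Iterator[ElementDef]:
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, code: str) -> bool:
        return any(e.code == code for e in self.elements)

    def __getitem__(self, code: str) -> ElementDef:
        for e in self.elements:
            if e.code == code:
                return e
        raise KeyError(code)

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.elements]

    def by_class(self, element_class: str) -> list[str]:
        return [e.code for e in self.elements if e.element_class == element_class]

    @classmethod
    def from_mapping(cls, spec: Mapping[str, Mapping[str, str]]) -> "ElementRegistry":
        """Build a registry from ``{code: {class: ..., direction: ...}}``,
        e.g. parsed from a YAML/TOML config block."""
        defs = []
        for code, entry in spec.items():
            defs.append(
                ElementDef(
                    code=code,
                    element_class=entry["class"],
                    favorable_direction=entry.get(
                        "direction", _DIRECTION_BY_CLASS[entry["class"]]
                    ),
                    unit=entry.get("unit", "µg/g dry weight"),
                )
            )
        return cls(tuple(defs))


def default_registry() -> ElementRegistry:
    """The default 15-element registry of the spring-wheat grain ionome."""
    defs = []
    for cls_name, codes in _DEFAULT_CLASSES.items():
        for code in codes:
            defs.append(
                ElementDef(
                    code=code,
                    element_class=cls_name,
                    favorable_direction=_DIRECTION_BY_CLASS[cls_name],
                )
            )
    return ElementRegistry(tuple(defs))
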