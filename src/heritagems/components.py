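"""Curated chemical building blocks for candidate-ion generation.

The default table covers the components repeatedly identified in aged paint
and varnish layers: the fatty acids of drying oils and egg-yolk lipids with
their dicarboxylic and short-chain oxidative degradation products, abietane
resin acids of colophony, dammarane triterpenoids and the cadinene unit of
dammar's polymeric fraction, beeswax alkanes/alcohols/esters precursors,
cholesterol, and the pyrolytic PAH markers of pine tar (retene, simonellite).

The table is shipped as human-editable TSV (``data/components.tsv``) so that
further homologs -- e.g. additional wax chain lengths -- can be added without
touching code.  Libraries have value semantics: :meth:`ComponentLibrary.register`
returns a new library and leaves the original untouched.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterator

from .formula import Formula, parse_formula

__all__ = [
    "ComponentClass",
    "Component",
    "ComponentLibrary",
    "LibraryError",
    "default_library",
    "register_component",
    "FAMILIES",
    "ACID_CLASSES",
]

#: Material families recognized by the default tables.
FAMILIES = (
    "colophony",
    "linseed_oil",
    "egg_yolk",
    "dammar",
    "beeswax",
    "pine_tar",
)


class ComponentClass(str, Enum):
    FATTY_ACID = "fatty_acid"
    DICARBOXYLIC_ACID = "dicarboxylic_acid"
    DEGRADATION_ACID = "degradation_acid"
    BACKBONE = "backbone"
    RESIN_ACID_ABIETANE = "resin_acid_abietane"
    TRITERPENOID_DAMMARANE = "triterpenoid_dammarane"
    TRITERPENOID_PENTACYCLIC = "triterpenoid_pentacyclic"
    SESQUITERPENE = "sesquiterpene"
    WAX_ALKANE = "wax_alkane"
    WAX_ALCOHOL = "wax_alcohol"
    WAX_DIOL = "wax_diol"
    STEROL = "sterol"
    PAH_MARKER = "pah_marker"


#: Classes that can acylate a glycerol backbone or esterify a wax alcohol.
ACID_CLASSES = frozenset(
    {
        ComponentClass.FATTY_ACID,
        ComponentClass.DICARBOXYLIC_ACID,
        ComponentClass.DEGRADATION_ACID,
    }
)


class LibraryError(ValueError):
    """Raised for invalid library contents or lookups."""


@dataclass(frozen=True)
class Component:
    """A named neutral molecule with its elemental formula.

    ``families`` lists the material families whose chemistry this component
    participates in (a palmitic acid, for instance, occurs in drying oil,
    egg-yolk lipids and beeswax esters alike).
    """

    name: str
    abbreviation: str
    cls: ComponentClass
    formula: Formula
    families: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name or not self.abbreviation:
            raise LibraryError("component name and abbreviation must be non-empty")
        if self.formula.mass <= 0:
            raise LibraryError(f"component {self.name!r} has non-positive mass")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise LibraryError(f"unknown families for {self.name!r}: {sorted(unknown)}")


class ComponentLibrary:
    """An immutable collection of :class:`Component` entries.

    Lookup succeeds by name or by abbreviation for every entry; abbreviations
    are unique within a component class (and, in the default table, globally).
    """

    def __init__(self, components: Iterator[Component] | list[Component]) -> None:
        entries = tuple(components)
        seen: set[tuple[ComponentClass, str]] = set()
        for comp in entries:
            key = (comp.cls, comp.abbreviation)
            if key in seen:
                raise LibraryError(
                    f"duplicate abbreviation {comp.abbreviation!r} in class "
                    f"{comp.cls.value}"
                )
            seen.add(key)
        self._components = entries
        self._by_name = {c.name: c for c in entries}
        self._by_abbrev: dict[str, Component] = {}
        for comp in entries:
            self._by_abbrev.setdefault(comp.abbreviation, comp)

    @property
    def components(self) -> tuple[Component, ...]:
        return self._components

    def __len__(self) -> int:
        return len(self._components)

    def __iter__(self) -> Iterator[Component]:
        return iter(self._components)

    def lookup(self, key: str) -> Component:
        """Find a component by exact name or abbreviation."""
        comp = self._by_name.get(key) or self._by_abbrev.get(key)
        if comp is None:
            raise LibraryError(f"no component named or abbreviated {key!r}")
        return comp

    def by_class(self, cls: ComponentClass) -> tuple[Component, ...]:
        return tuple(c for c in self._components if c.cls is cls)

    def for_family(self, family: str) -> tuple[Component, ...]:
        if family not in FAMILIES:
            raise LibraryError(f"unknown material family {family!r}")
        return tuple(c for c in self._components if family in c.families)

    def register(self, component: Component) -> "ComponentLibrary":
        """Return a new library extended with ``component`` (value semantics)."""
        for existing in self._components:
            if (
                existing.cls is component.cls
                and existing.abbreviation == component.abbreviation
            ):
                raise LibraryError(
                    f"abbreviation {component.abbreviation!r} already used in "
                    f"class {component.cls.value}"
                )
        return ComponentLibrary([*self._components, component])

    def to_tsv(self) -> str:
        """Serialize in the shipped table schema."""
        buf = _io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "abbreviation", "class", "formula", "families"])
        for comp in self._components:
            writer.writerow(
                [
                    comp.name,
                    comp.abbreviation,
                    comp.cls.value,
                    comp.formula.hill(),
                    ";".join(sorted(comp.families)),
                ]
            )
        return buf.getvalue()


def _parse_table(text: str) -> ComponentLibrary:
    rows = [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    reader = csv.DictReader(rows, delimiter="\t")
    entries = []
    for record in reader:
        entries.append(
            Component(
                name=record["name"],
                abbreviation=record["abbreviation"],
                cls=ComponentClass(record["class"]),
                formula=parse_formula(record["formula"]),
                families=frozenset(
                    f for f in record["families"].split(";") if f
                ),
            )
        )
    return ComponentLibrary(entries)


def default_library() -> ComponentLibrary:
    """The package's built-in component table (``data/components.tsv``)."""
    text = resources.files("heritagems.data").joinpath("components.tsv").read_text()
    return _parse_table(text)


def register_component(
    library: ComponentLibrary, component: Component
) -> ComponentLibrary:
    """Functional alias for :meth:`ComponentLibrary.register`."""
    return library.register(component)
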