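"""Combinatorial assembly of candidate ions from component building blocks.

The chemistry encoded here is the aging and ionization behaviour of the
materials, made executable:

* acylglycerols -- glycerol esterified with 1-3 acids (each ester bond loses
  one water), with dicarboxylic/short-chain degradation acids substituting
  for original fatty acids in aged drying oil;
* wax esters -- a long-chain alcohol (or diol) esterified with 1 (or 2)
  fatty acids;
* abietane "dimers"/combinations -- plain formula sums of two resin acids,
  the high-mass aging signature of colophony-based varnishes;
* dammarane + cadinene combinations -- a triterpenoid core extended by one
  or two C15H24 sesquiterpene units, optionally minus one water;
* free acids, wax alkanes/alcohols, sterols and PAH markers as-is.

Every neutral parent is then expanded into its observable singly protonated
variants: [M+H]+ plus in-source losses of nH2O, a combined (H2O+CO) loss,
oxidative +nO gains and a -2H dehydrogenation.  Variants that would require
removing atoms the parent does not have are skipped.  Candidates with the
same cation formula are merged, keeping every provenance -- a peak in an
aged-material spectrum frequently admits several isomeric assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

from .components import (
    ACID_CLASSES,
    Component,
    ComponentClass,
    ComponentLibrary,
    FAMILIES,
    LibraryError,
)
from .formula import CO, Formula, FormulaError, H2, OXYGEN, PROTON, WATER, cation_mz, parse_formula

__all__ = [
    "AssemblySpec",
    "Provenance",
    "CandidateIon",
    "GenerationError",
    "GLYCEROL",
    "assemble_acylglycerol",
    "assemble_ester",
    "dimerize_resin_acids",
    "combine_with_cadinene",
    "ion_variants",
    "generate_library",
]

log = logging.getLogger(__name__)

GLYCEROL = parse_formula("C3H8O3")
_CADINENE = parse_formula("C15H24")

_ACYL_KIND = {1: "MAG", 2: "DAG", 3: "TAG"}


class GenerationError(ValueError):
    """Raised for invalid assembly inputs or an empty component pool."""


@dataclass(frozen=True)
class AssemblySpec:
    """Bounds and switches of a candidate-generation run.

    Defaults cover every modification the interpreted spectra require
    (up to two water losses, one combined H2O+CO loss, up to three oxygen
    gains, one dehydrogenation) without runaway combinatorics.
    """

    families: tuple[str, ...] = FAMILIES
    acid_pool: tuple[str, ...] | None = None  # abbreviation/name filter
    max_acyl: int = 3
    n_h2o_loss: int = 2
    co_loss_with_water: bool = True
    n_o_gain: int = 3
    dehydrogenation_2h: int = 1
    dimerization: bool = True
    cadinene_max: int = 2
    include_free_acids: bool = True
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not self.families:
            raise GenerationError("at least one material family must be enabled")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise GenerationError(f"unknown families: {sorted(unknown)}")
        if not 1 <= self.max_acyl <= 3:
            raise GenerationError("max_acyl must be in 1..3")
        if not 0 <= self.n_h2o_loss <= 2:
            raise GenerationError("n_h2o_loss must be in 0..2")
        if not 0 <= self.n_o_gain <= 3:
            raise GenerationError("n_o_gain must be in 0..3")
        if self.dehydrogenation_2h not in (0, 1):
            raise GenerationError("dehydrogenation_2h must be 0 or 1")
        if not 0 <= self.cadinene_max <= 2:
            raise GenerationError("cadinene_max must be in 0..2")


@dataclass(frozen=True)
class Provenance:
    """How a candidate ion was built: parents, assembly route, modifications.

    ``kind`` is one of ``parent``, ``free``, ``acylglycerol``, ``ester``,
    ``resin_dimer``, ``cadinene_combination``.  ``modifications`` records the
    ion-variant trail (e.g. ``("-H2O", "+O")``); protonation is implicit.
    ``parent_classes`` parallels ``parents`` so downstream marker rules can
    reason about classes without a library in hand.
    """

    family: str
    kind: str
    parents: tuple[str, ...]
    parent_abbrevs: tuple[str, ...]
    parent_classes: tuple[str, ...]
    assembly: str
    modifications: tuple[str, ...] = ()

    @property
    def n_modifications(self) -> int:
        return len(self.modifications)

    def describe(self) -> str:
        mods = "".join(self.modifications)
        return f"{self.assembly} [M{mods}+H]+"


@dataclass(frozen=True)
class CandidateIon:
    """A singly charged even-electron cation with full provenance.

    ``formula`` is the complete atom inventory of the cation (ionizing proton
    included); ``mz`` is the electron-mass-corrected theoretical m/z.
    """

    formula: Formula
    mz: float
    provenances: tuple[Provenance, ...]
    charge: int = 1

    def __post_init__(self) -> None:
        if not self.provenances:
            raise GenerationError("candidate ion needs at least one provenance")

    @property
    def n_modifications(self) -> int:
        """Smallest modification count across provenances (used for ranking)."""
        return min(p.n_modifications for p in self.provenances)

    def ion_type(self) -> str:
        best = min(self.provenances, key=lambda p: p.n_modifications)
        return f"[M{''.join(best.modifications)}+H]+"


# ---------------------------------------------------------------------------
# Neutral assembly operations
# ---------------------------------------------------------------------------


def _require_classes(
    components: Iterable[Component], allowed: frozenset[ComponentClass], what: str
) -> None:
    for comp in components:
        if comp.cls not in allowed:
            raise GenerationError(
                f"{comp.name!r} ({comp.cls.value}) cannot take part in {what}"
            )


def assemble_acylglycerol(acids: Sequence[Component]) -> Formula:
    """Neutral mono-/di-/triacylglycerol: glycerol + acids - n(H2O).

    Acid order is irrelevant (composition, not sn-position, is assigned).
    """
    if not 1 <= len(acids) <= 3:
        raise GenerationError(
            f"an acylglycerol takes 1-3 acids, got {len(acids)}"
        )
    _require_classes(acids, ACID_CLASSES, "acylglycerol assembly")
    formula = GLYCEROL
    for acid in acids:
        formula = formula + acid.formula
    return formula - WATER * len(acids)


def assemble_ester(alcohol: Component, acids: Sequence[Component]) -> Formula:
    """Neutral wax ester: alcohol + 1 acid, or diol + 2 acids, minus waters."""
    if alcohol.cls is ComponentClass.WAX_ALCOHOL:
        if len(acids) != 1:
            raise GenerationError("a monoester takes exactly one acid")
    elif alcohol.cls is ComponentClass.WAX_DIOL:
        if len(acids) != 2:
            raise GenerationError("a diol diester takes exactly two acids")
    else:
        raise GenerationError(
            f"{alcohol.name!r} ({alcohol.cls.value}) is not an esterifiable alcohol"
        )
    _require_classes(acids, ACID_CLASSES, "ester assembly")
    formula = alcohol.formula
    for acid in acids:
        formula = formula + acid.formula
    return formula - WATER * len(acids)


def dimerize_resin_acids(a: Component, b: Component) -> Formula:
    """Combination of two abietane resin acids: plain formula sum, no loss."""
    _require_classes(
        (a, b), frozenset({ComponentClass.RESIN_ACID_ABIETANE}), "resin-acid dimerization"
    )
    return a.formula + b.formula


def combine_with_cadinene(core: Component, n: int, water_losses: int = 0) -> Formula:
    """Dammarane core extended by ``n`` cadinene units minus ``water_losses`` H2O."""
    if core.cls is not ComponentClass.TRITERPENOID_DAMMARANE:
        raise GenerationError(
            f"{core.name!r} ({core.cls.value}) is not a dammarane core"
        )
    if n not in (1, 2):
        raise GenerationError(f"cadinene unit count must be 1 or 2, got {n}")
    if not 0 <= water_losses <= n:
        raise GenerationError(
            f"water_losses must be in 0..{n}, got {water_losses}"
        )
    return core.formula + _CADINENE * n - WATER * water_losses


# ---------------------------------------------------------------------------
# Protonated ion variants
# ---------------------------------------------------------------------------


def ion_variants(
    neutral: Formula,
    spec: AssemblySpec,
    provenance: Provenance | None = None,
) -> list[CandidateIon]:
    """All observable protonated variants of a neutral parent.

    Cation atoms = neutral + H - n(H2O) [- (H2O+CO)] + k(O) - d(H2), over the
    bounds in ``spec``.  Infeasible subtractions are skipped (debug-logged).
    """
    if provenance is None:
        provenance = Provenance(
            family="",
            kind="parent",
            parents=(neutral.hill(),),
            parent_abbrevs=(neutral.hill(),),
            parent_classes=(),
            assembly=neutral.hill(),
        )
    variants: list[CandidateIon] = []
    for n_water in range(spec.n_h2o_loss + 1):
        for co_loss in (False, True) if spec.co_loss_with_water else (False,):
            for n_oxygen in range(spec.n_o_gain + 1):
                for dehydro in range(spec.dehydrogenation_2h + 1):
                    mods: list[str] = []
                    if n_water:
                        mods.append(f"-{n_water if n_water > 1 else ''}H2O")
                    if co_loss:
                        mods.append("-H2O-CO")
                    if n_oxygen:
                        mods.append(f"+{n_oxygen if n_oxygen > 1 else ''}O")
                    if dehydro:
                        mods.append("-2H")
                    try:
                        atoms = neutral + PROTON - WATER * n_water
                        if co_loss:
                            atoms = atoms - WATER - CO
                        atoms = atoms + OXYGEN * n_oxygen
                        if dehydro:
                            atoms = atoms - H2
                    except FormulaError:
                        log.debug(
                            "skipping infeasible variant %s of %s",
                            mods,
                            neutral.hill(),
                        )
                        continue
                    variants.append(
                        CandidateIon(
                            formula=atoms,
                            mz=cation_mz(atoms),
                            provenances=(
                                replace(provenance, modifications=tuple(mods)),
                            ),
                        )
                    )
    return variants


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------


def _prov(
    family: str,
    kind: str,
    parents: Sequence[Component],
    assembly: str,
) -> Provenance:
    ordered = sorted(parents, key=lambda c: (c.cls.value, c.name))
    return Provenance(
        family=family,
        kind=kind,
        parents=tuple(c.name for c in ordered),
        parent_abbrevs=tuple(c.abbreviation for c in ordered),
        parent_classes=tuple(c.cls.value for c in ordered),
        assembly=assembly,
    )


def _family_parents(
    library: ComponentLibrary, family: str, spec: AssemblySpec
) -> list[tuple[Formula, Provenance]]:
    members = library.for_family(family)
    acids = [c for c in members if c.cls in ACID_CLASSES]
    if spec.acid_pool is not None:
        allowed = set(spec.acid_pool)
        acids = [
            c for c in acids if c.abbreviation in allowed or c.name in allowed
        ]
    backbone = [c for c in members if c.cls is ComponentClass.BACKBONE]
    parents: list[tuple[Formula, Provenance]] = []

    # Acylglycerols over the acid pool, combinations with repetition.
    if backbone and acids:
        for size in range(1, spec.max_acyl + 1):
            for combo in combinations_with_replacement(acids, size):
                abbrevs = "".join(
                    c.abbreviation for c in sorted(combo, key=lambda c: c.name)
                )
                parents.append(
                    (
                        assemble_acylglycerol(combo),
                        _prov(
                            family,
                            "acylglycerol",
                            [backbone[0], *combo],
                            f"{_ACYL_KIND[size]}({abbrevs})",
                        ),
                    )
                )

    # Free acids: hydrolysis/degradation products, so only meaningful where a
    # glycerolipid backbone exists.  (Wax-bound fatty acids stay esterified;
    # resin acids are emitted as parents of their own class below.)
    if spec.include_free_acids and backbone:
        for acid in acids:
            parents.append(
                (acid.formula, _prov(family, "free", [acid], acid.name))
            )

    # Wax esters and free wax components.
    alcohols = [c for c in members if c.cls is ComponentClass.WAX_ALCOHOL]
    diols = [c for c in members if c.cls is ComponentClass.WAX_DIOL]
    fatty = [c for c in acids if c.cls is ComponentClass.FATTY_ACID]
    for alcohol in alcohols:
        for acid in fatty:
            parents.append(
                (
                    assemble_ester(alcohol, [acid]),
                    _prov(
                        family,
                        "ester",
                        [alcohol, acid],
                        f"monoester({alcohol.abbreviation},{acid.abbreviation})",
                    ),
                )
            )
    for diol in diols:
        for pair in combinations_with_replacement(fatty, 2):
            parents.append(
                (
                    assemble_ester(diol, pair),
                    _prov(
                        family,
                        "ester",
                        [diol, *pair],
                        "diester({},{})".format(
                            diol.abbreviation,
                            ",".join(c.abbreviation for c in pair),
                        ),
                    ),
                )
            )
    for comp in members:
        if comp.cls in (
            ComponentClass.WAX_ALKANE,
            ComponentClass.WAX_ALCOHOL,
            ComponentClass.WAX_DIOL,
        ):
            parents.append((comp.formula, _prov(family, "parent", [comp], comp.name)))

    # Abietane resin acids; aging combinations only for colophony varnishes.
    abietanes = [c for c in members if c.cls is ComponentClass.RESIN_ACID_ABIETANE]
    for acid in abietanes:
        parents.append((acid.formula, _prov(family, "parent", [acid], acid.name)))
    if spec.dimerization and family == "colophony":
        for a, b in combinations_with_replacement(abietanes, 2):
            parents.append(
                (
                    dimerize_resin_acids(a, b),
                    _prov(
                        family,
                        "resin_dimer",
                        [a, b],
                        f"dimer({a.abbreviation},{b.abbreviation})",
                    ),
                )
            )

    # Triterpenoids.  Only the tetracyclic dammarane cores take part in the
    # polycadinene fraction, so cadinene combinations are built on them
    # alone; pentacyclic (oleanane/ursane-type) members are plain parents.
    # The printed combination assignments imply exactly one water lost in
    # total whether one or two units attach, so both the 0- and 1-water
    # variants are emitted and ppm matching decides.
    dammaranes = [
        c for c in members if c.cls is ComponentClass.TRITERPENOID_DAMMARANE
    ]
    for comp in members:
        if comp.cls is ComponentClass.TRITERPENOID_PENTACYCLIC:
            parents.append((comp.formula, _prov(family, "parent", [comp], comp.name)))
    cadinenes = [c for c in members if c.cls is ComponentClass.SESQUITERPENE]
    for core in dammaranes:
        parents.append((core.formula, _prov(family, "parent", [core], core.name)))
        if cadinenes and spec.cadinene_max:
            for n in range(1, spec.cadinene_max + 1):
                for lost in range(0, min(n, 1) + 1):
                    suffix = f"-{'2' if lost == 2 else ''}H2O" if lost else ""
                    parents.append(
                        (
                            combine_with_cadinene(core, n, lost),
                            _prov(
                                family,
                                "cadinene_combination",
                                [core, *cadinenes * n],
                                f"{core.abbreviation}+{n}Cad{suffix}",
                            ),
                        )
                    )

    # Sterols and PAH markers as-is.
    for comp in members:
        if comp.cls in (ComponentClass.STEROL, ComponentClass.PAH_MARKER):
            parents.append((comp.formula, _prov(family, "parent", [comp], comp.name)))
    return parents


def generate_library(
    components: ComponentLibrary, spec: AssemblySpec | None = None
) -> list[CandidateIon]:
    """Enumerate, deduplicate and sort the full candidate-ion library.

    Candidates sharing a cation formula are merged with concatenated
    provenances; output is sorted by (m/z, Hill formula) for reproducible
    diffs.  Raises :class:`GenerationError` if the enabled families yield no
    parents at all.
    """
    spec = spec or AssemblySpec()
    parents: list[tuple[Formula, Provenance]] = []
    for family in spec.families:
        parents.extend(_family_parents(components, family, spec))
    if not parents:
        raise GenerationError(
            f"no parents could be assembled for families {spec.families}"
        )
    merged: dict[Formula, list[Provenance]] = {}
    for neutral, provenance in parents:
        for candidate in ion_variants(neutral, spec, provenance):
            merged.setdefault(candidate.formula, [])
            for p in candidate.provenances:
                if not spec.dedupe or p not in merged[candidate.formula]:
                    merged[candidate.formula].append(p)
    library = [
        CandidateIon(formula=f, mz=cation_mz(f), provenances=tuple(provs))
        for f, provs in merged.items()
    ]
    library.sort(key=lambda c: (c.mz, c.formula.hill()))
    log.info(
        "generated %d candidate ions from %d neutral parents (families: %s)",
        len(library),
        len(parents),
        ", ".join(spec.families),
    )
    return library
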