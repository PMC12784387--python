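"""Marker-rule material identification over an annotated spectrum.

Material identification in heritage-MS practice is presence/absence
reasoning over named marker compounds: abietanes and their high-mass aging
combinations point to colophony-based varnish, diacid-substituted
glycerolipids to aged drying oil, cholesterol to egg binder, dammarane +
cadinene combinations to dammar, long-chain wax esters to beeswax, and the
pyrolytic PAHs retene and simonellite to pine tar.  This module formalizes
that reasoning as a transparent weighted-coverage score.

Each rule carries *required* markers -- an AND of OR-groups that gates any
nonzero score -- and weighted supporting markers.  The score of a gated rule
is (sum of matched weights) / (sum of all weights), hence in [0, 1] and
monotone in the matched set.  Rules are data (``data/marker_rules.json``),
not code, so they can be edited without a release.

Marker syntax: ``component:<name>`` (a provenance parent by name),
``class:<component class>`` (any parent of that class), and structural
``combo:`` markers -- ``resin_dimer``, ``dammarane+cadinene``,
``diacid_glycerolipid``, ``glycerolipid``, ``wax_ester``.

Triterpenoid evidence without a cadinene combination is deliberately not a
material call: several resins and tars share the C30 skeletons, so the
dammar rule reports an ambiguity flag instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .annotate import Annotation
from .generate import Provenance

__all__ = [
    "MarkerRule",
    "MaterialCall",
    "RuleError",
    "default_rules",
    "load_rules",
    "classify",
    "AMBIGUOUS_TRITERPENOID_FLAG",
]

AMBIGUOUS_TRITERPENOID_FLAG = "triterpenoids present but material ambiguous"

_COMBO_KINDS = {
    "resin_dimer": lambda p: p.kind == "resin_dimer",
    "dammarane+cadinene": lambda p: p.kind == "cadinene_combination",
    "glycerolipid": lambda p: p.kind == "acylglycerol",
    "diacid_glycerolipid": lambda p: p.kind == "acylglycerol"
    and "dicarboxylic_acid" in p.parent_classes,
    "wax_ester": lambda p: p.kind == "ester",
}


class RuleError(ValueError):
    """Raised for malformed marker rules."""


@dataclass(frozen=True)
class MarkerRule:
    """One material's identification rule.

    ``required`` is an AND of OR-groups of marker ids; ``weights`` maps every
    scoreable marker id to a non-negative weight.
    """

    material: str
    required: tuple[tuple[str, ...], ...]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.required or any(not group for group in self.required):
            raise RuleError(f"rule {self.material!r} needs at least one required marker")
        if not self.weights:
            raise RuleError(f"rule {self.material!r} has no weighted markers")
        for marker, weight in self.weights.items():
            _validate_marker(marker)
            if weight < 0:
                raise RuleError(f"negative weight for {marker!r} in {self.material!r}")
        for group in self.required:
            for marker in group:
                _validate_marker(marker)


@dataclass(frozen=True)
class MaterialCall:
    """A scored identification for one material."""

    material: str
    score: float
    matched_markers: tuple[str, ...]
    matched_weight: float
    flags: tuple[str, ...] = ()


def _validate_marker(marker: str) -> None:
    kind, sep, arg = marker.partition(":")
    if not sep or not arg:
        raise RuleError(f"malformed marker id {marker!r}")
    if kind not in ("component", "class", "combo"):
        raise RuleError(f"unknown marker kind in {marker!r}")
    if kind == "combo" and arg not in _COMBO_KINDS:
        raise RuleError(f"unknown combo marker {arg!r}")


def _marker_matched(marker: str, provenances: Sequence[Provenance]) -> bool:
    kind, _, arg = marker.partition(":")
    if kind == "component":
        return any(arg in p.parents for p in provenances)
    if kind == "class":
        return any(arg in p.parent_classes for p in provenances)
    return any(_COMBO_KINDS[arg](p) for p in provenances)


def load_rules(path: str | Path) -> list[MarkerRule]:
    """Load rules from a JSON file using the shipped schema."""
    payload = json.loads(Path(path).read_text())
    return _parse_rules(payload)


def _parse_rules(payload: dict) -> list[MarkerRule]:
    rules = []
    for raw in payload["rules"]:
        rules.append(
            MarkerRule(
                material=raw["material"],
                required=tuple(tuple(group) for group in raw["required"]),
                weights=dict(raw["weights"]),
            )
        )
    return rules


def default_rules() -> list[MarkerRule]:
    """The built-in rule set: one rule per material family."""
    text = resources.files("heritagems.data").joinpath("marker_rules.json").read_text()
    return _parse_rules(json.loads(text))


def classify(
    annotations: Sequence[Annotation], rules: Sequence[MarkerRule]
) -> list[MaterialCall]:
    """Score every rule against the rank-1 annotations of one spectrum.

    Returns calls sorted by descending score, ties broken by descending
    absolute matched weight and then material name -- deterministic for
    identical inputs.  With an empty annotation list all scores are zero.
    """
    if not rules:
        raise RuleError("no rules supplied")
    provenances: list[Provenance] = [
        prov
        for a in annotations
        if a.rank == 1
        for prov in a.candidate.provenances
    ]
    calls = []
    for rule in rules:
        matched = tuple(
            marker
            for marker in rule.weights
            if _marker_matched(marker, provenances)
        )
        matched_weight = sum(rule.weights[m] for m in matched)
        total_weight = sum(rule.weights.values())
        gated = all(
            any(_marker_matched(marker, provenances) for marker in group)
            for group in rule.required
        )
        flags: list[str] = []
        if gated:
            score = matched_weight / total_weight if total_weight else 0.0
        else:
            score = 0.0
            mentions_triterpenoids = any(
                "triterpenoid" in m or "dammar" in m
                for group in rule.required
                for m in group
            )
            if mentions_triterpenoids and (
                _marker_matched("class:triterpenoid_dammarane", provenances)
                or _marker_matched("class:triterpenoid_pentacyclic", provenances)
            ):
                flags.append(AMBIGUOUS_TRITERPENOID_FLAG)
            elif matched:
                flags.append("supporting markers present but required markers absent")
        calls.append(
            MaterialCall(
                material=rule.material,
                score=score,
                matched_markers=matched,
                matched_weight=matched_weight if gated else 0.0,
                flags=tuple(flags),
            )
        )
    calls.sort(key=lambda c: (-c.score, -c.matched_weight, c.material))
    return calls
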