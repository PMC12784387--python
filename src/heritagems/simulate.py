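"""Synthetic centroid spectra with known ground truth, plus laser-dose math.

No public repository holds the spectra this kind of analysis is developed
against, so the package carries its own test bed: a simulator that draws
peaks from a candidate-ion library under a material recipe, with

* calibration error -- each measured m/z is the theoretical value times
  (1 + eps), eps ~ Normal(0, sd_ppm x 1e-6), emulating the sub-ppm to 2 ppm
  accuracy of an externally calibrated FT-ICR instrument;
* log-normal intensities scaled by component abundance and by aging
  parameters (hydrolysis shifts weight from TAGs toward DAGs/MAGs/free
  acids; oxidation controls the frequency of +nO variants; a fragmentation
  parameter penalizes water/CO losses);
* uniform-random chemical-noise peaks at a configurable rate per 100 Th,
  with intensities drawn from the lowest decile of the signal.

Intensities are deliberately *not* a physical ionization model -- no such
model is available for laser-ablation APCI of aged films; a class-weighted
log-normal is sufficient to exercise matching, clustering and
classification.  Every signal peak is linked to its candidate ion in the
returned ground-truth table, so recovery can be scored exactly.

The module also carries the instrument-geometry arithmetic: laser fluence
(pulse energy over illuminated spot area, J/cm^2), the dose parameter that
governs ablation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Annotation, Spectrum
from .components import FAMILIES
from .generate import CandidateIon, Provenance

__all__ = [
    "MaterialRecipe",
    "InstrumentGeometry",
    "RecipeError",
    "default_recipe",
    "matte_varnish_recipe",
    "simulate_spectrum",
    "score_recovery",
    "fluence",
    "round_sig",
]


class RecipeError(ValueError):
    """Raised for invalid recipe or geometry parameters."""


@dataclass(frozen=True)
class MaterialRecipe:
    """Composition and noise parameters driving one simulated spectrum.

    ``abundances`` maps material families to relative amounts (>= 0, not all
    zero).  ``hydrolysis`` in [0, 1] moves acylglycerol weight from intact
    TAGs toward DAG/MAG/free-acid hydrolysis products; ``oxidation`` in
    [0, 1] scales the weight of each +O gain; ``fragmentation`` scales each
    water/CO-loss or dehydrogenation step.
    """

    name: str
    abundances: Mapping[str, float]
    hydrolysis: float = 0.5
    oxidation: float = 0.3
    fragmentation: float = 0.3
    calibration_sd_ppm: float = 1.0
    intensity_log_sd: float = 0.7
    noise_per_100: float = 0.2
    n_signal_peaks: int = 120
    mz_window: tuple[float, float] = (100.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.abundances or all(a == 0 for a in self.abundances.values()):
            raise RecipeError("abundances must contain at least one positive entry")
        unknown = set(self.abundances) - set(FAMILIES)
        if unknown:
            raise RecipeError(f"unknown families in recipe: {sorted(unknown)}")
        if any(a < 0 for a in self.abundances.values()):
            raise RecipeError("abundances must be non-negative")
        for attr in ("hydrolysis", "oxidation", "fragmentation"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise RecipeError(f"{attr} must be in [0, 1]")
        if self.calibration_sd_ppm < 0 or self.intensity_log_sd < 0:
            raise RecipeError("standard deviations must be >= 0")
        if self.noise_per_100 < 0:
            raise RecipeError("noise rate must be >= 0")
        if self.n_signal_peaks < 1:
            raise RecipeError("n_signal_peaks must be >= 1")
        lo, hi = self.mz_window
        if not 0 < lo < hi:
            raise RecipeError(f"invalid m/z window {self.mz_window}")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f for f, a in self.abundances.items() if a > 0)


_RECIPE_SIZES = {
    "colophony": 100,
    "linseed_oil": 150,
    "egg_yolk": 120,
    "dammar": 100,
    "beeswax": 80,
    "pine_tar": 80,
}


# Dammar films fragment noticeably less than colophony-based varnish:
# mostly single water losses, little of the combined H2O+CO loss.
_RECIPE_FRAGMENTATION = {"dammar": 0.2, "beeswax": 0.2}


def default_recipe(family: str, **overrides) -> MaterialRecipe:
    """A single-family recipe at the package's standard study conditions."""
    if family not in FAMILIES:
        raise RecipeError(f"unknown material family {family!r}")
    recipe = MaterialRecipe(
        name=family,
        abundances={family: 1.0},
        fragmentation=_RECIPE_FRAGMENTATION.get(family, 0.3),
        n_signal_peaks=_RECIPE_SIZES[family],
    )
    return replace(recipe, **overrides) if overrides else recipe


def matte_varnish_recipe(**overrides) -> MaterialRecipe:
    """Dammar varnish matted with bleached beeswax -- the mixture layer."""
    recipe = MaterialRecipe(
        name="matte_dammar_varnish",
        abundances={"dammar": 1.0, "beeswax": 0.3},
        fragmentation=0.2,
        n_signal_peaks=120,
    )
    return replace(recipe, **overrides) if overrides else recipe


# ---------------------------------------------------------------------------
# Candidate plausibility weighting
# ---------------------------------------------------------------------------

_GLYCEROLIPID_FAMILIES = {"linseed_oil", "egg_yolk"}


def _group_key(p: Provenance) -> tuple:
    """Assembly group of a provenance.

    A group is a family's pool of comparable parent species: all its TAGs,
    all its DAGs, its free acids, its sterols, and so on.  The family's
    signal for a group is shared across the group's members, so that a
    single named compound (cholesterol, retene) is not swamped by the
    combinatorial multiplicity of acylglycerol isomers.
    """
    if p.kind in ("acylglycerol", "ester"):
        subkey: object = len(p.parents)
    else:
        subkey = p.parent_classes[0] if p.parent_classes else ""
    return (p.family, p.kind, subkey)


def _group_factor(p: Provenance, recipe: MaterialRecipe) -> float:
    """Relative signal share of a provenance's assembly group."""
    h = recipe.hydrolysis
    if p.kind == "acylglycerol":
        n_acyl = len(p.parents) - 1  # glycerol + acids
        return {3: max(1.0 - h, 0.05), 2: max(h, 0.05), 1: 0.6 * max(h, 0.05)}[n_acyl]
    if p.kind == "free" and p.family in _GLYCEROLIPID_FAMILIES:
        return 0.5 * max(h, 0.05)
    if p.kind == "resin_dimer":
        return 0.8
    if p.kind == "cadinene_combination":
        return 0.6
    return 1.0


def _modification_factor(p: Provenance, recipe: MaterialRecipe) -> float:
    n_oxygen = 0
    n_other = 0
    for mod in p.modifications:
        if mod.startswith("+"):
            n_oxygen += int(mod[1:-1]) if len(mod) > 2 else 1
        else:
            n_other += 1
    return recipe.oxidation**n_oxygen * recipe.fragmentation**n_other


def _group_sizes(library: Sequence[CandidateIon]) -> dict[tuple, int]:
    """Number of distinct parent assemblies per group, over a whole library."""
    assemblies: dict[tuple, set[str]] = {}
    for candidate in library:
        for p in candidate.provenances:
            assemblies.setdefault(_group_key(p), set()).add(p.assembly)
    return {key: len(val) for key, val in assemblies.items()}


def _provenance_weight(
    p: Provenance, recipe: MaterialRecipe, group_sizes: Mapping[tuple, int]
) -> float:
    abundance = recipe.abundances.get(p.family, 0.0)
    if abundance <= 0:
        return 0.0
    share = _group_factor(p, recipe) / group_sizes[_group_key(p)]
    return abundance * share * _modification_factor(p, recipe)


def _candidate_weight(
    candidate: CandidateIon,
    recipe: MaterialRecipe,
    group_sizes: Mapping[tuple, int],
) -> tuple[float, Provenance | None]:
    best_w, best_p = 0.0, None
    for p in candidate.provenances:
        w = _provenance_weight(p, recipe, group_sizes)
        if w > best_w:
            best_w, best_p = w, p
    return best_w, best_p


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------


def simulate_spectrum(
    recipe: MaterialRecipe,
    library: Sequence[CandidateIon],
    seed: int | None = None,
) -> tuple[Spectrum, pd.DataFrame]:
    """Draw one synthetic spectrum and its ground-truth assignment table.

    ``seed`` overrides ``recipe.seed``; runs with identical inputs are
    bit-reproducible.  The truth table has one row per peak, ``kind`` either
    ``signal`` (with formula, theoretical m/z and generating provenance) or
    ``noise``.
    """
    if not library:
        raise RecipeError("cannot simulate from an empty candidate library")
    rng = np.random.default_rng(recipe.seed if seed is None else seed)
    lo, hi = recipe.mz_window

    group_sizes = _group_sizes(library)
    weights = np.zeros(len(library))
    best_prov: list[Provenance | None] = [None] * len(library)
    for i, candidate in enumerate(library):
        if not lo <= candidate.mz <= hi:
            continue
        weights[i], best_prov[i] = _candidate_weight(candidate, recipe, group_sizes)
    eligible = np.flatnonzero(weights > 0)
    if eligible.size == 0:
        raise RecipeError(
            f"recipe {recipe.name!r} selects no candidates from this library"
        )
    n_signal = min(recipe.n_signal_peaks, eligible.size)
    p = weights[eligible] / weights[eligible].sum()
    chosen = rng.choice(eligible, size=n_signal, replace=False, p=p)
    chosen = np.sort(chosen)

    records = []
    scale = 1.0e7 / weights[chosen].max()
    for i in chosen:
        candidate = library[i]
        prov = best_prov[i]
        measured = candidate.mz * (
            1.0 + rng.normal(0.0, recipe.calibration_sd_ppm * 1e-6)
        )
        intensity = (
            scale
            * weights[i]
            * math.exp(rng.normal(0.0, recipe.intensity_log_sd))
        )
        records.append(
            {
                "kind": "signal",
                "mz": measured,
                "intensity": intensity,
                "formula": candidate.formula.hill(),
                "mz_theoretical": candidate.mz,
                "family": prov.family,
                "assembly": prov.assembly,
                "modifications": "".join(prov.modifications),
            }
        )

    n_noise = rng.poisson(recipe.noise_per_100 * (hi - lo) / 100.0)
    if n_noise:
        signal_intensities = np.array([r["intensity"] for r in records])
        ceiling = float(np.quantile(signal_intensities, 0.1))
        floor = float(signal_intensities.min()) * 0.1
        for mz in rng.uniform(lo, hi, size=n_noise):
            records.append(
                {
                    "kind": "noise",
                    "mz": float(mz),
                    "intensity": float(rng.uniform(floor, ceiling)),
                    "formula": "",
                    "mz_theoretical": np.nan,
                    "family": "",
                    "assembly": "",
                    "modifications": "",
                }
            )

    truth = pd.DataFrame.from_records(records).sort_values("mz", kind="mergesort")
    # Centroided peak lists are strictly increasing; collapse exact collisions.
    truth = truth.drop_duplicates(subset="mz", keep="first").reset_index(drop=True)
    spectrum = Spectrum(
        mz=truth["mz"].to_numpy(),
        intensity=truth["intensity"].to_numpy(),
        metadata={
            "source": "heritagems.simulate",
            "recipe": recipe.name,
            "polarity": "+",
            "window": recipe.mz_window,
            "seed": int(recipe.seed if seed is None else seed),
        },
    )
    return spectrum, truth


def score_recovery(
    annotations: Sequence[Annotation], truth: pd.DataFrame
) -> float:
    """Fraction of signal peaks whose rank-1 annotation is the true formula."""
    rank1 = {a.peak_index: a for a in annotations if a.rank == 1}
    signal = truth.index[truth["kind"] == "signal"]
    if len(signal) == 0:
        return float("nan")
    hits = 0
    for idx in signal:
        a = rank1.get(idx)
        if a is not None and a.candidate.formula.hill() == truth.at[idx, "formula"]:
            hits += 1
    return hits / len(signal)


# ---------------------------------------------------------------------------
# Instrument geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentGeometry:
    """Laser dose geometry: pulse energy on the sample and illuminated spot."""

    pulse_energy_mj: float = 4.8
    spot_diameter_mm: float = 0.4
    pulses_per_acquisition: int = 7
    repetition_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        for attr in (
            "pulse_energy_mj",
            "spot_diameter_mm",
            "pulses_per_acquisition",
            "repetition_rate_hz",
        ):
            if getattr(self, attr) <= 0:
                raise RecipeError(f"{attr} must be positive")


def fluence(geometry: InstrumentGeometry) -> float:
    """Energy fluence in J/cm^2: pulse energy over the circular spot area."""
    energy_j = geometry.pulse_energy_mj * 1e-3
    radius_cm = geometry.spot_diameter_mm / 2.0 / 10.0
    return energy_j / (math.pi * radius_cm**2)


def round_sig(value: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (for reporting fluence)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, digits - 1 - exponent)
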