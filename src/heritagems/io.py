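"""Peak-list readers, report writers and run configuration.

Supported peak-list inputs: two-column CSV/TSV (``mz,intensity`` header
optional), MGF and centroided mzML (both via pyteomics).  Malformed numeric
fields are rejected with the offending line number -- never silently
coerced.  Duplicate m/z values are merged by intensity sum (logged).

Reports mirror the layout of published interpretation tables: measured m/z,
signed ppm error to two decimals, ion formula, ion type and the possible
parent compound(s), as TSV plus a JSON bundle with run metadata (package
version, constants version, config hash, seed).  Identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .annotate import Annotation, Cluster, Spectrum, SpectrumError
from .classify import MaterialCall
from .formula import CONSTANTS_VERSION, format_ppm

__all__ = [
    "PeaklistError",
    "RunConfig",
    "read_peaklist",
    "write_peaklist",
    "write_report",
]

log = logging.getLogger(__name__)


class PeaklistError(ValueError):
    """Raised for unreadable or malformed peak-list files."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    input: str = ""
    families: tuple[str, ...] = ()
    tolerance_ppm: float = 2.0
    min_gap: float = 50.0
    min_peaks: int = 3
    rule_file: str = ""
    output_dir: str = "."
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        if self.min_gap <= 0 or self.min_peaks < 1:
            raise ValueError("invalid cluster parameters")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a JSON config; unknown keys are rejected."""
        payload = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in payload:
            payload["families"] = tuple(payload["families"])
        return cls(**payload)

    def hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _finalize(mz: list[float], intensity: list[float], source: str) -> Spectrum:
    if not mz:
        raise PeaklistError(f"{source}: empty peak list")
    order = np.argsort(mz, kind="stable")
    mz_arr = np.asarray(mz, dtype=float)[order]
    int_arr = np.asarray(intensity, dtype=float)[order]
    unique, inverse = np.unique(mz_arr, return_inverse=True)
    if len(unique) < len(mz_arr):
        log.info(
            "%s: merged %d duplicate m/z values by intensity sum",
            source,
            len(mz_arr) - len(unique),
        )
        summed = np.zeros(len(unique))
        np.add.at(summed, inverse, int_arr)
        mz_arr, int_arr = unique, summed
    return Spectrum(mz=mz_arr, intensity=int_arr, metadata={"source": source})


def _read_delimited(path: Path, delimiter: str) -> Spectrum:
    mz: list[float] = []
    intensity: list[float] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].strip().startswith("#"):
                continue
            if row[0].strip().lower() in ("mz", "m/z"):
                continue  # header row
            if len(row) < 2:
                raise PeaklistError(
                    f"{path}: line {lineno}: expected two columns, got {len(row)}"
                )
            try:
                mz.append(float(row[0]))
                intensity.append(float(row[1]))
            except ValueError as exc:
                raise PeaklistError(
                    f"{path}: line {lineno}: malformed numeric field ({row[:2]})"
                ) from exc
    return _finalize(mz, intensity, str(path))


def _read_mgf(path: Path) -> Spectrum:
    try:
        from pyteomics import mgf
    except ImportError as exc:  # pragma: no cover - present in supported envs
        raise PeaklistError(
            "reading MGF requires the pyteomics package"
        ) from exc
    with mgf.MGF(str(path)) as reader:
        spectra = list(reader)
    if not spectra:
        raise PeaklistError(f"{path}: no spectra in MGF file")
    if len(spectra) > 1:
        log.info("%s: %d spectra in MGF, using the first", path, len(spectra))
    first = spectra[0]
    return _finalize(
        list(first["m/z array"]), list(first["intensity array"]), str(path)
    )


def _read_mzml(path: Path) -> Spectrum:
    try:
        from pyteomics import mzml

        reader = mzml.MzML(str(path))
    except Exception as exc:
        # pyteomics needs its optional psims backend for PSI formats;
        # degrade with a clear message instead of a deep traceback.
        raise PeaklistError(
            "reading mzML requires pyteomics with its psims backend installed; "
            "export the peak list as CSV/TSV or MGF instead"
        ) from exc
    with reader:
        spectra = list(reader)
    if not spectra:
        raise PeaklistError(f"{path}: no spectra in mzML file")
    first = spectra[0]
    if "profile spectrum" in first or "centroid spectrum" not in first:
        raise PeaklistError(
            f"{path}: mzML spectrum is not centroided; peak-pick it first"
        )
    return _finalize(
        list(first["m/z array"]), list(first["intensity array"]), str(path)
    )


_FORMATS = {
    "csv": lambda p: _read_delimited(p, ","),
    "tsv": lambda p: _read_delimited(p, "\t"),
    "mgf": _read_mgf,
    "mzml": _read_mzml,
}

_SUFFIXES = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mgf": "mgf", ".mzml": "mzml"}


def read_peaklist(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read a centroided peak list; format from ``fmt`` or the file suffix."""
    path = Path(path)
    if not path.exists():
        raise PeaklistError(f"no such file: {path}")
    if fmt is None:
        fmt = _SUFFIXES.get(path.suffix.lower())
        if fmt is None:
            raise PeaklistError(f"cannot infer peak-list format of {path}")
    if fmt not in _FORMATS:
        raise PeaklistError(f"unsupported format {fmt!r}")
    try:
        return _FORMATS[fmt](path)
    except SpectrumError as exc:
        raise PeaklistError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    """Write the CSV dialect: header ``mz,intensity``, m/z to 5 decimals."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["mz", "intensity"])
        for m, i in zip(spectrum.mz, spectrum.intensity):
            writer.writerow([f"{m:.5f}", f"{i:.6g}"])


def _annotation_rows(annotations: Sequence[Annotation]) -> list[list[str]]:
    rows = []
    for a in annotations:
        compounds = "; ".join(
            dict.fromkeys(p.describe() for p in a.candidate.provenances)
        )
        rows.append(
            [
                f"{a.peak.mz:.5f}",
                format_ppm(a.ppm),
                f"{a.candidate.formula.hill()}+",
                a.candidate.ion_type(),
                str(a.rank),
                compounds,
            ]
        )
    return rows


def write_report(
    annotations: Sequence[Annotation],
    clusters: Sequence[Cluster],
    calls: Sequence[MaterialCall],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write annotations/clusters/materials TSVs plus a JSON metadata bundle.

    Returns the paths written.  Output is deterministic for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    paths: dict[str, Path] = {}

    paths["annotations"] = out / "annotations.tsv"
    with paths["annotations"].open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "measured_mz",
                "delta_ppm",
                "ion_formula",
                "ion_type",
                "rank",
                "possible_compounds",
            ]
        )
        writer.writerows(_annotation_rows(annotations))

    paths["clusters"] = out / "clusters.tsv"
    with paths["clusters"].open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["low_mz", "high_mz", "n_peaks", "summed_intensity"])
        for cluster in clusters:
            writer.writerow(
                [
                    f"{cluster.low:.5f}",
                    f"{cluster.high:.5f}",
                    str(len(cluster)),
                    f"{cluster.summed_intensity:.6g}",
                ]
            )

    paths["materials"] = out / "materials.tsv"
    with paths["materials"].open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["material", "score", "matched_markers", "flags"])
        for call in calls:
            writer.writerow(
                [
                    call.material,
                    f"{call.score:.3f}",
                    "; ".join(call.matched_markers),
                    "; ".join(call.flags),
                ]
            )

    paths["report"] = out / "report.json"
    payload = {
        "package_version": __version__,
        "constants_version": CONSTANTS_VERSION,
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_annotations": len(annotations),
        "n_rank1": sum(1 for a in annotations if a.rank == 1),
        "n_clusters": len(clusters),
        "materials": [
            {"material": c.material, "score": round(c.score, 6), "flags": list(c.flags)}
            for c in calls
        ],
    }
    paths["report"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
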