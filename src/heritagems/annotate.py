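"""Peak annotation, cluster detection and spectrum summaries.

Centroided peaks are matched to candidate ions within a relative (ppm)
tolerance window using binary search on the m/z-sorted library -- a full
peak x candidate cross product is never formed.  The default tolerance of
2 ppm reflects the mass-accuracy contract of an externally calibrated
FT-ICR instrument; a looser setting (~5 ppm) is appropriate for
uncalibrated data.

Candidates for one peak are ranked by |ppm error|, ties broken by fewer
modifications and then by canonical formula string, so reports are
deterministic.  Isobaric alternative assignments (several parent
combinations giving one cation formula) are carried jointly on the merged
candidate's provenance list rather than competing for rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .generate import CandidateIon
from .formula import ppm_error

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumError",
    "Annotation",
    "Cluster",
    "Summary",
    "annotate",
    "detect_clusters",
    "summarize",
]


class SpectrumError(ValueError):
    """Raised for malformed spectra or annotation inputs."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided peak list: strictly increasing m/z, non-negative intensity."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.shape != self.mz.shape:
            raise SpectrumError("m/z and intensity must be 1-D arrays of equal length")
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            raise SpectrumError("spectrum contains NaN or infinite values")
        if np.any(self.mz <= 0):
            raise SpectrumError("all m/z values must be positive")
        if np.any(self.intensity < 0):
            raise SpectrumError("intensities must be non-negative")
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumError("m/z values must be strictly increasing")
        window = self.metadata.get("window")
        if window is not None and len(self.mz):
            lo, hi = window
            if self.mz[0] < lo or self.mz[-1] > hi:
                raise SpectrumError(
                    f"peaks outside the declared acquisition window {window}"
                )

    def __len__(self) -> int:
        return len(self.mz)

    def peaks(self) -> Iterator[Peak]:
        for m, i in zip(self.mz, self.intensity):
            yield Peak(float(m), float(i))

    def peak(self, index: int) -> Peak:
        return Peak(float(self.mz[index]), float(self.intensity[index]))


@dataclass(frozen=True)
class Annotation:
    """One peak <-> candidate match with its signed ppm error and rank."""

    peak_index: int
    peak: Peak
    candidate: CandidateIon
    ppm: float
    rank: int


@dataclass(frozen=True)
class Cluster:
    """A contiguous group of peaks separated from neighbours by > min_gap."""

    low: float
    high: float
    peak_indices: tuple[int, ...]
    summed_intensity: float

    def __len__(self) -> int:
        return len(self.peak_indices)


def annotate(
    spectrum: Spectrum,
    library: Sequence[CandidateIon],
    tol: float = 2.0,
) -> list[Annotation]:
    """Match every peak against the library within ``tol`` ppm.

    Returns all matches for all peaks, ranked per peak; peaks without any
    candidate produce no annotations (they are 'unannotated' and can be
    counted via :func:`summarize`).  The library must be sorted by m/z.
    """
    if tol <= 0:
        raise SpectrumError(f"tolerance must be positive, got {tol}")
    lib_mz = np.array([c.mz for c in library], dtype=float)
    if np.any(np.diff(lib_mz) < 0):
        raise SpectrumError("candidate library must be sorted by m/z")
    annotations: list[Annotation] = []
    rel = tol * 1e-6
    for index, measured in enumerate(spectrum.mz):
        # |(measured - t)/t| <= rel  <=>  t in [measured/(1+rel), measured/(1-rel)]
        lo = np.searchsorted(lib_mz, measured / (1.0 + rel), side="left")
        hi = np.searchsorted(lib_mz, measured / (1.0 - rel), side="right")
        if lo == hi:
            continue
        matches = sorted(
            library[lo:hi],
            key=lambda c: (
                abs(ppm_error(measured, c.mz)),
                c.n_modifications,
                c.formula.hill(),
            ),
        )
        peak = spectrum.peak(index)
        for rank, candidate in enumerate(matches, start=1):
            annotations.append(
                Annotation(
                    peak_index=index,
                    peak=peak,
                    candidate=candidate,
                    ppm=ppm_error(measured, candidate.mz),
                    rank=rank,
                )
            )
    return annotations


def detect_clusters(
    spectrum: Spectrum, min_gap: float = 50.0, min_peaks: int = 3
) -> list[Cluster]:
    """Greedy scan splitting the peak list at m/z gaps larger than ``min_gap``.

    Clusters with fewer than ``min_peaks`` members are discarded; the
    retained peaks are covered exactly once.
    """
    if min_gap <= 0:
        raise SpectrumError(f"min_gap must be positive, got {min_gap}")
    if len(spectrum) == 0:
        return []
    groups: list[list[int]] = [[0]]
    for i in range(1, len(spectrum)):
        if spectrum.mz[i] - spectrum.mz[i - 1] > min_gap:
            groups.append([])
        groups[-1].append(i)
    clusters = []
    for members in groups:
        if len(members) < min_peaks:
            continue
        clusters.append(
            Cluster(
                low=float(spectrum.mz[members[0]]),
                high=float(spectrum.mz[members[-1]]),
                peak_indices=tuple(members),
                summed_intensity=float(spectrum.intensity[members].sum()),
            )
        )
    return clusters


@dataclass(frozen=True)
class Summary:
    """Annotation coverage of one spectrum."""

    n_peaks: int
    n_annotated: int
    annotated_fraction: float
    intensity_fraction: float
    max_abs_ppm: float
    class_counts: dict[str, int]


def summarize(annotations: Sequence[Annotation], spectrum: Spectrum) -> Summary:
    """Coverage statistics: peak/intensity fractions explained, worst error,
    and rank-1 parent-class counts."""
    rank1 = [a for a in annotations if a.rank == 1]
    if any(a.peak_index >= len(spectrum) for a in rank1):
        raise SpectrumError("annotations do not belong to this spectrum")
    annotated = sorted({a.peak_index for a in rank1})
    total_intensity = float(spectrum.intensity.sum())
    explained = float(spectrum.intensity[annotated].sum()) if annotated else 0.0
    class_counts: dict[str, int] = {}
    for a in rank1:
        classes = {
            cls for prov in a.candidate.provenances for cls in prov.parent_classes
        }
        for cls in sorted(classes):
            class_counts[cls] = class_counts.get(cls, 0) + 1
    n = len(spectrum)
    return Summary(
        n_peaks=n,
        n_annotated=len(annotated),
        annotated_fraction=len(annotated) / n if n else 0.0,
        intensity_fraction=explained / total_intensity if total_intensity else 0.0,
        max_abs_ppm=max((abs(a.ppm) for a in rank1), default=0.0),
        class_counts=class_counts,
    )
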