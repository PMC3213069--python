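"""Query inputs: full spectra and peak lists, denoising and peak picking.

A query is either a processed 1D spectrum (two-column ASCII: ppm,
intensity) or an externally determined peak list (ppm, height).  Spectra
are denoised by a user-supplied noise threshold and reduced to peaks;
peak lists are canonicalized and de-duplicated.  No baseline correction,
apodization or phasing is attempted — inputs are assumed to be fully
processed spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .library import Peak, canonicalize_ppm, dedupe_peaks


@dataclass(frozen=True)
class RawSpectrum:
    """A sampled spectrum: strictly increasing ppm grid with intensities."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or inten.ndim != 1 or ppm.size != inten.size:
            raise ValidationError("spectrum needs matching 1-D ppm and intensity arrays")
        if ppm.size < 3:
            raise ValidationError(f"spectrum too short: {ppm.size} point(s), need at least 3")
        if not (np.isfinite(ppm).all() and np.isfinite(inten).all()):
            raise ValidationError("spectrum contains non-finite values")
        order = np.argsort(ppm, kind="stable")
        ppm, inten = ppm[order], inten[order]
        if np.any(np.diff(ppm) <= 0):
            raise ValidationError("duplicate ppm positions in spectrum")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.ppm.size)


@dataclass(frozen=True)
class PeakList:
    """Canonicalized query peaks, ready for library search."""

    peaks: tuple[Peak, ...]
    origin: str = "user-supplied"  # or "picked-from-spectrum"

    def __post_init__(self):
        peaks = tuple(p if isinstance(p, Peak) else Peak(*p) for p in self.peaks)
        centis = [p.centi for p in peaks]
        if len(set(centis)) != len(centis):
            raise ValidationError("peak list has duplicate canonical coordinates")
        object.__setattr__(self, "peaks", tuple(sorted(peaks, key=lambda p: p.ppm)))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple], origin: str = "user-supplied") -> "PeakList":
        """Build a peak list from (ppm, height) pairs, collapsing duplicates."""
        return cls(dedupe_peaks(pairs), origin=origin)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def ppms(self) -> tuple[float, ...]:
        return tuple(p.ppm for p in self.peaks)

    def centi_array(self) -> np.ndarray:
        return np.array([p.centi for p in self.peaks], dtype=np.int64)

    def above(self, eta: float) -> "PeakList":
        """Peaks with height >= *eta* (the noise-threshold convention)."""
        return PeakList(tuple(p for p in self.peaks if p.height >= eta), origin=self.origin)


def _parse_two_columns(path: str | Path) -> list[tuple[float, float, int]]:
    rows: list[tuple[float, float, int]] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", " ").split()
        if len(tokens) != 2:
            raise ParseError(f"expected two numeric columns, got {line!r}", lineno)
        try:
            rows.append((float(tokens[0]), float(tokens[1]), lineno))
        except ValueError:
            raise ParseError(f"non-numeric token in {line!r}", lineno) from None
    return rows


def read_spectrum(path: str | Path) -> RawSpectrum:
    """Read a two-column ASCII spectrum (ppm, intensity).

    Comma- or whitespace-separated; '#' comment lines skipped.  The
    conventional descending NMR ppm axis is accepted and re-sorted, so
    the result is axis-direction invariant.
    """
    rows = _parse_two_columns(path)
    if len(rows) < 3:
        raise ValidationError(f"{path}: spectrum too short ({len(rows)} point(s), need >= 3)")
    return RawSpectrum(
        ppm=np.array([r[0] for r in rows]), intensity=np.array([r[1] for r in rows])
    )


def read_peaklist(path: str | Path) -> PeakList:
    """Read a two-column ASCII peak list (ppm, height).

    Canonicalizes shifts, collapses duplicate coordinates (larger height
    kept).  An empty file yields an empty peak list; whether that is an
    error is the searcher's decision.
    """
    rows = _parse_two_columns(path)
    return PeakList.from_pairs([(r[0], r[1]) for r in rows], origin="user-supplied")


def pick_peaks(spec: RawSpectrum, eta: float) -> PeakList:
    """Denoise and pick peaks from a spectrum.

    Points with intensity below *eta* are removed first (the comparison
    keeps points with intensity >= eta); peaks are then the local maxima
    of the surviving intensity sequence.  A plateau of equal maximal
    values yields a single peak at the plateau's central ppm.  Peak
    positions are canonicalized to 0.01 ppm; heights are preserved.

    An *eta* above the global maximum yields an empty peak list, not an
    error — downstream search decides how to treat an empty query.
    """
    if eta < 0:
        raise ValidationError(f"noise threshold must be >= 0, got {eta}")
    mask = spec.intensity >= eta
    ppm = spec.ppm[mask]
    inten = spec.intensity[mask]
    if ppm.size == 0:
        return PeakList((), origin="picked-from-spectrum")

    # Group the surviving sequence into runs of equal intensity; a run is a
    # peak if it is higher than both neighbouring runs (sequence ends count
    # as lower).  This realizes the plateau-centering rule.
    peaks: list[tuple[float, float]] = []
    run_start = 0
    runs: list[tuple[int, int, float]] = []  # [start, end) half-open, value
    for i in range(1, inten.size + 1):
        if i == inten.size or inten[i] != inten[run_start]:
            runs.append((run_start, i, float(inten[run_start])))
            run_start = i
    for j, (start, end, value) in enumerate(runs):
        left = runs[j - 1][2] if j > 0 else -np.inf
        right = runs[j + 1][2] if j + 1 < len(runs) else -np.inf
        if value > left and value > right:
            center = (ppm[start] + ppm[end - 1]) / 2.0
            peaks.append((canonicalize_ppm(center), value))
    return PeakList.from_pairs(peaks, origin="picked-from-spectrum")
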