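"""Seedable generators for libraries, mixtures, noise and rendered spectra.

Every benchmark in this package runs on synthetic data produced here, so
no external database download is ever required.  The generators emulate
the structural features of curated ¹H peak-list libraries that matter
for search behaviour:

* per-metabolite peak counts spanning the ranges seen in real curated
  libraries (1–181 peaks for the larger, 1–66 for the smaller);
* cross-metabolite peak-coordinate sharing, controlled by an overlap
  rate (shared coordinates are what make greedy assignment lossy);
* query mixtures pooled from n randomly chosen members;
* two spectral noise channels: random removal of up to 50% of peaks and
  chemical-shift perturbation of ±0.01 … ±0.05 ppm per peak;
* Lorentzian line rendering onto a ppm grid, for exercising the peak
  picker on full spectra.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .library import (
    METABOLITE_TYPES,
    SOLVENTS,
    STANDARD_FREQUENCIES,
    MetaboliteRecord,
    Peak,
    ReferenceLibrary,
    canonicalize_ppm,
    centi_to_ppm,
    dedupe_peaks,
    ppm_to_centi,
)
from .spectra import PeakList, RawSpectrum

#: Shift magnitudes (ppm) at which perturbation noise is defined.
SHIFT_MAGNITUDES = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass(frozen=True)
class NoiseSpec:
    """One spectral-noise condition.

    ``remove_fraction`` of each peak list is deleted uniformly at random
    (count = floor(fraction × n), so at least one peak always survives
    for fractions <= 0.5); every survivor is then shifted by
    ±``shift_magnitude`` ppm with an independent random sign per peak.
    """

    remove_fraction: float = 0.0
    shift_magnitude: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.remove_fraction <= 0.5):
            raise ValidationError(
                f"remove_fraction must be in [0, 0.5], got {self.remove_fraction}"
            )
        if not any(math.isclose(self.shift_magnitude, m) for m in SHIFT_MAGNITUDES):
            raise ValidationError(
                f"shift_magnitude must be one of {SHIFT_MAGNITUDES}, got {self.shift_magnitude}"
            )


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth of a pooled mixture: its members and their pooled peaks."""

    member_ids: tuple[str, ...]
    pooled_peaks: tuple[Peak, ...]

    @property
    def n(self) -> int:
        return len(self.member_ids)

    def to_peaklist(self) -> PeakList:
        return PeakList(self.pooled_peaks, origin="user-supplied")

    def to_json(self) -> str:
        return json.dumps(
            {
                "member_ids": list(self.member_ids),
                "pooled_peaks": [[p.ppm, p.height] for p in self.pooled_peaks],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureTruth":
        obj = json.loads(text)
        return cls(
            member_ids=tuple(obj["member_ids"]),
            pooled_peaks=dedupe_peaks([tuple(p) for p in obj["pooled_peaks"]]),
        )


def generate_library(
    k: int,
    peak_count_range: tuple[int, int] = (1, 66),
    ppm_range: tuple[float, float] = (0.0, 10.0),
    overlap_rate: float = 0.25,
    seed: int | None = None,
    source: str = "synthetic",
) -> ReferenceLibrary:
    """Generate a synthetic reference library of *k* metabolite records.

    Per-record peak counts are drawn uniformly in ``peak_count_range``.
    Each peak coordinate is, with probability ``overlap_rate``, re-drawn
    from coordinates already used by earlier records (creating the
    cross-metabolite sharing structure real libraries show); otherwise it
    is a fresh, globally unused 0.01 ppm grid point.  With
    ``overlap_rate=0`` the records are therefore pairwise disjoint.

    Raises
    ------
    ConfigurationError
        If the grid inside ``ppm_range`` cannot supply the requested
        number of distinct coordinates.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    cmin, cmax = int(peak_count_range[0]), int(peak_count_range[1])
    if not (1 <= cmin <= cmax):
        raise ConfigurationError(f"invalid peak_count_range {peak_count_range}")
    if not (0.0 <= overlap_rate <= 1.0):
        raise ConfigurationError(f"overlap_rate must be in [0, 1], got {overlap_rate}")
    lo_c = ppm_to_centi(canonicalize_ppm(ppm_range[0]))
    hi_c = ppm_to_centi(canonicalize_ppm(ppm_range[1]))
    grid_size = hi_c - lo_c + 1
    if grid_size < cmax:
        raise ConfigurationError(
            f"ppm_range {ppm_range} holds only {grid_size} grid coordinates, "
            f"fewer than the maximal peak count {cmax}"
        )

    rng = np.random.default_rng(seed)
    used: set[int] = set()       # coordinates used by any finished record
    unused = list(range(lo_c, hi_c + 1))
    rng.shuffle(unused)          # fresh coordinates served in shuffled order
    fresh_pos = 0

    mtypes = sorted(METABOLITE_TYPES)
    solvents = sorted(SOLVENTS)
    width = max(4, len(str(k)))
    records: list[MetaboliteRecord] = []
    for i in range(1, k + 1):
        count = int(rng.integers(cmin, cmax + 1))
        coords: set[int] = set()
        shared_pool = sorted(used)
        while len(coords) < count:
            pool = [c for c in shared_pool if c not in coords]
            if pool and rng.random() < overlap_rate:
                coords.add(int(pool[rng.integers(len(pool))]))
                continue
            # fresh draw: next unused shuffled grid point
            while fresh_pos < len(unused) and unused[fresh_pos] in used:
                fresh_pos += 1
            if fresh_pos >= len(unused):
                raise ConfigurationError(
                    "ppm grid exhausted: widen ppm_range, raise overlap_rate, "
                    "or lower k / peak counts"
                )
            coords.add(unused[fresh_pos])
            fresh_pos += 1
        used.update(coords)
        heights = rng.uniform(1.0, 100.0, size=count)
        peaks = tuple(
            Peak(centi_to_ppm(c), float(h)) for c, h in zip(sorted(coords), heights)
        )
        records.append(
            MetaboliteRecord(
                id=f"SYN{i:0{width}d}",
                name=f"synthetic metabolite {i}",
                peaks=peaks,
                source=source,
                mtype=str(rng.choice(mtypes)),
                ph=round(float(rng.uniform(3.0, 10.0)), 2),
                solvent=str(rng.choice(solvents)),
                frequency=float(rng.choice(STANDARD_FREQUENCIES)),
            )
        )
    return ReferenceLibrary(records)


def make_mixture(lib: ReferenceLibrary, n: int, seed: int | None = None) -> MixtureTruth:
    """Pool *n* distinct records sampled uniformly without replacement.

    The pooled peak list is the canonical union of the members' peaks
    (shared coordinates collapse, larger height kept).
    """
    if not (1 <= n <= len(lib)):
        raise ConfigurationError(f"mixture size n={n} outside [1, k={len(lib)}]")
    rng = np.random.default_rng(seed)
    ids = sorted(lib.ids)
    members = tuple(sorted(str(x) for x in rng.choice(ids, size=n, replace=False)))
    pooled: list[Peak] = []
    for mid in members:
        pooled.extend(lib.get(mid).peaks)
    return MixtureTruth(member_ids=members, pooled_peaks=dedupe_peaks(pooled))


def apply_noise(
    peaks: Sequence[Peak],
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> tuple[Peak, ...]:
    """Apply removal then shift noise to a peak set.

    floor(remove_fraction × n) peaks are deleted uniformly at random;
    each survivor is shifted by +magnitude or -magnitude with equal
    probability and re-canonicalized (coordinates that collide after the
    shift collapse, larger height kept).  Deterministic under
    ``noise.seed`` unless an explicit *rng* is passed.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    peaks = tuple(peaks)
    n = len(peaks)
    if n == 0:
        return ()
    n_remove = int(math.floor(noise.remove_fraction * n))
    if n_remove:
        drop = set(rng.choice(n, size=n_remove, replace=False).tolist())
        survivors = [p for i, p in enumerate(peaks) if i not in drop]
    else:
        survivors = list(peaks)
    if noise.shift_magnitude > 0:
        signs = rng.choice((-1.0, 1.0), size=len(survivors))
        survivors = [
            Peak(canonicalize_ppm(p.ppm + s * noise.shift_magnitude), p.height)
            for p, s in zip(survivors, signs)
        ]
    return dedupe_peaks(survivors)


def render_spectrum(
    peaks: Sequence[Peak],
    linewidth: float = 0.02,
    grid_step: float = 0.002,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ppm_range: tuple[float, float] | None = None,
    pad: float = 0.5,
) -> RawSpectrum:
    """Render a peak set as a sampled spectrum of Lorentzian lines.

    Each peak contributes ``h · (w/2)² / ((x - c)² + (w/2)²)`` with
    full-width-at-half-maximum *linewidth*; Gaussian baseline noise of
    standard deviation *noise_sd* is added on a uniform ppm grid.  The
    grid spans the peaks padded by *pad* ppm, or ``ppm_range`` if given.

    Requires ``grid_step <= linewidth / 4`` so every line is resolved by
    the grid.
    """
    if linewidth <= 0 or grid_step <= 0:
        raise ConfigurationError("linewidth and grid_step must be positive")
    if grid_step > linewidth / 4:
        raise ConfigurationError(
            f"grid_step {grid_step} must be <= linewidth/4 = {linewidth / 4}"
        )
    peaks = tuple(peaks)
    if ppm_range is not None:
        lo, hi = float(ppm_range[0]), float(ppm_range[1])
    elif peaks:
        lo = min(p.ppm for p in peaks) - pad
        hi = max(p.ppm for p in peaks) + pad
    else:
        lo, hi = 0.0, 10.0
    if hi <= lo:
        raise ConfigurationError(f"empty ppm interval [{lo}, {hi}]")
    x = np.arange(lo, hi + grid_step / 2, grid_step)
    if x.size < 3:
        raise ConfigurationError("grid too coarse for the requested interval")
    y = np.zeros_like(x)
    hw = linewidth / 2.0
    for p in peaks:
        y += p.height * hw**2 / ((x - p.ppm) ** 2 + hw**2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    return RawSpectrum(ppm=x, intensity=y)
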