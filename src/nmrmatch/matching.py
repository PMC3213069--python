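"""Significance scoring and the three library-search strategies.

The ranking statistic for a candidate metabolite with ``matched`` of its
``total`` library peaks found in the query is

    score = matched / (total + 1)

which, unlike the plain matched/total fraction, strictly prefers the
peak-richer candidate among metabolites with the same matched fraction
(5/10 scores 0.4545 while 2/4 scores 0.40).  The plain fraction is kept
available as the alternative scoring function ``f1`` for head-to-head
comparisons.

Three search strategies share this score:

``MH1``
    Exact matching: a library peak matches only a query peak at the same
    canonical 0.01 ppm coordinate.
``MH2``
    Tolerance matching: a library peak q matches if some query peak lies
    in the inclusive window [q - tol, q + tol]; with tol = 0 it is
    bit-identical to MH1.
``MH3``
    Greedy mutually exclusive assignment: repeatedly emit the
    best-scoring candidate and remove the query peaks it consumed, so
    later candidates cannot reuse them.  This trades false negatives
    (overlapping metabolites lose their peaks to earlier picks) for a
    much lower false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, ValidationError
from .library import (
    MetaboliteRecord,
    ReferenceLibrary,
    centi_to_ppm,
    filter_records,
    round2,
)
from .spectra import PeakList

METHODS = ("MH1", "MH2", "MH3")
SCORE_FUNCTIONS = ("f1", "f2")

#: Tiny slack so an integer centi-ppm distance exactly at the tolerance
#: boundary is counted inside the inclusive window despite float rounding.
_TOL_EPS = 1e-9


def significance_score(matched: int, total: int) -> float:
    """matched / (total + 1), the default ranking statistic (``f2``).

    Full precision; rounding to two decimals is display-only.
    """
    if total < 1:
        raise ValidationError(f"total peak count must be >= 1, got {total}")
    if matched < 0 or matched > total:
        raise ValidationError(f"matched={matched} outside [0, total={total}]")
    return matched / (total + 1)


def percentage_score(matched: int, total: int) -> float:
    """matched / total, the plain fraction used by earlier tools (``f1``)."""
    if total < 1:
        raise ValidationError(f"total peak count must be >= 1, got {total}")
    if matched < 0 or matched > total:
        raise ValidationError(f"matched={matched} outside [0, total={total}]")
    return matched / total


_SCORERS: dict[str, Callable[[int, int], float]] = {
    "f1": percentage_score,
    "f2": significance_score,
}


@dataclass
class SearchConfig:
    """Parameters of a library search.

    Parameters
    ----------
    method:
        ``"MH1"`` (exact), ``"MH2"`` (tolerance) or ``"MH3"`` (greedy).
    eta:
        Noise threshold; query peaks with height below it are dropped
        before matching.
    r:
        Confidence threshold in [0, 1]; only candidates with score >= r
        (inclusive) are reported.  Default 0.5.
    tolerance:
        Shift tolerance in ppm for the inclusive matching window.
        Must be 0 for MH1.  Default 0.
    features:
        Metadata filter passed to :func:`~nmrmatch.library.filter_records`.
    max_results:
        Cap on the ranked output length.  Default 100.
    score_function:
        ``"f2"`` (default, matched/(total+1)) or ``"f1"`` (matched/total).
    allow_mh3_tolerance:
        MH3 with a nonzero tolerance removes every query peak inside the
        window of each matched library peak; this mode is experimental
        and must be opted into explicitly.
    """

    method: str = "MH1"
    eta: float = 0.0
    r: float = 0.5
    tolerance: float = 0.0
    features: Mapping | None = None
    max_results: int = 100
    score_function: str = "f2"
    allow_mh3_tolerance: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not (0.0 <= self.r <= 1.0):
            raise ConfigurationError(f"confidence threshold r must be in [0, 1], got {self.r}")
        if self.tolerance < 0:
            raise ConfigurationError(f"shift tolerance must be >= 0, got {self.tolerance}")
        if self.eta < 0:
            raise ConfigurationError(f"noise threshold must be >= 0, got {self.eta}")
        if self.method == "MH1" and self.tolerance != 0:
            raise ConfigurationError("MH1 is exact matching: shift tolerance must be 0")
        if (
            self.method == "MH3"
            and self.tolerance != 0
            and not self.allow_mh3_tolerance
        ):
            raise ConfigurationError(
                "MH3 with nonzero shift tolerance is experimental; "
                "set allow_mh3_tolerance=True to enable it"
            )
        if self.max_results < 1:
            raise ConfigurationError(f"max_results must be >= 1, got {self.max_results}")
        if self.score_function not in SCORE_FUNCTIONS:
            raise ConfigurationError(
                f"unknown score function {self.score_function!r}; choose from {SCORE_FUNCTIONS}"
            )


@dataclass(frozen=True)
class MatchResult:
    """One ranked candidate: score, match counts and matched coordinates."""

    metabolite_id: str
    name: str
    score: float
    matched: int
    total: int
    matched_coords: tuple[float, ...]
    rank: int = 0

    @property
    def display_score(self) -> float:
        return round2(self.score)


def count_matches(
    record_peaks: Sequence[float] | np.ndarray,
    sample: PeakList | Sequence[float],
    tolerance: float = 0.0,
) -> tuple[int, tuple[float, ...]]:
    """Count library peaks matched by the sample under a shift tolerance.

    A library peak q is matched iff some sample peak p satisfies
    |q - p| <= tolerance (inclusive window); each library peak counts at
    most once no matter how many sample peaks fall inside its window.
    Tolerance 0 means exact canonical equality.  Returns the matched
    count and the matched library coordinates.
    """
    from .library import Peak, ppm_to_centi  # local to avoid cycle noise

    if isinstance(sample, PeakList):
        sample_c = sample.centi_array()
    else:
        sample_c = np.array(
            [p.centi if isinstance(p, Peak) else ppm_to_centi(float(p)) for p in sample],
            dtype=np.int64,
        )
    if isinstance(record_peaks, np.ndarray):
        lib_c = record_peaks.astype(np.int64)
    else:
        lib_c = np.array(
            [p.centi if isinstance(p, Peak) else ppm_to_centi(float(p)) for p in record_peaks],
            dtype=np.int64,
        )
    mask = _match_mask(np.sort(lib_c), np.sort(sample_c), tolerance)
    matched_coords = tuple(centi_to_ppm(int(c)) for c in np.sort(lib_c)[mask])
    return int(mask.sum()), matched_coords


def _match_mask(lib_c: np.ndarray, sample_c: np.ndarray, tolerance: float) -> np.ndarray:
    """Boolean mask over sorted *lib_c*: which coordinates have a sample
    peak within *tolerance* ppm.  Both inputs are sorted centi-ppm ints."""
    if lib_c.size == 0 or sample_c.size == 0:
        return np.zeros(lib_c.size, dtype=bool)
    tol_c = tolerance * 100.0 + _TOL_EPS
    idx = np.searchsorted(sample_c, lib_c)
    left = np.abs(lib_c - sample_c[np.clip(idx - 1, 0, sample_c.size - 1)])
    right = np.abs(sample_c[np.clip(idx, 0, sample_c.size - 1)] - lib_c)
    return np.minimum(left, right) <= tol_c


def _prepare(sample: PeakList, lib: ReferenceLibrary, cfg: SearchConfig):
    flib = filter_records(lib, cfg.features)
    if len(flib) == 0:
        raise ConfigurationError("no library records pass the metadata filter")
    denoised = sample.above(cfg.eta)
    if len(denoised) == 0:
        raise EmptyInputError(
            "query peak list is empty after noise thresholding; nothing to search"
        )
    return denoised, flib


def rank_results(results: Sequence[MatchResult], cfg: SearchConfig) -> list[MatchResult]:
    """Order results and assign 1-based ranks.

    Descending full-precision score; ties broken by more matched peaks,
    then lexicographic id.  Truncated at ``cfg.max_results``.
    """
    ordered = sorted(results, key=lambda m: (-m.score, -m.matched, m.metabolite_id))
    return [replace(m, rank=i) for i, m in enumerate(ordered[: cfg.max_results], start=1)]


def _linear_search(
    sample: PeakList, lib: ReferenceLibrary, cfg: SearchConfig, tolerance: float
) -> list[MatchResult]:
    denoised, flib = _prepare(sample, lib, cfg)
    sample_c = denoised.centi_array()  # already sorted by construction
    scorer = _SCORERS[cfg.score_function]
    hits: list[MatchResult] = []
    centi = flib.centi_arrays()
    for rec in flib:
        lib_c = centi[rec.id]
        mask = _match_mask(lib_c, sample_c, tolerance)
        matched = int(mask.sum())
        if matched == 0:
            continue
        score = scorer(matched, rec.total)
        if score >= cfg.r:
            hits.append(
                MatchResult(
                    metabolite_id=rec.id,
                    name=rec.name,
                    score=score,
                    matched=matched,
                    total=rec.total,
                    matched_coords=tuple(centi_to_ppm(int(c)) for c in lib_c[mask]),
                )
            )
    return rank_results(hits, cfg)


def mh1_search(sample: PeakList, lib: ReferenceLibrary, cfg: SearchConfig) -> list[MatchResult]:
    """Exact matching: score every candidate at zero tolerance, report
    those with score >= r in descending score order."""
    if cfg.method != "MH1":
        raise ConfigurationError(f"mh1_search called with method {cfg.method!r}")
    return _linear_search(sample, lib, cfg, tolerance=0.0)


def mh2_search(sample: PeakList, lib: ReferenceLibrary, cfg: SearchConfig) -> list[MatchResult]:
    """Tolerance matching: identical to MH1 except a library peak may be
    matched by any sample peak within the inclusive tolerance window."""
    if cfg.method != "MH2":
        raise ConfigurationError(f"mh2_search called with method {cfg.method!r}")
    return _linear_search(sample, lib, cfg, tolerance=cfg.tolerance)


def mh3_search(sample: PeakList, lib: ReferenceLibrary, cfg: SearchConfig) -> list[MatchResult]:
    """Greedy mutually exclusive assignment.

    Iteratively: re-score all remaining candidates against the remaining
    query peaks; select the highest score (ties: more library peaks, then
    lexicographic id); if its score >= r and it matches at least one
    remaining peak, emit it and remove the query coordinates it consumed,
    otherwise stop.  Also stops when query peaks or candidates run out.
    Ranks reflect selection order.

    Residual query peaks matching no candidate simply terminate the loop:
    they stay unassigned (noise, or an unknown compound).
    """
    if cfg.method != "MH3":
        raise ConfigurationError(f"mh3_search called with method {cfg.method!r}")
    denoised, flib = _prepare(sample, lib, cfg)
    tolerance = cfg.tolerance
    scorer = _SCORERS[cfg.score_function]
    remaining = denoised.centi_array()
    centi = flib.centi_arrays()
    candidates = list(flib)
    emitted: list[MatchResult] = []

    while remaining.size and candidates and len(emitted) < cfg.max_results:
        best: tuple | None = None
        for rec in candidates:
            lib_c = centi[rec.id]
            mask = _match_mask(lib_c, remaining, tolerance)
            matched = int(mask.sum())
            score = scorer(matched, rec.total) if matched else 0.0
            key = (-score, -rec.total, rec.id)
            if best is None or key < best[0]:
                best = (key, rec, mask, matched, score)
        _, rec, mask, matched, score = best
        if matched == 0 or score < cfg.r:
            break
        lib_c = centi[rec.id]
        matched_c = lib_c[mask]
        emitted.append(
            MatchResult(
                metabolite_id=rec.id,
                name=rec.name,
                score=score,
                matched=matched,
                total=rec.total,
                matched_coords=tuple(centi_to_ppm(int(c)) for c in matched_c),
                rank=len(emitted) + 1,
            )
        )
        if tolerance == 0:
            consume = np.isin(remaining, matched_c)
        else:
            tol_c = tolerance * 100.0 + _TOL_EPS
            consume = np.zeros(remaining.size, dtype=bool)
            for q in matched_c:
                consume |= np.abs(remaining - q) <= tol_c
        remaining = remaining[~consume]
        candidates.remove(rec)
    return emitted


_SEARCHERS = {"MH1": mh1_search, "MH2": mh2_search, "MH3": mh3_search}


def search(sample: PeakList, lib: ReferenceLibrary, cfg: SearchConfig) -> list[MatchResult]:
    """Dispatch to the strategy named in ``cfg.method``."""
    return _SEARCHERS[cfg.method](sample, lib, cfg)


def results_to_frame(results: Sequence[MatchResult], lib: ReferenceLibrary) -> pd.DataFrame:
    """Tabulate ranked results with record metadata for display/export."""
    rows = []
    for m in results:
        rec = lib.get(m.metabolite_id)
        rows.append(
            {
                "rank": m.rank,
                "id": m.metabolite_id,
                "name": m.name,
                "score": f"{m.display_score:.2f}",
                "score_full": m.score,
                "matched": m.matched,
                "total": m.total,
                "source": rec.source,
                "mtype": rec.mtype,
                "ph": rec.ph,
                "solvent": rec.solvent,
                "frequency": rec.frequency,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "id", "name", "score", "score_full", "matched", "total",
            "source", "mtype", "ph", "solvent", "frequency",
        ],
    )


def write_results_tsv(
    results: Sequence[MatchResult], lib: ReferenceLibrary, path: str | Path
) -> None:
    results_to_frame(results, lib).to_csv(path, sep="\t", index=False)
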