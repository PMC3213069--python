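"""Reference metabolite peak-list libraries: data model, text I/O, indexing.

A reference library is a curated collection of single-metabolite ¹H peak
lists, each peak a (chemical shift, relative height) pair, together with
the acquisition metadata that matters for matching across experimental
conditions: provenance, metabolite type, sample pH, solvent and
spectrometer frequency.

Chemical shifts are canonicalized to 0.01 ppm precision on entry.  All
downstream matching compares canonical coordinates, internally as integer
centi-ppm, so that "equal ppm" is exact arithmetic and never a floating
point accident.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ParseError, ValidationError

#: Metabolite provenance classes recognized in record metadata.
METABOLITE_TYPES = frozenset(
    {
        "drug",
        "food additive",
        "mammalian",
        "microbial",
        "plant",
        "synthetic/industrial chemical",
    }
)

#: Solvents recognized in record metadata.
SOLVENTS = frozenset({"water", "CDCl3", "CD3OD", "5% DMSO"})

#: Spectrometer frequencies (MHz) found in the curated reference data;
#: user-supplied records may carry any positive frequency.
STANDARD_FREQUENCIES = (400.0, 500.0, 600.0)

#: Valid sample pH interval for reference records.
PH_RANGE = (3.0, 10.0)

_QUANTUM = Decimal("0.01")


def canonicalize_ppm(value: float) -> float:
    """Round a chemical shift to 0.01 ppm, half away from zero.

    The rule is deterministic and idempotent: ``canonicalize_ppm(1.005)``
    is 1.01 on every platform, and re-canonicalizing a canonical value is
    the identity.

    Raises
    ------
    ValidationError
        If *value* is NaN or infinite.
    """
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"chemical shift is not a number: {value!r}") from exc
    if not math.isfinite(value):
        raise ValidationError(f"chemical shift must be finite, got {value!r}")
    # Decimal(repr(x)) sees the shortest decimal literal for x, so 1.005
    # quantizes from "1.005" and not from its binary expansion.
    return float(Decimal(repr(value)).quantize(_QUANTUM, rounding=ROUND_HALF_UP))


def ppm_to_centi(ppm: float) -> int:
    """Canonical ppm -> exact integer centi-ppm coordinate."""
    return int(round(ppm * 100))


def centi_to_ppm(centi: int) -> float:
    return centi / 100.0


def round2(value: float) -> float:
    """Display rounding to two decimals, half away from zero."""
    return float(Decimal(repr(float(value))).quantize(_QUANTUM, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, order=True)
class Peak:
    """A single resonance: canonical chemical shift (ppm) and height.

    Heights are unitless relative intensities; they are kept for display
    and for noise thresholding of query peaks but are never compared
    across library records.
    """

    ppm: float
    height: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "ppm", canonicalize_ppm(self.ppm))
        try:
            h = float(self.height)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"peak height is not a number: {self.height!r}") from exc
        if not math.isfinite(h) or h < 0:
            raise ValidationError(f"peak height must be finite and >= 0, got {h!r}")
        object.__setattr__(self, "height", h)

    @property
    def centi(self) -> int:
        return ppm_to_centi(self.ppm)


def dedupe_peaks(peaks: Iterable[Peak | tuple], warn: bool = False) -> tuple[Peak, ...]:
    """Collapse peaks sharing a canonical coordinate, keeping the larger height.

    Matching is coordinate-based, so duplicates would double-count; the
    taller duplicate is retained.  Returns peaks sorted by ppm.
    """
    coerced = [p if isinstance(p, Peak) else Peak(*p) for p in peaks]
    by_coord: dict[int, Peak] = {}
    collapsed = 0
    for p in coerced:
        prev = by_coord.get(p.centi)
        if prev is None:
            by_coord[p.centi] = p
        else:
            collapsed += 1
            if p.height > prev.height:
                by_coord[p.centi] = p
    if collapsed and warn:
        warnings.warn(
            f"collapsed {collapsed} duplicate peak coordinate(s) after 0.01 ppm "
            "canonicalization (larger height kept)",
            stacklevel=2,
        )
    return tuple(sorted(by_coord.values(), key=lambda p: p.ppm))


@dataclass(frozen=True)
class MetaboliteRecord:
    """One library entry: an identified metabolite and its peak list."""

    id: str
    name: str
    peaks: tuple[Peak, ...]
    source: str = "user"
    mtype: str = "mammalian"
    ph: float = 7.0
    solvent: str = "water"
    frequency: float = 500.0

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"record id must be non-empty without whitespace: {self.id!r}")
        peaks = tuple(p if isinstance(p, Peak) else Peak(*p) for p in self.peaks)
        if not peaks:
            raise ValidationError(f"record {self.id!r} has an empty peak list")
        centis = [p.centi for p in peaks]
        if len(set(centis)) != len(centis):
            raise ValidationError(
                f"record {self.id!r} has duplicate peak coordinates after canonicalization"
            )
        object.__setattr__(self, "peaks", tuple(sorted(peaks, key=lambda p: p.ppm)))
        if self.mtype not in METABOLITE_TYPES:
            raise ValidationError(f"record {self.id!r}: unknown metabolite type {self.mtype!r}")
        if self.solvent not in SOLVENTS:
            raise ValidationError(f"record {self.id!r}: unknown solvent {self.solvent!r}")
        ph = float(self.ph)
        if not (PH_RANGE[0] <= ph <= PH_RANGE[1]):
            raise ValidationError(
                f"record {self.id!r}: pH {ph} outside [{PH_RANGE[0]}, {PH_RANGE[1]}]"
            )
        object.__setattr__(self, "ph", ph)
        freq = float(self.frequency)
        if not (math.isfinite(freq) and freq > 0):
            raise ValidationError(f"record {self.id!r}: frequency must be positive, got {freq!r}")
        object.__setattr__(self, "frequency", freq)

    @property
    def total(self) -> int:
        """Total number of peaks (the denominator basis of the score)."""
        return len(self.peaks)

    def ppms(self) -> tuple[float, ...]:
        return tuple(p.ppm for p in self.peaks)

    def centi_array(self) -> np.ndarray:
        return np.array([p.centi for p in self.peaks], dtype=np.int64)


class ReferenceLibrary:
    """Indexed collection of :class:`MetaboliteRecord`.

    Besides the record list, the library maintains ``peak_index``, the
    inverse mapping canonical ppm coordinate -> ids of all records with a
    peak there, which is what makes coordinate-driven search cheap.

    A library is normally non-empty; empty instances arise only as the
    result of metadata filtering and are rejected by ``save_library`` and
    by the search entry points.
    """

    def __init__(self, records: Sequence[MetaboliteRecord]):
        records = tuple(records)
        ids = [r.id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate record id(s): {sorted(dupes)}")
        self._records = records
        self._by_id = {r.id: r for r in records}
        self._peak_index: dict[float, tuple[str, ...]] | None = None
        self._centi_cache: dict[str, np.ndarray] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[MetaboliteRecord]:
        return iter(self._records)

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self._by_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceLibrary):
            return NotImplemented
        return self._records == other._records

    @property
    def records(self) -> tuple[MetaboliteRecord, ...]:
        return self._records

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self._records)

    def get(self, metabolite_id: str) -> MetaboliteRecord:
        try:
            return self._by_id[metabolite_id]
        except KeyError:
            raise KeyError(f"no record with id {metabolite_id!r}") from None

    @property
    def peak_index(self) -> Mapping[float, tuple[str, ...]]:
        """Canonical ppm -> ids of records having a peak at that coordinate."""
        if self._peak_index is None:
            idx: dict[float, list[str]] = {}
            for rec in self._records:
                for p in rec.peaks:
                    idx.setdefault(p.ppm, []).append(rec.id)
            self._peak_index = {ppm: tuple(ids) for ppm, ids in sorted(idx.items())}
        return self._peak_index

    def centi_arrays(self) -> Mapping[str, np.ndarray]:
        """Per-record sorted centi-ppm coordinate arrays (cached)."""
        if self._centi_cache is None:
            self._centi_cache = {r.id: r.centi_array() for r in self._records}
        return self._centi_cache

    def filter(self, features: Mapping | None) -> "ReferenceLibrary":
        return filter_records(self, features)


_FILTER_KEYS = frozenset({"mtype", "ph", "solvent", "frequency", "source"})


def filter_records(lib: ReferenceLibrary, features: Mapping | None) -> ReferenceLibrary:
    """Restrict a library to records satisfying every metadata constraint.

    ``features`` maps any of ``mtype``, ``solvent``, ``source``,
    ``frequency`` (exact value or collection of values) and ``ph``
    (exact value or ``(low, high)`` inclusive interval).  An empty or
    ``None`` filter returns the library unchanged.
    """
    if not features:
        return lib
    unknown = set(features) - _FILTER_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown feature filter key(s) {sorted(unknown)}; valid keys: {sorted(_FILTER_KEYS)}"
        )

    def keep(rec: MetaboliteRecord) -> bool:
        for key, want in features.items():
            have = getattr(rec, key)
            if key == "ph" and isinstance(want, (tuple, list)):
                lo, hi = want
                if not (float(lo) <= have <= float(hi)):
                    return False
            elif key == "frequency":
                values = want if isinstance(want, (set, frozenset, tuple, list)) else (want,)
                if not any(math.isclose(have, float(v)) for v in values):
                    return False
            elif isinstance(want, (set, frozenset, tuple, list)):
                if have not in want:
                    return False
            elif have != want:
                return False
        return True

    return ReferenceLibrary([r for r in lib if keep(r)])


# ---------------------------------------------------------------------------
# Native text format
#
#   # comment
#   @id<TAB>name<TAB>source<TAB>mtype<TAB>ph<TAB>solvent<TAB>frequency
#   ppm<TAB>height
#   ...
#
# One block per metabolite, UTF-8, records sorted by id on save so the
# format is bit-stable under round-trips.
# ---------------------------------------------------------------------------

_FORMAT_HEADER = "# nmrmatch reference library v1"


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def save_library(lib: ReferenceLibrary, path: str | Path) -> None:
    """Write a library in the native text format (records sorted by id).

    Refuses to write an empty library; ``load_library(save_library(lib))``
    reproduces *lib* up to record order.
    """
    if len(lib) == 0:
        raise ValidationError("refusing to save an empty library")
    lines = [_FORMAT_HEADER]
    for rec in sorted(lib, key=lambda r: r.id):
        lines.append(
            "@"
            + "\t".join(
                [
                    rec.id,
                    rec.name,
                    rec.source,
                    rec.mtype,
                    f"{rec.ph:.2f}",
                    rec.solvent,
                    _format_number(rec.frequency),
                ]
            )
        )
        for p in rec.peaks:
            lines.append(f"{p.ppm:.2f}\t{_format_number(p.height)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_library(path: str | Path, dialect: str = "native") -> ReferenceLibrary:
    """Load a reference library.

    Parameters
    ----------
    path:
        Native format: a single text file.  ``hmdb-peaklist`` dialect: a
        directory of per-metabolite two-column peak files plus an optional
        ``metadata.tsv`` sidecar.
    dialect:
        ``"native"`` or ``"hmdb-peaklist"``.
    """
    if dialect == "native":
        return _load_native(Path(path))
    if dialect == "hmdb-peaklist":
        return _load_hmdb_like(Path(path))
    raise ConfigurationError(f"unknown library dialect {dialect!r}")


def _load_native(path: Path) -> ReferenceLibrary:
    records: list[MetaboliteRecord] = []
    header: list[str] | None = None
    pending: list[Peak] = []
    header_line = 0

    def flush():
        nonlocal header, pending
        if header is None:
            return
        hid, name, source, mtype, ph, solvent, freq = header
        peaks = dedupe_peaks(pending, warn=True)
        if not peaks:
            raise ValidationError(f"record {hid!r} (header at line {header_line}) has no peaks")
        records.append(
            MetaboliteRecord(
                id=hid, name=name, peaks=peaks, source=source, mtype=mtype,
                ph=float(ph), solvent=solvent, frequency=float(freq),
            )
        )
        header, pending = None, []

    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            flush()
            fields = line[1:].split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"record header needs 7 tab-separated fields, got {len(fields)}", lineno
                )
            header = fields
            header_line = lineno
            continue
        if header is None:
            raise ParseError("peak line before any record header", lineno)
        tokens = line.replace(",", " ").split()
        if len(tokens) != 2:
            raise ParseError(f"expected 'ppm height', got {line!r}", lineno)
        try:
            ppm, height = float(tokens[0]), float(tokens[1])
        except ValueError:
            raise ParseError(f"non-numeric token in {line!r}", lineno) from None
        pending.append(Peak(ppm, height))
    flush()
    if not records:
        raise ValidationError(f"{path}: no records found (a library must be non-empty)")
    return ReferenceLibrary(records)


def _load_hmdb_like(directory: Path) -> ReferenceLibrary:
    """Importer for a directory of per-metabolite two-column peak files.

    Each ``*.txt``/``*.csv``/``*.tsv`` file holds "ppm height" rows
    (comma or whitespace separated, blank lines and '#' comments allowed);
    the record id is the file stem.  A ``metadata.tsv`` sidecar with header
    ``id name source mtype ph solvent frequency`` supplies metadata;
    records without a sidecar row get neutral defaults.
    """
    if not directory.is_dir():
        raise ParseError(f"{directory} is not a directory")
    meta: dict[str, dict] = {}
    sidecar = directory / "metadata.tsv"
    if sidecar.exists():
        lines = sidecar.read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ParseError("empty metadata sidecar", 1)
        cols = [c.strip() for c in lines[0].split("\t")]
        for lineno, raw in enumerate(lines[1:], start=2):
            if not raw.strip() or raw.startswith("#"):
                continue
            vals = raw.split("\t")
            if len(vals) != len(cols):
                raise ParseError("metadata row does not match header", lineno)
            row = dict(zip(cols, (v.strip() for v in vals)))
            meta[row["id"]] = row

    records = []
    peak_files = sorted(
        p for p in directory.iterdir()
        if p.suffix in {".txt", ".csv", ".tsv"} and p.name != "metadata.tsv"
    )
    for pf in peak_files:
        peaks: list[Peak] = []
        for lineno, raw in enumerate(pf.read_text(encoding="utf-8").splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < 2:
                raise ParseError(f"{pf.name}: expected 'ppm height', got {line!r}", lineno)
            try:
                peaks.append(Peak(float(tokens[0]), float(tokens[1])))
            except ValueError:
                raise ParseError(f"{pf.name}: non-numeric token in {line!r}", lineno) from None
        if not peaks:
            raise ValidationError(f"{pf.name}: empty peak list")
        row = meta.get(pf.stem, {})
        records.append(
            MetaboliteRecord(
                id=pf.stem,
                name=row.get("name", pf.stem),
                peaks=dedupe_peaks(peaks, warn=True),
                source=row.get("source", "user"),
                mtype=row.get("mtype", "mammalian"),
                ph=float(row.get("ph", 7.0)),
                solvent=row.get("solvent", "water"),
                frequency=float(row.get("frequency", 500.0)),
            )
        )
    if not records:
        raise ValidationError(f"{directory}: no peak files found")
    return ReferenceLibrary(records)
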