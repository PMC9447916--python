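"""Domain model for multi-locus mouse STR genotypes.

An STR (short tandem repeat, microsatellite) allele is named by its repeat
count; microvariant alleles carry a partial repeat written ``<repeats>.<digit>``
(e.g. ``20.3`` = 20 full repeats plus 3 extra bases). A genotype at one marker
is a *set* of distinct alleles: a homozygous locus prints a single value and
counts once, two values mean a heterozygous locus, and three or more distinct
alleles indicate an amplified (multi-allelic) locus. A profile maps the
markers of a typing panel — here the 19-locus CellCheck mouse panel — to
genotypes.

This module provides the value types (:class:`Allele`, :class:`Genotype`,
:class:`MarkerDefinition`, :class:`STRProfile`), token parsing, and the
tabular CSV interchange used by every other stage.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Allele",
    "Genotype",
    "MarkerDefinition",
    "STRProfile",
    "ProfileParseError",
    "PIGTAIL",
    "parse_allele",
    "format_allele",
    "parse_genotype",
    "format_genotype",
    "allele_total",
    "load_profiles",
    "write_profiles",
    "load_panel",
    "normalize_marker_id",
]

#: Fixed 7-nt 5' tag appended to every reverse primer of the panel to promote
#: complete adenylation (consistent +A fragment sizing).
PIGTAIL = "GTTTCTT"

_ALLELE_RE = re.compile(r"^\s*(\d+)(?:\.(\d))?\s*$")

# en/em dashes and minus sign, as they appear in typeset marker labels
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})


class ProfileParseError(ValueError):
    """Raised for malformed allele tokens or profile tables."""


def normalize_marker_id(marker_id: str) -> str:
    """Normalize a marker label to ASCII (``1–1`` → ``1-1``) and strip space."""
    return marker_id.translate(_DASHES).strip()


@dataclass(frozen=True)
class Allele:
    """One STR allele: whole repeat count plus optional single-digit microvariant.

    Ordering is lexicographic on ``(repeats, microvariant)`` with integral
    alleles sorting before microvariants of the same repeat count; this is the
    display order. Equality is exact: ``27 != 27.2 != 26.2``.
    """

    repeats: int
    microvariant: int | None = None

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValueError(f"negative repeat count: {self.repeats}")
        if self.microvariant is not None and not 0 <= self.microvariant <= 9:
            raise ValueError(f"microvariant must be a single digit: {self.microvariant}")

    # None < int fails, so map "no microvariant" to -1 for ordering
    def _sort_key(self) -> tuple[int, int]:
        return (self.repeats, -1 if self.microvariant is None else self.microvariant)

    def __lt__(self, other: "Allele") -> bool:  # type: ignore[override]
        if not isinstance(other, Allele):
            return NotImplemented
        return self._sort_key() < other._sort_key()

    def __le__(self, other: "Allele") -> bool:  # type: ignore[override]
        if not isinstance(other, Allele):
            return NotImplemented
        return self._sort_key() <= other._sort_key()

    def __gt__(self, other: "Allele") -> bool:  # type: ignore[override]
        if not isinstance(other, Allele):
            return NotImplemented
        return self._sort_key() > other._sort_key()

    def __ge__(self, other: "Allele") -> bool:  # type: ignore[override]
        if not isinstance(other, Allele):
            return NotImplemented
        return self._sort_key() >= other._sort_key()

    def __str__(self) -> str:
        if self.microvariant is None:
            return str(self.repeats)
        return f"{self.repeats}.{self.microvariant}"


def parse_allele(token: str) -> Allele:
    """Parse an allele token such as ``"16"`` or ``"20.3"``.

    The microvariant part, when present, must be exactly one digit; anything
    else (empty token, two-digit fraction, non-numeric text) raises
    :class:`ProfileParseError` naming the offending token.
    """
    m = _ALLELE_RE.match(token)
    if m is None:
        raise ProfileParseError(f"malformed allele token: {token!r}")
    repeats = int(m.group(1))
    micro = int(m.group(2)) if m.group(2) is not None else None
    return Allele(repeats, micro)


def format_allele(allele: Allele) -> str:
    """Normalized token for an allele (inverse of :func:`parse_allele`)."""
    return str(allele)


@dataclass(frozen=True)
class Genotype:
    """The set of distinct alleles observed at one marker.

    Set semantics are load-bearing for scoring: a homozygous locus prints one
    value and contributes one allele to profile totals, while a locus with
    three or more distinct alleles (an amplified region) contributes each of
    them.
    """

    alleles: frozenset[Allele] = frozenset()

    @classmethod
    def of(cls, *tokens: str) -> "Genotype":
        return cls(frozenset(parse_allele(t) for t in tokens))

    def __iter__(self) -> Iterator[Allele]:
        return iter(sorted(self.alleles, key=Allele._sort_key))

    def __len__(self) -> int:
        return len(self.alleles)

    def __bool__(self) -> bool:
        return bool(self.alleles)

    def __contains__(self, allele: object) -> bool:
        return allele in self.alleles

    @property
    def is_empty(self) -> bool:
        return not self.alleles

    @property
    def is_multi_allelic(self) -> bool:
        """True when >= 3 distinct alleles are present (amplified locus)."""
        return len(self.alleles) >= 3

    def shared(self, other: "Genotype") -> int:
        return len(self.alleles & other.alleles)

    def __str__(self) -> str:
        return format_genotype(self)


EMPTY_GENOTYPE = Genotype()


def parse_genotype(cell_text: str) -> Genotype:
    """Parse a comma-separated allele cell (``"26.2,27.2"``) into a genotype.

    Empty or whitespace-only text yields the empty genotype (marker not
    typed). Duplicate tokens collapse: ``"17,17"`` is the single-allele
    genotype ``{17}``.
    """
    text = cell_text.strip()
    if not text:
        return EMPTY_GENOTYPE
    return Genotype(frozenset(parse_allele(tok) for tok in text.split(",")))


def format_genotype(genotype: Genotype) -> str:
    """Canonical cell text: alleles ascending, comma-separated; empty → ``""``."""
    return ",".join(str(a) for a in genotype)


@dataclass(frozen=True)
class MarkerDefinition:
    """Panel metadata for one STR marker.

    ``range_min``/``range_max`` bound the repeat counts known to occur at the
    locus; ``pigtail`` is the fixed adenylation tag shared by all reverse
    primers of the panel.
    """

    marker_id: str
    chromosome: str
    range_min: Allele
    range_max: Allele
    forward_primer: str = ""
    reverse_primer: str = ""
    pigtail: str = PIGTAIL

    def __post_init__(self) -> None:
        if self.range_max < self.range_min:
            raise ValueError(
                f"marker {self.marker_id}: range_min {self.range_min} exceeds "
                f"range_max {self.range_max}"
            )

    def contains(self, allele: Allele) -> bool:
        return self.range_min <= allele <= self.range_max

    def integer_repeat_range(self) -> tuple[int, int]:
        """Whole-repeat bounds usable for uniform allele sampling.

        A microvariant lower bound (e.g. 7.1) excludes its own integral
        allele, so the first usable whole repeat is one higher.
        """
        lo = self.range_min.repeats + (0 if self.range_min.microvariant is None else 1)
        return lo, self.range_max.repeats


@dataclass
class STRProfile:
    """A named STR profile: marker id → genotype, with line metadata.

    Markers absent from the mapping are treated exactly like markers mapped
    to an empty genotype — both mean "not typed here".
    """

    name: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    species: str = "Mus musculus"
    accession: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = {
            normalize_marker_id(m): g for m, g in self.genotypes.items()
        }

    def genotype(self, marker_id: str) -> Genotype:
        return self.genotypes.get(normalize_marker_id(marker_id), EMPTY_GENOTYPE)

    def non_empty_markers(self) -> set[str]:
        return {m for m, g in self.genotypes.items() if g}

    def set_genotype(self, marker_id: str, genotype: Genotype) -> None:
        self.genotypes[normalize_marker_id(marker_id)] = genotype


def allele_total(profile: STRProfile, markers: Iterable[str]) -> int:
    """Total distinct-allele count of ``profile`` over the given markers.

    Each marker contributes the size of its genotype set: 1 for a homozygous
    locus, 2 for heterozygous, k for a k-allelic amplified locus, 0 if
    untyped. Additive over disjoint marker sets.
    """
    return sum(len(profile.genotype(m)) for m in markers)


# ---------------------------------------------------------------------------
# CSV interchange
#
# Profile tables use the layout of a published comparison table: one row per
# marker, one column per cell line, allele tokens comma-separated inside the
# cell (hence quoted). UTF-8, LF line endings.
# ---------------------------------------------------------------------------

def _read_rows(path_or_buf) -> list[list[str]]:
    if hasattr(path_or_buf, "read"):
        return [row for row in csv.reader(path_or_buf)]
    with open(path_or_buf, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh)]


def load_profiles(path_or_buf, panel: Sequence[MarkerDefinition] | None = None) -> list[STRProfile]:
    """Read a marker-by-line profile CSV into one :class:`STRProfile` per column.

    The first column holds marker ids; every further column is a cell line.
    Duplicate marker rows are an error. If a ``panel`` is supplied, marker ids
    outside it are kept but flagged with a warning.
    """
    rows = _read_rows(path_or_buf)
    if not rows:
        raise ProfileParseError("empty profile file")
    header = rows[0]
    if len(header) < 1:
        raise ProfileParseError("profile file lacks a header row")
    line_names = [h.strip() for h in header[1:]]
    profiles = [STRProfile(name=n) for n in line_names]

    known = (
        {normalize_marker_id(m.marker_id) for m in panel} if panel is not None else None
    )
    seen: set[str] = set()
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        marker = normalize_marker_id(row[0])
        if marker in seen:
            raise ProfileParseError(f"duplicate marker row: {marker}")
        seen.add(marker)
        if known is not None and marker not in known:
            warnings.warn(f"marker {marker!r} is not in the panel; retained", stacklevel=2)
        cells = list(row[1:]) + [""] * (len(line_names) - (len(row) - 1))
        for profile, cell in zip(profiles, cells):
            try:
                genotype = parse_genotype(cell)
            except ProfileParseError as err:
                raise ProfileParseError(
                    f"marker {marker}, line {profile.name!r}: {err}"
                ) from err
            profile.genotypes[marker] = genotype
    return profiles


def write_profiles(
    profiles: Sequence[STRProfile],
    path_or_buf,
    markers: Sequence[str] | None = None,
) -> None:
    """Write profiles in the marker-by-line CSV dialect read by :func:`load_profiles`.

    Marker rows follow ``markers`` when given, else the union of marker ids in
    first-seen order across profiles.
    """
    if markers is None:
        ordered: list[str] = []
        for p in profiles:
            for m in p.genotypes:
                if m not in ordered:
                    ordered.append(m)
        markers = ordered
    markers = [normalize_marker_id(m) for m in markers]

    def _emit(fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["marker"] + [p.name for p in profiles])
        for m in markers:
            writer.writerow([m] + [format_genotype(p.genotype(m)) for p in profiles])

    if hasattr(path_or_buf, "write"):
        _emit(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="", encoding="utf-8") as fh:
            _emit(fh)


def dumps_profiles(profiles: Sequence[STRProfile], markers: Sequence[str] | None = None) -> str:
    buf = io.StringIO()
    write_profiles(profiles, buf, markers)
    return buf.getvalue()


def load_panel(path_or_buf) -> list[MarkerDefinition]:
    """Read panel metadata CSV: marker,chromosome,range_min,range_max[,fwd,rev]."""
    rows = _read_rows(path_or_buf)
    if not rows:
        raise ProfileParseError("empty panel file")
    header = [h.strip().lower() for h in rows[0]]
    idx = {name: i for i, name in enumerate(header)}
    for required in ("marker", "chromosome", "range_min", "range_max"):
        if required not in idx:
            raise ProfileParseError(f"panel file missing column {required!r}")
    panel = []
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        panel.append(
            MarkerDefinition(
                marker_id=normalize_marker_id(row[idx["marker"]]),
                chromosome=row[idx["chromosome"]].strip(),
                range_min=parse_allele(row[idx["range_min"]]),
                range_max=parse_allele(row[idx["range_max"]]),
                forward_primer=row[idx["fwd_primer"]].strip() if "fwd_primer" in idx else "",
                reverse_primer=row[idx["rev_primer"]].strip() if "rev_primer" in idx else "",
            )
        )
    return panel
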