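"""Threshold-based allele calling from electropherogram peak tables.

Capillary electrophoresis of the multiplex PCR products yields, per marker, a
set of peaks: an allele label (repeat count, pre-binned by the sizing
software) and a height in relative fluorescence units (RFU). A peak is called
as an allele when its height reaches the detection threshold — 100 RFU by
default, with ties at the threshold included. More than two surviving alleles
at a diploid locus is flagged ``multi_allelic`` (amplified region or
contamination); no surviving peaks is flagged ``no_signal``.

Peaks arrive as ``(marker, allele, height)`` triples; raw trace processing,
size-standard calibration and stutter filtering happen upstream in the
instrument software and are out of scope here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .profile_model import (
    Allele,
    Genotype,
    ProfileParseError,
    STRProfile,
    normalize_marker_id,
    parse_allele,
)

__all__ = [
    "Peak",
    "CallingConfig",
    "MarkerCall",
    "QCSummary",
    "call_marker",
    "call_profile",
    "load_peak_table",
    "write_peak_table",
]

FLAG_NO_SIGNAL = "no_signal"
FLAG_MULTI_ALLELIC = "multi_allelic"


@dataclass(frozen=True)
class Peak:
    """One electropherogram peak: marker, binned allele, height in RFU."""

    marker_id: str
    allele: Allele
    height: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak height must be non-negative: {self.height}")
        object.__setattr__(self, "marker_id", normalize_marker_id(self.marker_id))


@dataclass(frozen=True)
class CallingConfig:
    """``rfu_threshold``: minimum peak height called (>= passes); default 100 RFU."""

    rfu_threshold: float = 100.0
    max_alleles_expected: int = 2  # diploid

    def __post_init__(self) -> None:
        if self.rfu_threshold <= 0:
            raise ValueError(f"rfu_threshold must be positive: {self.rfu_threshold}")


@dataclass(frozen=True)
class MarkerCall:
    marker_id: str
    genotype: Genotype
    flags: frozenset[str]
    #: sub-threshold peaks, reported for QC but never called
    subthreshold: tuple[Peak, ...] = ()


@dataclass
class QCSummary:
    no_signal: list[str] = field(default_factory=list)
    multi_allelic: list[str] = field(default_factory=list)
    untyped_panel_markers: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.no_signal or self.multi_allelic or self.untyped_panel_markers)


def call_marker(peaks: Sequence[Peak], config: CallingConfig = CallingConfig()) -> MarkerCall:
    """Call one marker's genotype from its peaks.

    Duplicate allele entries are merged keeping the maximum height before
    thresholding. Calling is invariant to the order of ``peaks``.
    """
    markers = {p.marker_id for p in peaks}
    if len(markers) > 1:
        raise ValueError(f"peaks span multiple markers: {sorted(markers)}")
    marker_id = next(iter(markers)) if markers else ""

    best: dict[Allele, float] = {}
    for p in peaks:
        best[p.allele] = max(best.get(p.allele, 0.0), p.height)

    called = frozenset(a for a, h in best.items() if h >= config.rfu_threshold)
    sub = tuple(
        sorted(
            (Peak(marker_id, a, h) for a, h in best.items() if h < config.rfu_threshold),
            key=lambda p: p.allele._sort_key(),
        )
    )
    flags = set()
    if not called:
        flags.add(FLAG_NO_SIGNAL)
    elif len(called) > config.max_alleles_expected:
        flags.add(FLAG_MULTI_ALLELIC)
    return MarkerCall(marker_id, Genotype(called), frozenset(flags), sub)


def call_profile(
    peak_table: Iterable[Peak],
    config: CallingConfig = CallingConfig(),
    line_name: str = "called",
    panel_markers: Iterable[str] | None = None,
) -> tuple[STRProfile, QCSummary]:
    """Call a full profile from a peak table.

    Peaks are grouped by marker and each marker is called independently.
    When ``panel_markers`` is given, panel markers with no peaks at all are
    listed in the QC summary as untyped.
    """
    by_marker: dict[str, list[Peak]] = {}
    for p in peak_table:
        by_marker.setdefault(p.marker_id, []).append(p)

    profile = STRProfile(name=line_name)
    qc = QCSummary()
    for marker_id in by_marker:
        call = call_marker(by_marker[marker_id], config)
        profile.set_genotype(marker_id, call.genotype)
        if FLAG_NO_SIGNAL in call.flags:
            qc.no_signal.append(marker_id)
        if FLAG_MULTI_ALLELIC in call.flags:
            qc.multi_allelic.append(marker_id)
    if panel_markers is not None:
        qc.untyped_panel_markers = sorted(
            normalize_marker_id(m)
            for m in panel_markers
            if normalize_marker_id(m) not in by_marker
        )
    return profile, qc


# Peak CSV dialect: header `marker,allele,height_rfu`.

def load_peak_table(path_or_buf) -> list[Peak]:
    if hasattr(path_or_buf, "read"):
        rows = list(csv.reader(path_or_buf))
    else:
        with open(path_or_buf, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    if not rows:
        raise ProfileParseError("empty peak table")
    peaks = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or not row[0].strip():
            continue
        if len(row) < 3:
            raise ProfileParseError(f"peak table row {i}: expected marker,allele,height_rfu")
        try:
            peaks.append(Peak(row[0], parse_allele(row[1]), float(row[2])))
        except (ProfileParseError, ValueError) as err:
            raise ProfileParseError(f"peak table row {i}: {err}") from err
    return peaks


def write_peak_table(peaks: Sequence[Peak], path_or_buf) -> None:
    def _emit(fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["marker", "allele", "height_rfu"])
        for p in peaks:
            writer.writerow([p.marker_id, str(p.allele), f"{p.height:g}"])

    if hasattr(path_or_buf, "write"):
        _emit(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="", encoding="utf-8") as fh:
            _emit(fh)
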