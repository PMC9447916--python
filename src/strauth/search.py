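"""Rank a query STR profile against a local reference database.

Mirrors the behaviour of online STR similarity tools: every reference is
scored against the query, then results are filtered by a minimum score and a
minimum number of usable markers, and ranked by score descending. Excluded
references are retained with a reason — in an authentication run the
negative evidence matters as much as the hits.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Sequence

from .profile_model import STRProfile, format_genotype
from .scoring import (
    DegenerateComparisonError,
    MatchConfig,
    MatchResult,
    score_pair,
)

__all__ = ["SearchConfig", "SearchReport", "search", "render_report"]


@dataclass(frozen=True)
class SearchConfig:
    """Search settings. Defaults: Tanabe, non-empty markers, 70% filter, ≥8 markers."""

    match: MatchConfig = MatchConfig()
    score_filter: float = 70.0
    min_markers: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.score_filter <= 100:
            raise ValueError(f"score_filter must be in [0, 100]: {self.score_filter}")
        if self.min_markers < 1:
            raise ValueError(f"min_markers must be >= 1: {self.min_markers}")


@dataclass
class SearchReport:
    query_name: str
    config: SearchConfig
    results: list[MatchResult] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def top_hit(self) -> MatchResult | None:
        return self.results[0] if self.results else None


class QueryTooSparseError(ValueError):
    """Query types fewer markers than the search's min_markers floor."""


def search(
    query: STRProfile,
    database: Sequence[STRProfile],
    config: SearchConfig = SearchConfig(),
) -> SearchReport:
    """Compare ``query`` against every profile in ``database``.

    Retained results satisfy ``score >= score_filter`` and
    ``|markers_used| >= min_markers``; they are sorted by score descending
    with ties broken by reference name ascending (a deterministic stand-in
    for the unspecified ordering of equal scores). Everything else lands in
    ``report.excluded`` with a reason.
    """
    if len(query.non_empty_markers()) < config.min_markers:
        raise QueryTooSparseError(
            f"query {query.name!r} types {len(query.non_empty_markers())} markers; "
            f"min_markers is {config.min_markers}"
        )
    report = SearchReport(query_name=query.name, config=config)
    for reference in database:
        try:
            result = score_pair(query, reference, config.match)
        except DegenerateComparisonError:
            report.excluded.append((reference.name, "no usable markers"))
            continue
        if len(result.markers_used) < config.min_markers:
            report.excluded.append(
                (reference.name, f"only {len(result.markers_used)} usable markers")
            )
        elif result.score_rounded < config.score_filter:
            report.excluded.append((reference.name, "below score filter"))
        else:
            report.results.append(result)
    report.results.sort(key=lambda r: (-r.score_percent, r.reference_name))
    return report


def _report_markers(
    query: STRProfile, references: Sequence[STRProfile]
) -> list[str]:
    ordered: list[str] = []
    for p in (query, *references):
        for m in p.genotypes:
            if m not in ordered and p.genotypes[m]:
                ordered.append(m)
    return ordered


def render_report(
    report: SearchReport,
    fmt: str = "text",
    query: STRProfile | None = None,
    references: Sequence[STRProfile] | None = None,
) -> str:
    """Render a report as a text table or CSV.

    When the underlying profiles are supplied, the text layout mirrors the
    published comparison tables: markers as rows, lines as columns, percent
    scores as a footer row. Without profiles only the score summary is
    rendered.
    """
    if fmt not in ("text", "csv"):
        raise ValueError(f"unknown report format: {fmt!r} (expected 'text' or 'csv')")
    by_name = {}
    if references is not None:
        by_name = {p.name: p for p in references}
    ordered_refs = [
        by_name[r.reference_name] for r in report.results if r.reference_name in by_name
    ]

    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(
            ["reference", "score_percent", "shared", "n_query", "n_reference", "markers_used"]
        )
        for r in report.results:
            writer.writerow(
                [
                    r.reference_name,
                    f"{r.score_rounded:.{r.rounding}f}",
                    r.shared,
                    r.n_query,
                    r.n_reference,
                    len(r.markers_used),
                ]
            )
        for name, reason in report.excluded:
            writer.writerow([name, "", "", "", "", f"excluded: {reason}"])
        return buf.getvalue()

    lines: list[str] = []
    lines.append(f"STR similarity search — query: {report.query_name}")
    lines.append(
        f"algorithm={report.config.match.algorithm.value} "
        f"mode={report.config.match.marker_mode.value} "
        f"score_filter={report.config.score_filter:g}% "
        f"min_markers={report.config.min_markers}"
    )
    lines.append("")
    if query is not None and ordered_refs:
        markers = _report_markers(query, ordered_refs)
        header = ["marker", query.name] + [p.name for p in ordered_refs]
        rows = [
            [m, format_genotype(query.genotype(m))]
            + [format_genotype(p.genotype(m)) for p in ordered_refs]
            for m in markers
        ]
        footer = ["% match", ""] + [
            f"{r.score_rounded:.{r.rounding}f}"
            for r in report.results
            if r.reference_name in by_name
        ]
        widths = [
            max(len(str(row[i])) for row in [header, *rows, footer])
            for i in range(len(header))
        ]
        for row in [header, *rows, footer]:
            lines.append("  ".join(str(c).ljust(w) for c, w in zip(row, widths)).rstrip())
    else:
        if report.results:
            lines.append(f"{'reference':30s}  {'score':>7s}  shared  markers")
            for r in report.results:
                lines.append(
                    f"{r.reference_name:30s}  {r.score_rounded:6.{r.rounding}f}%  "
                    f"{r.shared:6d}  {len(r.markers_used):7d}"
                )
        else:
            lines.append("no matches passed the filters")
    if report.excluded:
        lines.append("")
        lines.append("excluded:")
        for name, reason in report.excluded:
            lines.append(f"  {name}: {reason}")
    return "\n".join(lines) + "\n"
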