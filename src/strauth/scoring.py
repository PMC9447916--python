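"""Pairwise STR profile comparison statistics.

Two families of percent-match scores are standard in cell-line
authentication. With ``s`` the number of alleles shared between a query and a
reference over a chosen marker set, and ``n_q`` / ``n_r`` the total distinct
alleles of each profile over that set:

* Tanabe:  ``100 * 2s / (n_q + n_r)`` — symmetric,
* Masters (vs. query):     ``100 * s / n_q``,
* Masters (vs. reference): ``100 * s / n_r``.

Alleles are compared as exact set elements per marker; a microvariant allele
(e.g. 27.2) never matches the neighbouring integral allele (27). The default
configuration mirrors the standard database-search setting: Tanabe over the
markers that are non-empty in *both* profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable

from .profile_model import STRProfile, allele_total

__all__ = [
    "Algorithm",
    "MarkerMode",
    "MatchConfig",
    "MatchResult",
    "DegenerateComparisonError",
    "select_markers",
    "shared_allele_count",
    "tanabe_score",
    "masters_score",
    "score_pair",
    "round_half_up",
]


class Algorithm(str, Enum):
    TANABE = "tanabe"
    MASTERS_VS_QUERY = "masters_vs_query"
    MASTERS_VS_REFERENCE = "masters_vs_reference"


class MarkerMode(str, Enum):
    #: markers with at least one allele in both profiles (the default)
    NON_EMPTY_BOTH = "non_empty_both"
    #: markers non-empty in the query, regardless of the reference
    QUERY_MARKERS = "query_markers"
    #: every marker typed in either profile
    ALL_PANEL = "all_panel"


class DegenerateComparisonError(ValueError):
    """Raised when a comparison has no usable markers.

    Deliberately distinct from a 0% score: a zero would read as strong
    evidence of non-identity, whereas no overlapping typed markers is no
    evidence at all.
    """


@dataclass(frozen=True)
class MatchConfig:
    """Scoring settings; the defaults are the conventional search settings."""

    algorithm: Algorithm = Algorithm.TANABE
    marker_mode: MarkerMode = MarkerMode.NON_EMPTY_BOTH
    rounding: int = 2


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one pairwise comparison.

    ``score_percent`` is the full-precision value; ``score_rounded`` applies
    half-up rounding to the configured number of decimals, matching how
    scores are conventionally printed (e.g. 82.93).
    """

    query_name: str
    reference_name: str
    shared: int
    n_query: int
    n_reference: int
    markers_used: frozenset[str]
    algorithm: Algorithm
    score_percent: float
    rounding: int = 2

    @property
    def score_rounded(self) -> float:
        return round_half_up(self.score_percent, self.rounding)

    def __str__(self) -> str:
        return (
            f"{self.query_name} vs {self.reference_name}: "
            f"{self.score_rounded:.{self.rounding}f}% "
            f"({self.shared} shared / {self.n_query}+{self.n_reference} alleles, "
            f"{len(self.markers_used)} markers, {self.algorithm.value})"
        )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention for printed scores)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def select_markers(
    query: STRProfile, reference: STRProfile, mode: MarkerMode = MarkerMode.NON_EMPTY_BOTH
) -> set[str]:
    """Marker ids over which the two profiles are compared, per ``mode``."""
    if mode is MarkerMode.NON_EMPTY_BOTH:
        return query.non_empty_markers() & reference.non_empty_markers()
    if mode is MarkerMode.QUERY_MARKERS:
        return query.non_empty_markers()
    if mode is MarkerMode.ALL_PANEL:
        return set(query.genotypes) | set(reference.genotypes)
    raise ValueError(f"unknown marker mode: {mode!r}")


def shared_allele_count(
    query: STRProfile, reference: STRProfile, markers: Iterable[str]
) -> int:
    """Number of alleles shared per marker, summed: Σ |Q_m ∩ R_m|."""
    return sum(
        query.genotype(m).shared(reference.genotype(m)) for m in markers
    )


def _build_result(
    query: STRProfile,
    reference: STRProfile,
    config: MatchConfig,
    algorithm: Algorithm,
) -> MatchResult:
    markers = select_markers(query, reference, config.marker_mode)
    if not markers:
        raise DegenerateComparisonError(
            f"no usable markers between {query.name!r} and {reference.name!r} "
            f"(mode {config.marker_mode.value})"
        )
    shared = shared_allele_count(query, reference, markers)
    n_q = allele_total(query, markers)
    n_r = allele_total(reference, markers)
    if algorithm is Algorithm.TANABE:
        score = 100.0 * 2.0 * shared / (n_q + n_r)
    elif algorithm is Algorithm.MASTERS_VS_QUERY:
        if n_q == 0:
            raise DegenerateComparisonError(f"query {query.name!r} has no alleles")
        score = 100.0 * shared / n_q
    elif algorithm is Algorithm.MASTERS_VS_REFERENCE:
        if n_r == 0:
            raise DegenerateComparisonError(f"reference {reference.name!r} has no alleles")
        score = 100.0 * shared / n_r
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return MatchResult(
        query_name=query.name,
        reference_name=reference.name,
        shared=shared,
        n_query=n_q,
        n_reference=n_r,
        markers_used=frozenset(markers),
        algorithm=algorithm,
        score_percent=score,
        rounding=config.rounding,
    )


def tanabe_score(
    query: STRProfile, reference: STRProfile, config: MatchConfig = MatchConfig()
) -> MatchResult:
    """Symmetric percent match ``200·s/(n_q+n_r)`` over the configured markers."""
    return _build_result(query, reference, config, Algorithm.TANABE)


def masters_score(
    query: STRProfile,
    reference: STRProfile,
    config: MatchConfig = MatchConfig(algorithm=Algorithm.MASTERS_VS_QUERY),
) -> MatchResult:
    """Masters percent match, normalized by query or reference allele total."""
    algorithm = config.algorithm
    if algorithm is Algorithm.TANABE:
        algorithm = Algorithm.MASTERS_VS_QUERY
    return _build_result(query, reference, config, algorithm)


def score_pair(
    query: STRProfile, reference: STRProfile, config: MatchConfig = MatchConfig()
) -> MatchResult:
    """Dispatch on ``config.algorithm``."""
    return _build_result(query, reference, config, config.algorithm)
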