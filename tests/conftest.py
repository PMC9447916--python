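"""Shared fixtures and the independent brute-force scoring oracle.

The oracle works on plain ``dict[marker] -> set[token]`` structures and never
touches the package's scoring path, so agreement between the two is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import pytest

from strauth import (
    STRProfile,
    load_colgfp_profile,
    load_reference_panel,
    load_similarity_profiles,
)

# ---------------------------------------------------------------------------
# brute-force oracle: literal per-marker set intersection over token strings
# ---------------------------------------------------------------------------


def as_token_sets(profile: STRProfile) -> dict[str, set[str]]:
    return {
        marker: {str(a) for a in genotype}
        for marker, genotype in profile.genotypes.items()
    }


def brute_force_tanabe(
    query: dict[str, set[str]], reference: dict[str, set[str]]
) -> tuple[float, int, int, int]:
    """(score, shared, n_query, n_reference) over markers non-empty in both."""
    markers = {m for m, s in query.items() if s} & {
        m for m, s in reference.items() if s
    }
    shared = sum(len(query[m] & reference[m]) for m in markers)
    n_q = sum(len(query[m]) for m in markers)
    n_r = sum(len(reference[m]) for m in markers)
    return 100.0 * 2.0 * shared / (n_q + n_r), shared, n_q, n_r


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def colgfp():
    return load_colgfp_profile()


@pytest.fixture(scope="session")
def similarity_profiles():
    return load_similarity_profiles()


@pytest.fixture(scope="session")
def table_query(similarity_profiles):
    """The query column of the packaged comparison table (18 markers)."""
    return similarity_profiles[0]


@pytest.fixture(scope="session")
def table_references(similarity_profiles):
    return similarity_profiles[1:]
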