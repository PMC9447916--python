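"""Tanabe/Masters scoring: worked examples, oracle equivalence, properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strauth import (
    Algorithm,
    DegenerateComparisonError,
    MarkerMode,
    MatchConfig,
    STRProfile,
    SimConfig,
    generate_profile,
    masters_score,
    parse_genotype,
    select_markers,
    shared_allele_count,
    tanabe_score,
)
from strauth.scoring import round_half_up

from conftest import as_token_sets, brute_force_tanabe


def _profile(name, **genotypes):
    return STRProfile(
        name=name, genotypes={m: parse_genotype(g) for m, g in genotypes.items()}
    )


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------


def test_select_markers_non_empty_both_excludes_half_typed(colgfp, table_references):
    at3 = next(p for p in table_references if p.name == "AT-3")
    markers = select_markers(colgfp, at3, MarkerMode.NON_EMPTY_BOTH)
    assert len(markers) == 18
    assert "9-2" not in markers  # typed in the query only


def test_select_markers_modes(colgfp, table_references):
    at3 = next(p for p in table_references if p.name == "AT-3")
    assert select_markers(colgfp, colgfp) == colgfp.non_empty_markers()
    assert select_markers(colgfp, at3, MarkerMode.QUERY_MARKERS) == colgfp.non_empty_markers()
    assert "9-2" in select_markers(colgfp, at3, MarkerMode.ALL_PANEL)


def test_select_markers_disjoint_profiles():
    a = _profile("a", **{"1-1": "16"})
    b = _profile("b", **{"2-1": "15"})
    assert select_markers(a, b) == set()


# ---------------------------------------------------------------------------
# worked examples frozen from the packaged comparison table
# ---------------------------------------------------------------------------


def test_shared_allele_counts(table_query, table_references):
    by_name = {p.name: p for p in table_references}
    markers = select_markers(table_query, by_name["AT-3"])
    assert shared_allele_count(table_query, by_name["AT-3"], markers) == 17
    assert shared_allele_count(table_query, by_name["MLTC-1"], markers) == 15
    assert (
        shared_allele_count(table_query, table_query, markers)
        == sum(len(table_query.genotype(m)) for m in markers)
        == 20
    )


@pytest.mark.parametrize(
    "reference,expected",
    [
        ("AT-3", 82.93),
        ("YUMMER1.7-H2B-GFP5", 80.00),
        ("MS1", 78.05),
        ("YUMM1.7", 76.92),
        ("MCA-205", 76.19),
        ("MLTC-1", 73.17),
    ],
)
def test_tanabe_reproduces_published_scores(table_query, table_references, reference, expected):
    by_name = {p.name: p for p in table_references}
    result = tanabe_score(table_query, by_name[reference])
    assert result.score_rounded == pytest.approx(expected, abs=1e-9)


def test_masters_variants_on_at3(table_query, table_references):
    at3 = next(p for p in table_references if p.name == "AT-3")
    vs_q = masters_score(table_query, at3, MatchConfig(algorithm=Algorithm.MASTERS_VS_QUERY))
    vs_r = masters_score(table_query, at3, MatchConfig(algorithm=Algorithm.MASTERS_VS_REFERENCE))
    assert vs_q.score_rounded == 85.00  # 17/20
    assert vs_r.score_rounded == 80.95  # 17/21


def test_identity_and_disjoint_scores(table_query):
    assert tanabe_score(table_query, table_query).score_percent == 100.0
    a = _profile("a", **{"1-1": "16", "2-1": "15"})
    b = _profile("b", **{"1-1": "17", "2-1": "14"})
    assert tanabe_score(a, b).score_percent == 0.0


def test_zero_usable_markers_is_an_error_not_zero():
    a = _profile("a", **{"1-1": "16"})
    b = _profile("b", **{"2-1": "15"})
    with pytest.raises(DegenerateComparisonError):
        tanabe_score(a, b)


def test_microvariant_never_matches_integral_neighbour():
    a = _profile("a", **{"7-1": "27"})
    b = _profile("b", **{"7-1": "26.2,27.2"})
    assert tanabe_score(a, b).shared == 0


def test_round_half_up_matches_printed_convention():
    assert round_half_up(82.92682926829268) == 82.93
    assert round_half_up(76.92307692307692) == 76.92
    assert round_half_up(78.04878048780488) == 78.05
    assert round_half_up(2.675) == 2.68  # binary-float trap for bankers' rounding


# ---------------------------------------------------------------------------
# oracle equivalence and algebraic properties on synthetic profiles
# ---------------------------------------------------------------------------


def test_oracle_equivalence_on_many_random_pairs(panel):
    """Scoring path equals literal per-marker set intersection, 200+ pairs."""
    for seed in range(220):
        a = generate_profile(panel, SimConfig(seed=seed, het_prob=0.5), name="a")
        b = generate_profile(panel, SimConfig(seed=10_000 + seed, het_prob=0.5), name="b")
        expected, shared, n_q, n_r = brute_force_tanabe(as_token_sets(a), as_token_sets(b))
        result = tanabe_score(a, b)
        assert result.score_percent == expected  # identical arithmetic, no tolerance
        assert (result.shared, result.n_query, result.n_reference) == (shared, n_q, n_r)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(sa=st.integers(0, 2**20), sb=st.integers(0, 2**20), het=st.floats(0, 1))
def test_scoring_properties(panel, sa, sb, het):
    """Symmetry, Masters duality, bounds, and the 100% iff exact-agreement law."""
    a = generate_profile(panel, SimConfig(seed=sa, het_prob=het), name="a")
    b = generate_profile(panel, SimConfig(seed=sb, het_prob=het), name="b")
    t_ab, t_ba = tanabe_score(a, b), tanabe_score(b, a)
    assert t_ab.score_percent == t_ba.score_percent
    mq = masters_score(a, b, MatchConfig(algorithm=Algorithm.MASTERS_VS_QUERY))
    mr = masters_score(b, a, MatchConfig(algorithm=Algorithm.MASTERS_VS_REFERENCE))
    assert mq.score_percent == mr.score_percent
    assert 0.0 <= t_ab.score_percent <= 100.0
    assert t_ab.shared <= min(t_ab.n_query, t_ab.n_reference)
    agree = all(
        a.genotype(m) == b.genotype(m) for m in t_ab.markers_used
    )
    assert (t_ab.score_percent == 100.0) == agree
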