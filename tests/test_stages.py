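"""Stage series construction and the interval calculus."""

import itertools

import pytest
from hypothesis import given, strategies as st

import devonto as d
from devonto.errors import (
    IncompleteStagesError,
    InvertedIntervalError,
    StageSeriesError,
    SuperStageFillerError,
    TermNotFoundError,
)
from devonto.fixtures import STANDARD_STAGES, UNKNOWN_STAGE, stage_id
from devonto.model import Ontology, OntologyTerm, Predicate, Relationship, \
    TermID
from devonto.stages import StageInterval, TemporalRelation


def ordinal(series, name):
    return series.ordinal(stage_id(name))


# -- series construction ---------------------------------------------------

def test_immediately_preceded_by_orders_stages(series):
    assert ordinal(series, "High-pec") == ordinal(series, "Prim-25") + 1
    assert [series.name_of(i) for i in range(3)] == \
        ["Prim-5", "Prim-15", "Prim-25"]


def test_single_stage_ontology():
    onto = Ontology()
    onto.add_term(OntologyTerm(id=TermID("TSTG", "0000001"), name="stage 1"))
    series = d.build_stage_series(onto)
    assert len(series) == 1


def _chain_ontology(n):
    onto = Ontology()
    ids = [TermID("TSTG", f"{i + 1:07d}") for i in range(n)]
    for i, t in enumerate(ids):
        onto.add_term(OntologyTerm(id=t, name=f"stage {i + 1}"))
    for a, b in zip(ids, ids[1:]):
        onto.add_relationship(Relationship(
            b, Predicate.IMMEDIATELY_PRECEDED_BY, a))
    return onto, ids


def test_cycle_detected():
    onto, ids = _chain_ontology(3)
    onto.add_relationship(Relationship(
        ids[0], Predicate.IMMEDIATELY_PRECEDED_BY, ids[2]))
    with pytest.raises(StageSeriesError):
        d.build_stage_series(onto)


def test_branching_chain_detected():
    onto, ids = _chain_ontology(3)
    extra = TermID("TSTG", "0000009")
    onto.add_term(OntologyTerm(id=extra, name="rogue stage"))
    onto.add_relationship(Relationship(
        extra, Predicate.IMMEDIATELY_PRECEDED_BY, ids[0]))
    with pytest.raises(StageSeriesError, match="two successors"):
        d.build_stage_series(onto)


def test_disconnected_fragments_detected():
    onto, ids = _chain_ontology(3)
    for t in (TermID("TSTG", "0000008"), TermID("TSTG", "0000009")):
        onto.add_term(OntologyTerm(id=t, name=f"stray {t.local}"))
    onto.add_relationship(Relationship(
        TermID("TSTG", "0000009"), Predicate.IMMEDIATELY_PRECEDED_BY,
        TermID("TSTG", "0000008")))
    with pytest.raises(StageSeriesError):
        d.build_stage_series(onto)


def test_non_contiguous_super_stage_detected():
    onto, ids = _chain_ontology(4)
    sup = TermID("TSTG", "0000100")
    onto.add_term(OntologyTerm(id=sup, name="gappy period"))
    onto.add_relationship(Relationship(ids[0], Predicate.PART_OF, sup))
    onto.add_relationship(Relationship(ids[2], Predicate.PART_OF, sup))
    with pytest.raises(StageSeriesError, match="contiguous"):
        d.build_stage_series(onto)


def test_series_round_trips_through_obo(heart):
    text = d.write_obo(heart.stages)
    series2 = d.build_stage_series(d.parse_obo(text))
    assert series2.leaves == heart.series().leaves


# -- interval extraction ---------------------------------------------------

def test_heart_interval(heart, series):
    iv = d.interval_of(heart.anatomy, series,
                       TermID.parse("ZFA:0000114"))
    assert iv == StageInterval(ordinal(series, "High-pec"),
                               ordinal(series, "Adult"))


def test_unknown_start_maps_to_absent_side(heart, series):
    t = TermID("TEST", "0000050")
    heart.anatomy.add_term(OntologyTerm(id=t, name="vague structure"))
    heart.anatomy.add_relationship(
        Relationship(t, Predicate.START_STAGE, UNKNOWN_STAGE))
    heart.anatomy.add_relationship(
        Relationship(t, Predicate.END_STAGE, stage_id("Prim-25")))
    iv = d.interval_of(heart.anatomy, series, t)
    assert iv.start is None
    assert iv.end == ordinal(series, "Prim-25")


def test_double_unknown_is_error(heart, series):
    t = TermID("TEST", "0000050")
    heart.anatomy.add_term(OntologyTerm(id=t, name="ghost structure"))
    for pred in (Predicate.START_STAGE, Predicate.END_STAGE):
        heart.anatomy.add_relationship(Relationship(t, pred, UNKNOWN_STAGE))
    with pytest.raises(IncompleteStagesError):
        d.interval_of(heart.anatomy, series, t)


def test_super_stage_filler_is_error(heart, series):
    t = TermID("TEST", "0000050")
    pharyngula = TermID("TSTG", "0000011")
    heart.anatomy.add_term(OntologyTerm(id=t, name="sloppy structure"))
    heart.anatomy.add_relationship(
        Relationship(t, Predicate.START_STAGE, pharyngula))
    with pytest.raises(SuperStageFillerError):
        d.interval_of(heart.anatomy, series, t)


def test_inverted_interval_is_error(heart, series):
    d.set_stage(heart.anatomy, TermID.parse("ZFA:0000114"), "end",
                stage_id("Prim-5"))
    with pytest.raises(InvertedIntervalError):
        d.interval_of(heart.anatomy, series, TermID.parse("ZFA:0000114"))


# -- contains / junction ---------------------------------------------------

def test_contains_named_examples(series):
    o = lambda name: ordinal(series, name)
    outer = StageInterval(o("Prim-5"), o("Adult"))
    inner = StageInterval(o("High-pec"), o("Day 5"))
    assert d.contains(outer, inner)
    assert d.contains(inner, inner)  # reflexive
    assert not d.contains(StageInterval(o("High-pec"), o("Adult")),
                          StageInterval(o("Prim-5"), o("Adult")))


def test_contains_unknown_sides_are_permissive():
    assert d.contains(StageInterval(None, 5), StageInterval(0, 5))
    assert d.contains(StageInterval(2, 5), StageInterval(None, 5))
    assert not d.contains(StageInterval(2, 5), StageInterval(1, None))


def test_junction_named_examples(series):
    o = lambda name: ordinal(series, name)
    # primitive heart tube ends Prim-5, heart tube starts Prim-5
    assert d.junction(StageInterval(o("Prim-5"), o("Prim-5")),
                      StageInterval(o("Prim-5"), o("Prim-25"))) is \
        TemporalRelation.OVERLAPPING
    # heart tube ends Prim-25, heart starts High-pec
    assert d.junction(StageInterval(o("Prim-5"), o("Prim-25")),
                      StageInterval(o("High-pec"), o("Adult"))) is \
        TemporalRelation.ABUTTING
    # ends Prim-5, starts Protruding-mouth: two stages skipped
    assert d.junction(StageInterval(o("Prim-5"), o("Prim-5")),
                      StageInterval(o("Protruding-mouth"), o("Adult"))) is \
        TemporalRelation.GAP


def oracle_junction(pred_end, succ_start):
    """Brute-force ordinal comparison, written independently."""
    if pred_end is None or succ_start is None:
        return "UNDETERMINED"
    diff = succ_start - pred_end
    if diff < 0:
        return "PREMATURE"
    if diff == 0:
        return "OVERLAPPING"
    if diff == 1:
        return "ABUTTING"
    return "GAP"


def all_intervals(n, with_unknown=True):
    sides = list(range(n)) + ([None] if with_unknown else [])
    for s, e in itertools.product(sides, sides):
        if s is None and e is None:
            continue
        if s is not None and e is not None and s > e:
            continue
        yield StageInterval(s, e)


def test_junction_exhaustive_against_oracle_six_stage_series():
    pairs = 0
    for a, b in itertools.product(all_intervals(6), repeat=2):
        got = d.junction(a, b)
        assert got.value == oracle_junction(a.end, b.start)
        pairs += 1
    assert pairs == 33 ** 2  # every ordered pair, exactly one relation each


def oracle_contains(outer, inner):
    lo = -10 if outer.start is None else outer.start
    hi = 10 if outer.end is None else outer.end
    s = lo if inner.start is None else inner.start
    e = hi if inner.end is None else inner.end
    return lo <= s and e <= hi


def test_contains_agrees_with_bounds_oracle():
    for a, b in itertools.product(all_intervals(6), repeat=2):
        assert d.contains(a, b) == oracle_contains(a, b)


known_interval = st.tuples(st.integers(0, 5), st.integers(0, 5)).map(
    lambda p: StageInterval(min(p), max(p)))


@given(known_interval, known_interval, known_interval)
def test_contains_is_partial_order(a, b, c):
    assert d.contains(a, a)
    if d.contains(a, b) and d.contains(b, a):
        assert a == b
    if d.contains(a, b) and d.contains(b, c):
        assert d.contains(a, c)


def test_interval_invariants_enforced():
    with pytest.raises(IncompleteStagesError):
        StageInterval(None, None)
    with pytest.raises(InvertedIntervalError):
        StageInterval(3, 1)


# -- super-stage expansion -------------------------------------------------

def test_expand_pharyngula_super_stage(series):
    leaves = d.expand_super_stage(series, TermID("TSTG", "0000011"))
    assert [series.names[t] for t in leaves] == \
        ["Prim-5", "Prim-15", "Prim-25", "High-pec"]


def test_expand_leaf_is_singleton(series):
    assert d.expand_super_stage(series, stage_id("Prim-5")) == \
        [stage_id("Prim-5")]


def test_expand_unknown_sentinel_spans_whole_series(series):
    assert d.expand_super_stage(series, UNKNOWN_STAGE) == list(series.leaves)


def test_expand_unknown_id_raises(series):
    with pytest.raises(TermNotFoundError):
        d.expand_super_stage(series, TermID("TSTG", "9999999"))
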