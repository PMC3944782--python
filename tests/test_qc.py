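"""Release-gate consistency checks and report aggregation."""

import pytest

import devonto as d
from devonto.fixtures import HEART, HEART_TUBE, stage_id
from devonto.model import OntologyTerm, Predicate, Relationship, TermID
from devonto.qc import Rule, Severity, ValidationConfig


def rules_of(violations):
    return [(v.rule_id.value, v.subject.curie) for v in violations]


# -- containment checks ----------------------------------------------------

def test_heart_hierarchies_are_stage_consistent(heart, series):
    assert d.check_subclass_stages(heart.anatomy, series) == []
    assert d.check_partonomy_stages(heart.anatomy, series) == []


def test_child_equal_to_parent_window_passes(heart, series):
    # 'cavitated compound organ' spans the same window as its parent
    assert d.check_subclass_stages(heart.anatomy, series) == []


def test_child_starting_before_parent_flagged_once(heart, series):
    # heart is_a cavitated compound organ (Prim-5..Adult): push heart's
    # start two stages before the parent's
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Prim-5"))
    d.set_stage(heart.anatomy,
                TermID.parse("TEST:0000002"), "start", stage_id("Prim-25"))
    out = d.check_subclass_stages(heart.anatomy, series)
    assert rules_of(out) == [("SUB-STAGE", "ZFA:0000114")]
    assert TermID.parse("TEST:0000002") in out[0].related
    assert "Prim-25" in out[0].message  # stages named by name, not ordinal


def test_part_ending_after_whole_flagged(heart, series):
    d.set_stage(heart.anatomy,
                TermID.parse("TEST:0000003"), "end", stage_id("Juvenile"))
    out = d.check_partonomy_stages(heart.anatomy, series)
    assert rules_of(out) == [("PART-STAGE", "ZFA:0000114")]


def test_part_with_unknown_start_is_unprovable(heart, series):
    from devonto.fixtures import UNKNOWN_STAGE
    d.set_stage(heart.anatomy, HEART, "start", UNKNOWN_STAGE)
    d.set_stage(heart.anatomy,
                TermID.parse("TEST:0000003"), "start", stage_id("Prim-25"))
    assert d.check_partonomy_stages(heart.anatomy, series) == []


# -- develops_from ---------------------------------------------------------

def test_heart_chain_junctions_all_legal(heart, series):
    assert d.check_develops_from(heart.anatomy, series) == []


def test_gap_junction_flagged(heart, series):
    # heart tube still ends Prim-25; heart start pushed to Protruding-mouth
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Protruding-mouth"))
    out = d.check_develops_from(heart.anatomy, series)
    assert rules_of(out) == [("DF-JUNCTION", "ZFA:0000114")]
    assert "GAP" in out[0].message


def test_premature_junction_flagged(heart, series):
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Prim-15"))
    out = d.check_develops_from(heart.anatomy, series)
    assert rules_of(out) == [("DF-JUNCTION", "ZFA:0000114")]
    assert "PREMATURE" in out[0].message


def test_unknown_successor_start_is_undetermined(heart, series):
    from devonto.fixtures import UNKNOWN_STAGE
    d.set_stage(heart.anatomy, HEART, "start", UNKNOWN_STAGE)
    assert d.check_develops_from(heart.anatomy, series) == []


def test_premature_downgrade_switch(heart, series):
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Prim-15"))
    config = ValidationConfig(premature_is_warning=True)
    out = d.check_develops_from(heart.anatomy, series, config)
    assert out[0].severity is Severity.WARNING
    report = d.validate(heart.anatomy, heart.stages, config)
    assert report.passed  # downgraded finding no longer blocks release


# -- completeness ----------------------------------------------------------

def test_double_unknown_term_flagged(heart, series):
    from devonto.fixtures import UNKNOWN_STAGE
    d.set_stage(heart.anatomy, HEART_TUBE, "start", UNKNOWN_STAGE)
    d.set_stage(heart.anatomy, HEART_TUBE, "end", UNKNOWN_STAGE)
    out = d.check_stage_completeness(heart.anatomy, series)
    assert rules_of(out) == [("STAGE-COMPLETE", "ZFA:0000360")]


def test_missing_stage_relations_flagged(heart, series):
    t = TermID("TEST", "0000050")
    heart.anatomy.add_term(OntologyTerm(
        id=t, name="stageless structure",
        definition=d.Definition("Structure with no stage relations.")))
    out = d.check_stage_completeness(heart.anatomy, series)
    assert rules_of(out) == [("STAGE-COMPLETE", "TEST:0000050")]


def test_super_stage_filler_flagged(heart, series):
    d.set_stage(heart.anatomy, HEART, "start", TermID("TSTG", "0000011"))
    out = d.check_stage_completeness(heart.anatomy, series)
    assert rules_of(out) == [("STAGE-LEAF", "ZFA:0000114")]


def test_fully_specified_fixture_has_no_completeness_findings(heart, series):
    assert d.check_stage_completeness(heart.anatomy, series) == []


# -- metadata policy -------------------------------------------------------

def test_obsolete_term_with_surviving_edge_is_error(heart):
    t = TermID("ZFA", "0000990")
    heart.anatomy.add_term(OntologyTerm(id=t, name="old pericardium",
                                        is_obsolete=True))
    heart.anatomy.add_relationship(Relationship(
        t, Predicate.PART_OF, TermID.parse("TEST:0000003")))
    out = d.check_metadata_policy(heart.anatomy)
    assert ("META-OBS", "ZFA:0000990") in rules_of(out)
    assert all(v.severity is Severity.ERROR for v in out
               if v.rule_id is Rule.META_OBS)


def test_fully_defined_fixture_yields_no_definition_warnings(heart):
    assert [v for v in d.check_metadata_policy(heart.anatomy)
            if v.rule_id is Rule.META_DEF] == []


def test_undefined_terms_counted_exactly():
    onto = d.Ontology()
    for i in range(10):
        defn = d.Definition("Defined.") if i >= 3 else None
        onto.add_term(OntologyTerm(id=TermID("TEST", f"{i + 1:07d}"),
                                   name=f"structure {i + 1}",
                                   definition=defn))
    out = [v for v in d.check_metadata_policy(onto)
           if v.rule_id is Rule.META_DEF]
    assert len(out) == 3


def test_plural_looking_name_warned_unless_plural_synonym():
    onto = d.Ontology()
    onto.add_term(OntologyTerm(id=TermID("TEST", "0000001"),
                               name="somites",
                               definition=d.Definition("Segments.")))
    out = d.check_metadata_policy(onto)
    assert [v.rule_id for v in out] == [Rule.META_SINGULAR]
    assert out[0].severity is Severity.WARNING


def test_replaced_by_pointing_at_obsolete_term_is_error(heart):
    a, b = TermID("ZFA", "0000991"), TermID("ZFA", "0000992")
    heart.anatomy.add_term(OntologyTerm(id=a, name="gone", is_obsolete=True,
                                        replaced_by=b))
    heart.anatomy.add_term(OntologyTerm(id=b, name="also gone",
                                        is_obsolete=True))
    out = d.check_metadata_policy(heart.anatomy)
    assert ("META-OBS", "ZFA:0000991") in rules_of(out)


# -- validate aggregation --------------------------------------------------

def test_heart_fixture_passes_with_zero_violations(heart):
    report = d.validate(heart.anatomy, heart.stages)
    assert report.passed
    assert report.violations == []


def test_empty_anatomy_passes(heart):
    report = d.validate(d.Ontology(), heart.stages)
    assert report.passed
    assert report.violations == []


def test_counts_match_injection_manifest():
    bundle = d.generate_valid(d.GeneratorParams(seed=7))
    spec = {"SUB-STAGE": 1, "PART-STAGE": 1, "DF-JUNCTION": 2}
    mutated = d.inject_violations(bundle, spec, seed=7)
    report = d.validate(mutated.anatomy, mutated.stages)
    got = {(v.rule_id.value, v.subject)
           for v in report.violations if v.severity is Severity.ERROR}
    assert got == set(mutated.manifest)
    assert sum(report.counts.values()) == len(report.violations)


def test_reports_are_deterministic():
    bundle = d.inject_violations(
        d.generate_valid(d.GeneratorParams(seed=3)),
        {"SUB-STAGE": 1, "STAGE-COMPLETE": 1}, seed=3)
    r1 = d.validate(bundle.anatomy, bundle.stages)
    r2 = d.validate(bundle.anatomy, bundle.stages)
    assert r1.to_json() == r2.to_json()
    assert r1.to_tsv() == r2.to_tsv()


def test_adding_violation_preserves_existing_ones(heart):
    # monotonicity: a new bad edge never hides an earlier finding
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Protruding-mouth"))
    before = rules_of(d.validate(heart.anatomy, heart.stages).violations)
    d.set_stage(heart.anatomy,
                TermID.parse("TEST:0000003"), "start", stage_id("Juvenile"))
    after = rules_of(d.validate(heart.anatomy, heart.stages).violations)
    assert set(before) <= set(after)
    assert len(after) > len(before)


def test_severity_override_via_yaml_config(heart):
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Protruding-mouth"))
    config = ValidationConfig.from_yaml(
        "severity:\n  DF-JUNCTION: WARNING\n")
    report = d.validate(heart.anatomy, heart.stages, config)
    assert report.passed
    assert report.counts == {"DF-JUNCTION": 1}


def test_ignore_list_suppresses_subject(heart):
    d.set_stage(heart.anatomy, HEART, "start", stage_id("Protruding-mouth"))
    config = ValidationConfig.from_yaml(
        "ignore:\n  DF-JUNCTION: [ZFA:0000114]\n")
    report = d.validate(heart.anatomy, heart.stages, config)
    assert report.passed
    assert report.violations == []


def test_series_build_failure_aborts(heart):
    from devonto.errors import StageSeriesError
    stages = heart.stages
    stages.add_term(OntologyTerm(id=TermID("TSTG", "0000999"),
                                 name="rogue stage"))
    stages.add_relationship(Relationship(
        TermID("TSTG", "0000999"), Predicate.IMMEDIATELY_PRECEDED_BY,
        stage_id("Prim-5")))
    with pytest.raises(StageSeriesError):
        d.validate(heart.anatomy, stages)
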