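"""Annotation records: tabular I/O, the expression stage check, rendering."""

import random

import pytest

import devonto as d
from devonto.annotations import (
    ExpressionAnnotation,
    PhenotypeAnnotation,
    read_annotations,
    write_annotations,
)
from devonto.errors import AnnotationError, RenderError
from devonto.fixtures import (
    ANTERIOR_CHAMBER_SB,
    HEART,
    SWIM_BLADDER,
    TUNICA_INTERNA,
    stage_id,
)
from devonto.model import TermID
from devonto.stages import StageInterval

EXPR_HEADER = ("#kind expression\n"
               "gene\tentity\tentity2\tstart_stage\tend_stage\tassay"
               "\texpressed\n")
PHEN_HEADER = ("#kind phenotype\n"
               "entity1_genus\tentity1_filler\tquality_id\tquality_label"
               "\tentity2\ttag\tstart_stage\tend_stage\tgenotype\n")


def read(text, bundle):
    return read_annotations(text, bundle.anatomy, bundle.stages,
                            bundle.series())


def test_expression_row_parsed_with_names(swim):
    text = EXPR_HEADER + ("wif1\tanterior swim bladder bud\t\t"
                          "Protruding-mouth\tProtruding-mouth\tISH\ttrue\n")
    [rec] = read(text, swim)
    assert isinstance(rec, ExpressionAnnotation)
    assert rec.gene == "wif1"
    assert rec.entity == TermID.parse("TEST:0000031")
    assert rec.observed == StageInterval(5, 5)
    assert rec.expressed


def test_empty_file_with_header_is_empty_list(swim):
    assert read(EXPR_HEADER, swim) == []


def test_composite_cell_parsed(swim):
    text = EXPR_HEADER + ("acta2\tsmooth muscle\ttunica interna\t"
                          "Protruding-mouth\tAdult\tIHC\ttrue\n")
    [rec] = read(text, swim)
    assert isinstance(rec.entity, d.CompositeEntity)
    assert rec.entity.filler == TUNICA_INTERNA


def test_relational_quality_without_entity2_is_row_error(swim):
    text = PHEN_HEADER + ("swim bladder\t\tPATO:0002002\t"
                          "has extra parts of type\t\tabnormal\t\t\t"
                          "mutant\n")
    with pytest.raises(AnnotationError) as err:
        read(text, swim)
    assert err.value.row == 3


def test_unresolvable_entity_is_row_error(swim):
    text = EXPR_HEADER + "wif1\tgas gland\t\tDay 5\tDay 5\tISH\ttrue\n"
    with pytest.raises(AnnotationError) as err:
        read(text, swim)
    assert err.value.row == 3
    assert err.value.column == "entity"


def test_malformed_stage_token_is_row_error(swim):
    text = EXPR_HEADER + "wif1\tswim bladder\t\tnot a stage\t\tISH\ttrue\n"
    with pytest.raises(AnnotationError) as err:
        read(text, swim)
    assert err.value.column == "start_stage"


def test_super_stage_in_annotation_expands_to_leaf_range(swim):
    text = EXPR_HEADER + "opa3\tswim bladder\t\tLarva\tLarva\tISH\ttrue\n"
    [rec] = read(text, swim)
    # 'Larva' covers Protruding-mouth..Day 5
    assert rec.observed == StageInterval(5, 7)


def test_round_trip_is_lossless(swim):
    text = write_annotations(swim.annotations, swim.series())
    back = read(text, swim)
    assert back == swim.annotations
    assert write_annotations(back, swim.series()) == text


# -- expression stage check ------------------------------------------------

def test_swim_bladder_annotations_are_stage_consistent(swim):
    out = d.check_expression_stages(swim.annotations, swim.anatomy,
                                    swim.series())
    assert out == []


def test_expression_before_entity_exists_flagged(heart):
    series = heart.series()
    ann = ExpressionAnnotation("nkx2.5", HEART, StageInterval(0, 0))
    out = d.check_expression_stages([ann], heart.anatomy, series)
    assert len(out) == 1
    assert out[0].rule_id is d.Rule.EXPR_STAGE
    assert out[0].subject == HEART
    assert "Prim-5" in out[0].message


def test_overlap_mode_is_weaker_than_containment(heart):
    series = heart.series()
    # window straddles the heart's start: conflict under containment,
    # tolerated under overlap
    ann = ExpressionAnnotation("nkx2.5", HEART, StageInterval(2, 4))
    assert len(d.check_expression_stages([ann], heart.anatomy,
                                         series)) == 1
    assert d.check_expression_stages([ann], heart.anatomy, series,
                                     mode="overlap") == []


def test_composite_entity_checked_against_both_windows(swim):
    series = swim.series()
    comp = d.compose(ANTERIOR_CHAMBER_SB, TUNICA_INTERNA)
    # anterior chamber exists 6.., tunica interna 5..; intersection 6..
    ok = ExpressionAnnotation("g1", comp, StageInterval(6, 7))
    bad = ExpressionAnnotation("g2", comp, StageInterval(5, 7))
    assert d.check_expression_stages([ok], swim.anatomy, series) == []
    assert len(d.check_expression_stages([bad], swim.anatomy, series)) == 1


def test_external_genus_composite_uses_filler_window(swim):
    series = swim.series()
    comp = d.compose(TermID.parse("BSPO:0000079"), SWIM_BLADDER)
    ok = ExpressionAnnotation("g", comp, StageInterval(5, 9))
    bad = ExpressionAnnotation("g", comp, StageInterval(0, 9))
    assert d.check_expression_stages([ok], swim.anatomy, series) == []
    assert len(d.check_expression_stages([bad], swim.anatomy, series)) == 1


def test_check_stable_under_reordering(swim, heart):
    series = heart.series()
    anns = [ExpressionAnnotation(f"g{i}", HEART, StageInterval(0, 0))
            for i in range(4)]
    anns.append(ExpressionAnnotation("ok", HEART, StageInterval(3, 4)))
    forward = d.check_expression_stages(anns, heart.anatomy, series)
    backward = d.check_expression_stages(anns[::-1], heart.anatomy, series)
    assert [v.message for v in forward] == [v.message for v in backward]
    assert len(forward) == 4  # each offending record exactly once


def test_phenotype_exemption_is_absolute(swim):
    """No stage window on any phenotype record ever raises a violation."""
    rng = random.Random(0)
    series = swim.series()
    entities = sorted(swim.anatomy.terms)
    records = []
    for _ in range(200):
        lo = rng.randrange(len(series))
        hi = rng.randrange(lo, len(series))
        records.append(PhenotypeAnnotation(
            rng.choice(entities), "PATO:0000462", "absent",
            stage=StageInterval(lo, hi), genotype="mutant"))
    assert d.check_expression_stages(records, swim.anatomy, series) == []


# -- EQ/EQE rendering ------------------------------------------------------

GREY_MATTER = TermID.parse("ZFA:0001681")
SPINAL_CORD = TermID.parse("ZFA:0000075")
OLIGODENDROCYTE = TermID.parse("ZFA:0009076")

EQE_NAMES = {GREY_MATTER: "grey matter", SPINAL_CORD: "spinal cord",
             OLIGODENDROCYTE: "oligodendrocyte"}


def test_render_eqe_composite_relational_quality():
    record = PhenotypeAnnotation(
        entity1=d.CompositeEntity(GREY_MATTER, SPINAL_CORD),
        quality_id="PATO:0002002",
        quality_label="has extra parts of type",
        entity2=OLIGODENDROCYTE)
    assert d.render_eqe(record, EQE_NAMES) == \
        "grey matter part_of spinal cord has extra parts of type " \
        "oligodendrocyte"


def test_render_eq_simple():
    record = PhenotypeAnnotation(
        entity1=TermID.parse("TEST:0000034"), quality_id="PATO:0000462",
        quality_label="absent")
    names = {TermID.parse("TEST:0000034"): "anterior chamber swim bladder"}
    assert d.render_eqe(record, names) == \
        "anterior chamber swim bladder absent"


def test_render_normal_tag_suffix():
    record = PhenotypeAnnotation(
        entity1=SPINAL_CORD, quality_id="PATO:0000461",
        quality_label="normal amount", tag="normal")
    assert d.render_eqe(record, EQE_NAMES).endswith(", normal")


def test_render_missing_name_raises():
    record = PhenotypeAnnotation(entity1=SPINAL_CORD, quality_id="q",
                                 quality_label="absent")
    with pytest.raises(RenderError):
        d.render_eqe(record, {})
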