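"""Expression and phenotype (EQ/EQE) annotation records.

Expression records tie a gene to an anatomical entity (a term or a
post-composed class), the stage window in which the assay observed it,
the assay, and whether expression was present (absence is recorded too).
Phenotype records follow the Entity–Quality(–Entity) convention: an
affected entity, a quality term from a quality ontology, and — for
relational qualities — a second entity; normal as well as abnormal
observations are captured.

The release-time check :func:`check_expression_stages` flags expression
records whose observed window is provably not contained in the entity's
existence window. Phenotype records are exempt by design: phenotypes
often involve the delayed development of a structure, so a phenotype may
legitimately be observed at stages where the intact structure would not
exist.

Tabular exchange format (UTF-8, tab-separated, ``#`` comments): a
``#kind expression`` or ``#kind phenotype`` line opens a section, followed
by a header row, then data rows; one file may hold several sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .compose import (
    CompositeEntity,
    DEFAULT_REGISTRY,
    SourceRegistry,
    compose,
)
from .errors import (
    AnnotationError,
    DevontoError,
    IntervalError,
    RenderError,
)
from .model import Ontology, TermID, resolve
from .qc import Rule, Severity, Violation
from .stages import (
    StageInterval,
    StageSeries,
    contains,
    expand_super_stage,
    interval_of,
    intersects,
)

Entity = Union[TermID, CompositeEntity]

EXPRESSION_COLUMNS = ["gene", "entity", "entity2", "start_stage",
                      "end_stage", "assay", "expressed"]
PHENOTYPE_COLUMNS = ["entity1_genus", "entity1_filler", "quality_id",
                     "quality_label", "entity2", "tag", "start_stage",
                     "end_stage", "genotype"]


@dataclass(frozen=True)
class ExpressionAnnotation:
    gene: str
    entity: Entity
    observed: StageInterval
    assay: str = "ISH"
    expressed: bool = True
    row: Optional[int] = field(default=None, compare=False)


@dataclass(frozen=True)
class PhenotypeAnnotation:
    entity1: Entity
    quality_id: str
    quality_label: str
    entity2: Optional[Entity] = None
    tag: str = "abnormal"
    stage: Optional[StageInterval] = None
    genotype: str = ""
    row: Optional[int] = field(default=None, compare=False)

    @property
    def is_eqe(self) -> bool:
        return self.entity2 is not None


Annotation = Union[ExpressionAnnotation, PhenotypeAnnotation]


def _resolve_entity(token: str, onto: Ontology, *, row: int,
                    column: str) -> TermID:
    """A cell holds either a CURIE or a resolvable name/synonym."""
    token = token.strip()
    try:
        return resolve(onto, token)
    except DevontoError:
        pass
    try:
        tid = TermID.parse(token)
    except ValueError:
        raise AnnotationError(f"unresolvable entity {token!r}",
                              row=row, column=column) from None
    if tid.prefix in DEFAULT_REGISTRY.anatomy_prefixes and tid not in onto:
        raise AnnotationError(f"unresolvable entity {token!r}",
                              row=row, column=column)
    return tid


def _stage_bound(token: str, series: StageSeries, onto: Ontology,
                 *, row: int, column: str, side: str) -> Optional[int]:
    """Map a stage cell to an ordinal; super-stages expand to their bound."""
    token = token.strip()
    if not token or token.lower() == "unknown":
        return None
    try:
        tid = resolve(onto, token)
    except DevontoError:
        raise AnnotationError(f"malformed stage token {token!r}",
                              row=row, column=column) from None
    try:
        leaves = expand_super_stage(series, tid)
    except DevontoError:
        raise AnnotationError(f"malformed stage token {token!r}",
                              row=row, column=column) from None
    leaf = leaves[0] if side == "start" else leaves[-1]
    return series.ordinal(leaf)


def _interval_from_cells(start_tok: str, end_tok: str, series: StageSeries,
                         stage_onto: Ontology, *, row: int,
                         required: bool) -> Optional[StageInterval]:
    start = _stage_bound(start_tok, series, stage_onto, row=row,
                         column="start_stage", side="start")
    end = _stage_bound(end_tok, series, stage_onto, row=row,
                       column="end_stage", side="end")
    if start is None and end is None:
        if required:
            raise AnnotationError("expression record needs an observed "
                                  "stage window", row=row,
                                  column="start_stage")
        return None
    try:
        return StageInterval(start, end)
    except IntervalError as exc:
        raise AnnotationError(str(exc), row=row,
                              column="start_stage") from None


def read_annotations(text: str, onto: Ontology, stage_onto: Ontology,
                     series: StageSeries,
                     registry: SourceRegistry = DEFAULT_REGISTRY
                     ) -> list[Annotation]:
    """Parse a tabular annotation file into typed records.

    Row and column positions are carried on every error. Composite cells
    use the ``entity`` + ``entity2``/``entity1_filler`` split columns; a
    relational quality (by convention any phenotype row filling
    ``entity2``) must resolve both entities.
    """
    records: list[Annotation] = []
    kind: Optional[str] = None
    header: Optional[list[str]] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("kind"):
                kind = body.split()[1] if len(body.split()) > 1 else ""
                if kind not in ("expression", "phenotype"):
                    raise AnnotationError(
                        f"unknown annotation kind {kind!r}", row=lineno)
                header = None
            continue
        cells = line.split("\t")
        if kind is None:
            raise AnnotationError("data before any '#kind' declaration",
                                  row=lineno)
        if header is None:
            expected = (EXPRESSION_COLUMNS if kind == "expression"
                        else PHENOTYPE_COLUMNS)
            got = [c.strip() for c in cells]
            if got != expected:
                raise AnnotationError(
                    f"bad header for kind {kind}: expected "
                    f"{expected}, got {got}", row=lineno)
            header = got
            continue
        cells += [""] * (len(header) - len(cells))
        rowmap = dict(zip(header, (c.strip() for c in cells)))
        if kind == "expression":
            records.append(_expression_row(rowmap, lineno, onto, stage_onto,
                                           series, registry))
        else:
            records.append(_phenotype_row(rowmap, lineno, onto, stage_onto,
                                          series, registry))
    return records


def _entity_cell(genus_tok: str, filler_tok: str, onto: Ontology,
                 registry: SourceRegistry, *, row: int,
                 columns: tuple[str, str]) -> Entity:
    genus = _resolve_entity(genus_tok, onto, row=row, column=columns[0])
    if not filler_tok.strip():
        return genus
    filler = _resolve_entity(filler_tok, onto, row=row, column=columns[1])
    try:
        return compose(genus, filler, registry)
    except DevontoError as exc:
        raise AnnotationError(str(exc), row=row,
                              column=columns[1]) from None


def _expression_row(cells: Mapping[str, str], row: int, onto: Ontology,
                    stage_onto: Ontology, series: StageSeries,
                    registry: SourceRegistry) -> ExpressionAnnotation:
    entity = _entity_cell(cells["entity"], cells["entity2"], onto, registry,
                          row=row, columns=("entity", "entity2"))
    observed = _interval_from_cells(cells["start_stage"], cells["end_stage"],
                                    series, stage_onto, row=row,
                                    required=True)
    return ExpressionAnnotation(
        gene=cells["gene"], entity=entity, observed=observed,
        assay=cells["assay"] or "ISH",
        expressed=cells["expressed"].lower() not in ("false", "0", "no"),
        row=row)


def _phenotype_row(cells: Mapping[str, str], row: int, onto: Ontology,
                   stage_onto: Ontology, series: StageSeries,
                   registry: SourceRegistry) -> PhenotypeAnnotation:
    entity1 = _entity_cell(cells["entity1_genus"], cells["entity1_filler"],
                           onto, registry,
                           row=row, columns=("entity1_genus",
                                             "entity1_filler"))
    quality_id = cells["quality_id"]
    entity2: Optional[Entity] = None
    if cells["entity2"]:
        entity2 = _resolve_entity(cells["entity2"], onto, row=row,
                                  column="entity2")
    stage = _interval_from_cells(cells["start_stage"], cells["end_stage"],
                                 series, stage_onto, row=row, required=False)
    tag = cells["tag"] or "abnormal"
    if tag not in ("abnormal", "normal"):
        raise AnnotationError(f"tag must be abnormal|normal, got {tag!r}",
                              row=row, column="tag")
    record = PhenotypeAnnotation(
        entity1=entity1, quality_id=quality_id,
        quality_label=cells["quality_label"], entity2=entity2, tag=tag,
        stage=stage, genotype=cells["genotype"], row=row)
    validate_phenotype_relational(record)
    return record


_RELATIONAL_MARKERS = ("has extra parts of type", "has fewer parts of type",
                       "towards", "away from")


def validate_phenotype_relational(p: PhenotypeAnnotation) -> None:
    """A relational quality requires the second entity of the EQE triple."""
    if any(m in p.quality_label for m in _RELATIONAL_MARKERS) \
            and p.entity2 is None:
        raise AnnotationError(
            f"relational quality {p.quality_label!r} requires entity2",
            row=p.row, column="entity2")


def _cell_of_entity(e: Entity) -> tuple[str, str]:
    if isinstance(e, CompositeEntity):
        return e.genus.curie, e.filler.curie
    return e.curie, ""


def write_annotations(records: Iterable[Annotation],
                      series: StageSeries) -> str:
    """Serialize records back to the tabular dialect (lossless round-trip)."""
    expr = [r for r in records if isinstance(r, ExpressionAnnotation)]
    phen = [r for r in records if isinstance(r, PhenotypeAnnotation)]

    def stage_cell(ordinal: Optional[int]) -> str:
        return "" if ordinal is None else series.name_of(ordinal)

    out: list[str] = []
    if expr:
        out.append("#kind expression")
        out.append("\t".join(EXPRESSION_COLUMNS))
        for r in expr:
            g, f = _cell_of_entity(r.entity)
            out.append("\t".join([
                r.gene, g, f, stage_cell(r.observed.start),
                stage_cell(r.observed.end), r.assay,
                "true" if r.expressed else "false"]))
    if phen:
        if out:
            out.append("")
        out.append("#kind phenotype")
        out.append("\t".join(PHENOTYPE_COLUMNS))
        for r in phen:
            g, f = _cell_of_entity(r.entity1)
            e2 = r.entity2.curie if isinstance(r.entity2, TermID) else (
                r.entity2.id.curie if r.entity2 is not None else "")
            s = stage_cell(r.stage.start) if r.stage else ""
            e = stage_cell(r.stage.end) if r.stage else ""
            out.append("\t".join([
                g, f, r.quality_id, r.quality_label, e2, r.tag, s, e,
                r.genotype]))
    return "\n".join(out) + "\n"


def _entity_interval(entity: Entity, onto: Ontology, series: StageSeries,
                     registry: SourceRegistry) -> Optional[StageInterval]:
    """Existence window of a plain or composite entity.

    Composites with an external genus use the anatomy filler's window
    (external partners carry no stages); anatomy+anatomy composites use
    the intersection of both windows. ``None`` when no window is provable.
    """
    if isinstance(entity, TermID):
        try:
            return interval_of(onto, series, entity)
        except IntervalError:
            return None
    filler_iv = _entity_interval(entity.filler, onto, series, registry)
    if entity.genus.prefix not in registry.anatomy_prefixes:
        return filler_iv
    genus_iv = _entity_interval(entity.genus, onto, series, registry)
    if filler_iv is None or genus_iv is None:
        return filler_iv or genus_iv
    start = (filler_iv.start if genus_iv.start is None
             else genus_iv.start if filler_iv.start is None
             else max(filler_iv.start, genus_iv.start))
    end = (filler_iv.end if genus_iv.end is None
           else genus_iv.end if filler_iv.end is None
           else min(filler_iv.end, genus_iv.end))
    if start is not None and end is not None and start > end:
        return None  # windows never co-exist; nothing provable to check
    return StageInterval(start, end)


def _entity_label(entity: Entity, onto: Ontology) -> str:
    if isinstance(entity, CompositeEntity):
        return f"{entity.genus.curie} part_of {entity.filler.curie}"
    term = onto.terms.get(entity)
    return term.name if term is not None and term.name else entity.curie


def check_expression_stages(anns: Iterable[Annotation], onto: Ontology,
                            series: StageSeries,
                            registry: SourceRegistry = DEFAULT_REGISTRY,
                            mode: str = "containment") -> list[Violation]:
    """Flag expression records observed outside their entity's window.

    ``mode="containment"`` (default) requires the observed window to lie
    within the entity's existence window; ``mode="overlap"`` only requires
    the windows to intersect. Phenotype records are never checked —
    the exemption is absolute. Unknown sides are permissive.
    """
    if mode not in ("containment", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for ann in anns:
        if not isinstance(ann, ExpressionAnnotation):
            continue
        entity_iv = _entity_interval(ann.entity, onto, series, registry)
        if entity_iv is None:
            continue
        ok = (contains(entity_iv, ann.observed) if mode == "containment"
              else intersects(entity_iv, ann.observed))
        if ok:
            continue
        entity_id = (ann.entity.id if isinstance(ann.entity, CompositeEntity)
                     else ann.entity)
        msg = (f"expression of {ann.gene} in "
               f"'{_entity_label(ann.entity, onto)}' observed at "
               f"{ann.observed.render(series)}, outside the entity's "
               f"existence window {entity_iv.render(series)}")
        out.append(Violation(Rule.EXPR_STAGE, entity_id, (),
                             Severity.ERROR, msg))
    out.sort(key=lambda v: (v.subject.curie, v.message))
    return out


def render_eqe(p: PhenotypeAnnotation, names: Mapping[TermID, str]) -> str:
    """Render an EQ/EQE annotation as its human-readable sentence.

    ``<entity1> <quality>`` for EQ, ``<entity1> <quality> <entity2>`` for
    EQE; a composite entity renders as ``<genus name> part_of <filler
    name>``; a normal observation is suffixed ``, normal``.
    """

    def name(e: Entity) -> str:
        if isinstance(e, CompositeEntity):
            return f"{name(e.genus)} part_of {name(e.filler)}"
        try:
            return names[e]
        except KeyError:
            raise RenderError(f"no name for {e.curie}") from None

    text = f"{name(p.entity1)} {p.quality_label}"
    if p.entity2 is not None:
        text += f" {name(p.entity2)}"
    if p.tag == "normal":
        text += ", normal"
    return text
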