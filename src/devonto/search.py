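"""Query expansion over the subsumption and partonomy hierarchies.

A search for a term returns annotations made to the term itself and to
every class beneath it via is_a/part_of — including placed post-composed
classes, which hang under their anatomy filler. Expansion deliberately
excludes develops_from: a developmental progenitor is a distinct
structure, not a sub-structure, so annotations to it are not returned
for its product (nor vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .annotations import (
    Annotation,
    ExpressionAnnotation,
    PhenotypeAnnotation,
)
from .compose import CompositeEntity, extend_ontology
from .errors import IndexingError, TermNotFoundError
from .model import HIERARCHY, Ontology, TermID, descendants, resolve
from .stages import StageInterval, StageSeries, expand_super_stage, intersects


@dataclass
class SearchIndex:
    """Annotation records partitioned by entity, over the working graph."""

    records: list[Annotation]
    direct: dict[TermID, list[int]]
    graph: Ontology  # ontology extended with placed composites
    anatomy: Ontology
    _cache: dict[TermID, frozenset[TermID]] = field(default_factory=dict)

    def expansion(self, query: TermID) -> frozenset[TermID]:
        if query not in self._cache:
            self._cache[query] = frozenset(
                descendants(self.graph, query, HIERARCHY))
        return self._cache[query]


def _entity_key(entity) -> TermID:
    return entity.id if isinstance(entity, CompositeEntity) else entity


def build_index(anns: Iterable[Annotation], onto: Ontology,
                composites: Iterable[CompositeEntity] = ()) -> SearchIndex:
    """Index every record under exactly one direct entity key.

    Composites referenced by records are placed automatically, in
    addition to any passed explicitly.
    """
    records = list(anns)
    all_composites = set(composites)
    for r in records:
        for e in ((r.entity,) if isinstance(r, ExpressionAnnotation)
                  else (r.entity1, r.entity2)):
            if isinstance(e, CompositeEntity):
                all_composites.add(e)
    graph = extend_ontology(onto, all_composites)
    direct: dict[TermID, list[int]] = {}
    for i, r in enumerate(records):
        entity = r.entity if isinstance(r, ExpressionAnnotation) else r.entity1
        key = _entity_key(entity)
        if key not in graph:
            raise IndexingError(
                f"record {i} (row {r.row}) refers to unknown entity "
                f"{key.curie}")
        direct.setdefault(key, []).append(i)
    return SearchIndex(records, direct, graph, onto)


def _resolve_query(index: SearchIndex, query: Union[str, TermID]) -> TermID:
    if isinstance(query, TermID):
        if query not in index.graph:
            raise TermNotFoundError(query.curie)
        return query
    return resolve(index.anatomy, query)


def search_expression(index: SearchIndex, query: Union[str, TermID],
                      stage_filter: Optional[StageInterval] = None
                      ) -> list[ExpressionAnnotation]:
    """Expression records annotated to the query or any descendant.

    ``stage_filter`` keeps records whose observed window intersects the
    filter window (a search at a stage should find anything observed
    then — intersection, unlike the containment rule used for
    validation). Build the filter with :func:`stage_filter_window`.
    """
    qid = _resolve_query(index, query)
    expansion = index.expansion(qid)
    out = []
    for key in expansion:
        for i in index.direct.get(key, ()):
            r = index.records[i]
            if not isinstance(r, ExpressionAnnotation):
                continue
            if stage_filter is not None and not intersects(
                    r.observed, stage_filter):
                continue
            out.append((i, r))
    return [r for _, r in sorted(out, key=lambda p: p[0])]


def search_phenotype(index: SearchIndex, query: Union[str, TermID],
                     include_entity2: bool = False
                     ) -> list[PhenotypeAnnotation]:
    """Phenotype records whose affected entity falls under the query.

    Retrieval is driven by entity1 (the affected entity); the second
    entity of an EQE triple does not trigger retrieval unless
    ``include_entity2`` is set.
    """
    qid = _resolve_query(index, query)
    expansion = index.expansion(qid)
    out = {}
    for key in expansion:
        for i in index.direct.get(key, ()):
            r = index.records[i]
            if isinstance(r, PhenotypeAnnotation):
                out[i] = r
    if include_entity2:
        for i, r in enumerate(index.records):
            if isinstance(r, PhenotypeAnnotation) and r.entity2 is not None \
                    and _entity_key(r.entity2) in expansion:
                out[i] = r
    return [out[i] for i in sorted(out)]


def stage_filter_window(series: StageSeries, stage_onto: Ontology,
                        stage: Union[str, TermID]) -> StageInterval:
    """Window of a leaf stage, super-stage or the unknown sentinel.

    A leaf covers its own ordinal; a super-stage covers its contiguous
    leaf range; the unknown sentinel covers the whole series.
    """
    if isinstance(stage, str):
        stage = resolve(stage_onto, stage)
    leaves = expand_super_stage(series, stage)
    return StageInterval(series.ordinal(leaves[0]),
                         series.ordinal(leaves[-1]))
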