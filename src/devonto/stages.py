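"""Total order of developmental stages and the interval calculus over it.

The stage ontology models the staging series as an ordered set of leaf
stage classes chained by ``immediately_preceded_by``, with ``part_of``
edges grouping consecutive leaves into super-stages (used only for
querying) and an ``unknown`` sentinel stage spanning the whole life cycle.
:func:`build_stage_series` recovers the total order; :class:`StageInterval`
and the predicates :func:`contains` / :func:`junction` implement the
interval calculus every temporal consistency check consumes.

Ordinals are 0-based internal bookkeeping; human-facing messages always
render stage names.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    IncompleteStagesError,
    IntervalError,
    InvertedIntervalError,
    StageSeriesError,
    SuperStageFillerError,
    TermNotFoundError,
    UnknownStageError,
)
from .model import Ontology, Predicate, Relationship, TermID

UNKNOWN_STAGE_NAME = "unknown"


@dataclass(frozen=True)
class StageSeries:
    """The totally ordered leaf stages plus super-stage membership."""

    leaves: tuple[TermID, ...]
    #: super-stage id -> (first leaf ordinal, last leaf ordinal), inclusive
    super_stages: dict[TermID, tuple[int, int]]
    unknown_id: Optional[TermID]
    names: dict[TermID, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.leaves)

    def ordinal(self, stage: TermID) -> int:
        try:
            return self.leaves.index(stage)
        except ValueError:
            raise TermNotFoundError(stage.curie) from None

    def is_leaf(self, stage: TermID) -> bool:
        return stage in self.leaves

    def is_super(self, stage: TermID) -> bool:
        return stage in self.super_stages

    def name_of(self, ordinal: int) -> str:
        tid = self.leaves[ordinal]
        return self.names.get(tid, tid.curie)


def build_stage_series(stage_ontology: Ontology) -> StageSeries:
    """Recover the total stage order from ``immediately_preceded_by`` edges.

    Leaf stages must form one chain: every leaf except the first has
    exactly one predecessor and every leaf except the last exactly one
    successor. Branches, cycles and disconnected fragments raise
    :class:`StageSeriesError` naming the offending stages. Super-stages are
    the targets of ``part_of`` edges from leaves; their member ordinals
    must be contiguous. The ``unknown`` sentinel is recognised by name.
    """
    live = {t.id: t for t in stage_ontology.live_terms()}
    unknown = next((tid for tid, t in sorted(live.items())
                    if t.name == UNKNOWN_STAGE_NAME), None)
    super_ids = {r.object for r in stage_ontology.relationships
                 if r.predicate is Predicate.PART_OF and r.object in live}
    candidates = sorted(t for t in live
                        if t != unknown and t not in super_ids)
    if not candidates:
        raise StageSeriesError("stage ontology has no leaf stages")

    succ: dict[TermID, TermID] = {}
    pred: dict[TermID, TermID] = {}
    for r in stage_ontology.relationships:
        if r.predicate is not Predicate.IMMEDIATELY_PRECEDED_BY:
            continue
        later, earlier = r.subject, r.object
        for tid in (later, earlier):
            if tid not in live or tid == unknown or tid in super_ids:
                raise StageSeriesError(
                    f"immediately_preceded_by involves non-leaf stage "
                    f"{tid.curie}")
        if earlier in succ:
            raise StageSeriesError(
                f"stage {earlier.curie} has two successors "
                f"({succ[earlier].curie}, {later.curie})")
        if later in pred:
            raise StageSeriesError(
                f"stage {later.curie} has two predecessors "
                f"({pred[later].curie}, {earlier.curie})")
        succ[earlier] = later
        pred[later] = earlier

    heads = [t for t in candidates if t not in pred]
    if len(candidates) > 1 and len(heads) != 1:
        if not heads:
            raise StageSeriesError(
                "immediately_preceded_by chain has no first stage (cycle)")
        raise StageSeriesError(
            "disconnected stage chain fragments starting at: "
            + ", ".join(h.curie for h in heads))
    order: list[TermID] = []
    node = heads[0] if heads else candidates[0]
    seen = set()
    while node is not None:
        if node in seen:
            raise StageSeriesError(
                f"immediately_preceded_by cycle through {node.curie}")
        seen.add(node)
        order.append(node)
        node = succ.get(node)
    if len(order) != len(candidates):
        missing = sorted(set(candidates) - seen)
        raise StageSeriesError(
            "stages not reachable on the chain: "
            + ", ".join(m.curie for m in missing))

    ordinal = {tid: i for i, tid in enumerate(order)}
    supers: dict[TermID, tuple[int, int]] = {}
    for sup in sorted(super_ids):
        members = sorted(
            ordinal[r.subject]
            for r in stage_ontology.relationships
            if r.predicate is Predicate.PART_OF and r.object == sup
            and r.subject in ordinal)
        if not members:
            raise StageSeriesError(
                f"super-stage {sup.curie} covers no leaf stage")
        lo, hi = members[0], members[-1]
        if members != list(range(lo, hi + 1)):
            raise StageSeriesError(
                f"super-stage {sup.curie} membership is not contiguous")
        supers[sup] = (lo, hi)

    names = {tid: t.name for tid, t in live.items()}
    return StageSeries(tuple(order), supers, unknown, names)


@dataclass(frozen=True, order=True)
class StageInterval:
    """A term's existence window in leaf ordinals; ``None`` = unknown side.

    At least one side must be known, and a fully known interval must have
    ``start <= end``.
    """

    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self):
        if self.start is None and self.end is None:
            raise IncompleteStagesError(
                "an interval needs a known start stage or a known end stage")
        if self.start is not None and self.end is not None \
                and self.start > self.end:
            raise InvertedIntervalError(
                f"start ordinal {self.start} is after end ordinal {self.end}")

    def render(self, series: StageSeries) -> str:
        s = "unknown" if self.start is None else series.name_of(self.start)
        e = "unknown" if self.end is None else series.name_of(self.end)
        return f"{s}..{e}"


class TemporalRelation(enum.Enum):
    """Classification of the junction between two ordered intervals."""

    OVERLAPPING = "OVERLAPPING"
    ABUTTING = "ABUTTING"
    GAP = "GAP"
    PREMATURE = "PREMATURE"
    UNDETERMINED = "UNDETERMINED"


def interval_of(ontology: Ontology, series: StageSeries,
                term: TermID) -> StageInterval:
    """Extract a term's existence window from its stage relationships.

    Stage fillers must be leaves of the series or the unknown sentinel;
    a super-stage filler, a missing/double-unknown window, or an inverted
    window raises the corresponding :class:`IntervalError` subclass.
    """

    def side(predicate: Predicate, label: str) -> Optional[int]:
        objs = ontology.objects_of(term, predicate)
        if not objs:
            return None
        if len(objs) > 1:
            raise IntervalError(
                f"{term.curie} has {len(objs)} {label} relationships",
                term_id=term)
        obj = objs[0]
        if series.unknown_id is not None and obj == series.unknown_id:
            return None
        if series.is_super(obj):
            raise SuperStageFillerError(
                f"{label} of {term.curie} is the super-stage {obj.curie}; "
                "stage relations must point at leaf stages", term_id=term)
        if not series.is_leaf(obj):
            raise UnknownStageError(
                f"{label} of {term.curie} references {obj.curie}, "
                "which is not in the stage series", term_id=term)
        return series.ordinal(obj)

    start = side(Predicate.START_STAGE, "start_stage")
    end = side(Predicate.END_STAGE, "end_stage")
    if start is None and end is None:
        raise IncompleteStagesError(
            f"{term.curie} has neither a known start stage nor a known "
            "end stage", term_id=term)
    try:
        return StageInterval(start, end)
    except InvertedIntervalError:
        raise InvertedIntervalError(
            f"{term.curie} starts at {series.name_of(start)} after its end "
            f"{series.name_of(end)}", term_id=term) from None


def contains(outer: StageInterval, inner: StageInterval) -> bool:
    """True iff ``inner`` provably lies within ``outer``.

    An unknown side of the outer interval is unbounded (permissive); an
    unknown side of the inner interval is taken to satisfy the
    corresponding bound, because a violation cannot be proven from it.
    """
    start_ok = (outer.start is None or inner.start is None
                or inner.start >= outer.start)
    end_ok = (outer.end is None or inner.end is None
              or inner.end <= outer.end)
    return start_ok and end_ok


def junction(predecessor: StageInterval,
             successor: StageInterval) -> TemporalRelation:
    """Classify the temporal junction of a developmental succession.

    Compares the successor's start stage against the predecessor's end
    stage: equal = OVERLAPPING, one later = ABUTTING, more than one later =
    GAP, earlier = PREMATURE; UNDETERMINED when either side is unknown.
    """
    if predecessor.end is None or successor.start is None:
        return TemporalRelation.UNDETERMINED
    s, e = successor.start, predecessor.end
    if s == e:
        return TemporalRelation.OVERLAPPING
    if s == e + 1:
        return TemporalRelation.ABUTTING
    if s > e + 1:
        return TemporalRelation.GAP
    return TemporalRelation.PREMATURE


def intersects(a: StageInterval, b: StageInterval) -> bool:
    """True unless the two windows are provably disjoint."""
    if a.start is not None and b.end is not None and a.start > b.end:
        return False
    if b.start is not None and a.end is not None and b.start > a.end:
        return False
    return True


def expand_super_stage(series: StageSeries, stage: TermID) -> list[TermID]:
    """Expand a stage reference to its ordered leaf list.

    A leaf expands to itself, a super-stage to its contiguous leaf range,
    and the unknown sentinel (spanning the whole series) to every leaf.
    """
    if series.is_leaf(stage):
        return [stage]
    if series.is_super(stage):
        lo, hi = series.super_stages[stage]
        return list(series.leaves[lo:hi + 1])
    if series.unknown_id is not None and stage == series.unknown_id:
        return list(series.leaves)
    raise TermNotFoundError(stage.curie)


def set_stage(ontology: Ontology, term: TermID, which: str,
              stage: Optional[TermID]) -> None:
    """Replace a term's start_stage or end_stage relationship (curation edit).

    ``which`` is ``"start"`` or ``"end"``; ``stage=None`` removes the
    relationship entirely.
    """
    predicate = {"start": Predicate.START_STAGE,
                 "end": Predicate.END_STAGE}[which]
    ontology.relationships = [
        r for r in ontology.relationships
        if not (r.subject == term and r.predicate is predicate)]
    ontology._dirty = True
    if stage is not None:
        ontology.add_relationship(Relationship(term, predicate, stage))
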