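"""Core data model for stage-aware anatomy ontologies.

An :class:`Ontology` is a set of :class:`OntologyTerm` objects plus a list
of typed :class:`Relationship` edges and header directives. Anatomy
ontologies in this model carry three hierarchies — subsumption (``is_a``),
partonomy (``part_of``) and a developmental hierarchy (``develops_from``) —
and tie each anatomical class to the stage ontology via ``start_stage`` /
``end_stage``. Stage ontologies order their leaf stages with
``immediately_preceded_by``.

The graph-level operations (:func:`descendants`, :func:`resolve`,
:func:`derive_bridge_axioms`, :func:`clone_with_prefix`) live here as
module-level functions over an :class:`Ontology`.
"""

from __future__ import annotations

import enum
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

from .errors import (
    AmbiguousQueryError,
    ConfigError,
    DuplicateIdError,
    ObsoleteTermError,
    PrefixCollisionError,
    TermNotFoundError,
)

_CURIE_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_-]*):(\S+)$")

OBO_PURL_BASE = "http://purl.obolibrary.org/obo/"


@dataclass(frozen=True, order=True)
class TermID:
    """A CURIE-style class identifier, e.g. ``ZFA:0000114``.

    Native ontology classes use a zero-padded 7-digit local part;
    externally referenced classes (e.g. ``MPATH:359``, ``NCBITaxon:7955``)
    may use any local token.
    """

    prefix: str
    local: str

    @classmethod
    def parse(cls, text: str, *, require_canonical: bool = False) -> "TermID":
        m = _CURIE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a CURIE: {text!r}")
        tid = cls(m.group(1), m.group(2))
        if require_canonical and not tid.is_canonical:
            raise ValueError(
                f"id {text!r} does not have a 7-digit local part")
        return tid

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local}"

    @property
    def is_canonical(self) -> bool:
        return len(self.local) == 7 and self.local.isdigit()

    @property
    def uri(self) -> str:
        """OBO PURL for this id (``<base>/<prefix>_<local>``)."""
        return f"{OBO_PURL_BASE}{self.prefix}_{self.local}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


class SynonymScope(str, enum.Enum):
    EXACT = "EXACT"
    BROAD = "BROAD"
    NARROW = "NARROW"
    RELATED = "RELATED"


PLURAL = "PLURAL"


@dataclass(frozen=True, order=True)
class Synonym:
    """A typed synonym. A PLURAL synonym type implies EXACT scope."""

    text: str
    scope: SynonymScope = SynonymScope.EXACT
    synonym_type: Optional[str] = None
    xrefs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.synonym_type == PLURAL and self.scope is not SynonymScope.EXACT:
            raise ValueError("a PLURAL synonym must have EXACT scope")


@dataclass(frozen=True)
class Definition:
    text: str
    xrefs: tuple[str, ...] = ()


class Predicate(enum.Enum):
    """The six relationship types of the model."""

    IS_A = "is_a"
    PART_OF = "part_of"
    DEVELOPS_FROM = "develops_from"
    START_STAGE = "start_stage"
    END_STAGE = "end_stage"
    IMMEDIATELY_PRECEDED_BY = "immediately_preceded_by"

    @classmethod
    def from_name(cls, name: str) -> "Predicate":
        for p in cls:
            if p.value == name:
                return p
        raise KeyError(name)

    @property
    def external_id(self) -> Optional[str]:
        """RO/BFO CURIE of the relation, where one exists."""
        return _EXTERNAL_IDS.get(self)

    def __lt__(self, other):  # stable edge ordering in serialized output
        if isinstance(other, Predicate):
            return self.value < other.value
        return NotImplemented


_EXTERNAL_IDS = {
    Predicate.PART_OF: "BFO:0000050",
    Predicate.DEVELOPS_FROM: "RO:0002202",
    Predicate.START_STAGE: "RO:0002091",
    Predicate.END_STAGE: "RO:0002093",
    Predicate.IMMEDIATELY_PRECEDED_BY: "RO:0002087",
}

#: Edge types used for query expansion and closure.
HIERARCHY = frozenset({Predicate.IS_A, Predicate.PART_OF})


@dataclass(frozen=True, order=True)
class Relationship:
    subject: TermID
    predicate: Predicate
    object: TermID


@dataclass
class OntologyTerm:
    """One anatomical or stage class."""

    id: TermID
    name: str
    definition: Optional[Definition] = None
    synonyms: list[Synonym] = field(default_factory=list)
    xrefs: list[TermID] = field(default_factory=list)
    alt_ids: list[TermID] = field(default_factory=list)
    namespace: Optional[str] = None
    is_obsolete: bool = False
    replaced_by: Optional[TermID] = None
    consider: list[TermID] = field(default_factory=list)
    #: tags outside the supported inventory, preserved verbatim on round-trip
    extra_tags: list[tuple[str, str]] = field(default_factory=list)


class Ontology:
    """Terms + typed relationships + header directives.

    ``header`` maps a directive key to the list of its values (several
    directives, notably ``treat-xrefs-as-genus-differentia``, may repeat).
    ``extra_stanzas`` holds non-``[Term]`` stanzas verbatim so that
    round-tripping a file does not lose e.g. ``[Typedef]`` blocks.
    """

    def __init__(self,
                 header: Mapping[str, list[str]] | None = None,
                 terms: Iterable[OntologyTerm] = (),
                 relationships: Iterable[Relationship] = (),
                 extra_stanzas: Iterable[str] = ()):
        self.header: dict[str, list[str]] = {
            k: list(v) for k, v in (header or {}).items()}
        self.terms: dict[TermID, OntologyTerm] = {}
        self.relationships: list[Relationship] = []
        self.extra_stanzas: list[str] = list(extra_stanzas)
        self._dirty = True
        for t in terms:
            self.add_term(t)
        for r in relationships:
            self.add_relationship(r)

    # -- construction -----------------------------------------------------

    def add_term(self, term: OntologyTerm) -> None:
        if term.id in self.terms:
            raise DuplicateIdError(f"duplicate live id {term.id}",
                                   stanza=term.id.curie)
        alt_map = self._alt_id_map()
        if term.id in alt_map:
            raise DuplicateIdError(
                f"id {term.id} is already an alt_id of {alt_map[term.id]}",
                stanza=term.id.curie)
        for alt in term.alt_ids:
            if alt in self.terms or (alt in alt_map and alt_map[alt] != term.id):
                raise DuplicateIdError(
                    f"alt_id {alt} collides with an existing id",
                    stanza=term.id.curie)
        self.terms[term.id] = term
        self._dirty = True

    def add_relationship(self, rel: Relationship) -> None:
        self.relationships.append(rel)
        self._dirty = True

    def remove_relationships(self, *, subject: TermID | None = None,
                             predicate: Predicate | None = None) -> int:
        """Drop all edges matching the given subject and/or predicate."""
        keep = []
        dropped = 0
        for r in self.relationships:
            if ((subject is None or r.subject == subject)
                    and (predicate is None or r.predicate == predicate)):
                dropped += 1
            else:
                keep.append(r)
        self.relationships = keep
        self._dirty = True
        return dropped

    # -- lookup -----------------------------------------------------------

    def __contains__(self, term_id: TermID) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: TermID) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise TermNotFoundError(term_id.curie) from None

    def __len__(self) -> int:
        return len(self.terms)

    def live_terms(self) -> Iterator[OntologyTerm]:
        return (t for t in self.terms.values() if not t.is_obsolete)

    def out_edges(self, subject: TermID,
                  predicates: frozenset | set | None = None
                  ) -> list[Relationship]:
        self._reindex()
        rels = self._by_subject.get(subject, [])
        if predicates is None:
            return list(rels)
        return [r for r in rels if r.predicate in predicates]

    def in_edges(self, obj: TermID,
                 predicates: frozenset | set | None = None
                 ) -> list[Relationship]:
        self._reindex()
        rels = self._by_object.get(obj, [])
        if predicates is None:
            return list(rels)
        return [r for r in rels if r.predicate in predicates]

    def objects_of(self, subject: TermID, predicate: Predicate) -> list[TermID]:
        return [r.object for r in self.out_edges(subject, {predicate})]

    def _alt_id_map(self) -> dict[TermID, TermID]:
        self._reindex()
        return self._alt_ids

    def _reindex(self) -> None:
        if not self._dirty:
            return
        self._by_subject: dict[TermID, list[Relationship]] = defaultdict(list)
        self._by_object: dict[TermID, list[Relationship]] = defaultdict(list)
        for r in self.relationships:
            self._by_subject[r.subject].append(r)
            self._by_object[r.object].append(r)
        self._alt_ids: dict[TermID, TermID] = {}
        self._by_name: dict[str, list[TermID]] = defaultdict(list)
        self._by_synonym: dict[str, list[TermID]] = defaultdict(list)
        for t in self.terms.values():
            for alt in t.alt_ids:
                self._alt_ids[alt] = t.id
            self._by_name[t.name].append(t.id)
            for s in t.synonyms:
                self._by_synonym[s.text].append(t.id)
        self._dirty = False

    # -- graph views ------------------------------------------------------

    def graph(self, predicates: frozenset | set | None = None) -> nx.DiGraph:
        """Directed graph with one edge subject -> object per relationship."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for r in self.relationships:
            if predicates is None or r.predicate in predicates:
                g.add_edge(r.subject, r.object)
        return g

    def is_a_is_acyclic(self) -> bool:
        g = nx.DiGraph()
        for r in self.relationships:
            if r.predicate is Predicate.IS_A:
                s, o = r.subject, r.object
                if (s in self.terms and self.terms[s].is_obsolete) or \
                        (o in self.terms and self.terms[o].is_obsolete):
                    continue
                g.add_edge(s, o)
        return nx.is_directed_acyclic_graph(g)


# -- operations ------------------------------------------------------------

def descendants(ontology: Ontology, root: TermID,
                predicates: Iterable[Predicate] = HIERARCHY) -> set[TermID]:
    """Reflexive-transitive closure over the inverse of the given edge types.

    Returns every node from which ``root`` is reachable along edges of the
    given predicates — i.e. everything "beneath" the root in those
    hierarchies — always including ``root`` itself.
    """
    if root not in ontology:
        raise TermNotFoundError(root.curie)
    preds = frozenset(predicates)
    seen = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for rel in ontology.in_edges(node, preds):
            if rel.subject not in seen:
                seen.add(rel.subject)
                frontier.append(rel.subject)
    return seen


def ancestors(ontology: Ontology, start: TermID,
              predicates: Iterable[Predicate] = HIERARCHY) -> set[TermID]:
    """Reflexive-transitive closure forward along the given edge types."""
    preds = frozenset(predicates)
    seen = {start}
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for rel in ontology.out_edges(node, preds):
            if rel.object not in seen:
                seen.add(rel.object)
                frontier.append(rel.object)
    return seen


def _finish_resolution(ontology: Ontology, tid: TermID) -> TermID:
    term = ontology.terms.get(tid)
    if term is not None and term.is_obsolete:
        if term.replaced_by is not None:
            return term.replaced_by
        raise ObsoleteTermError(tid, term.consider)
    return tid


def resolve(ontology: Ontology, query: str) -> TermID:
    """Resolve a user query to a term id.

    Exact-match priority: live id > alt_id > name > exact synonym
    (including PLURAL synonyms). An alt_id resolves to the merge survivor
    carrying it. A hit on an obsolete term follows ``replaced_by`` when
    present and otherwise raises :class:`ObsoleteTermError` listing any
    ``consider`` candidates.
    """
    ontology._reindex()
    try:
        tid = TermID.parse(query)
    except ValueError:
        tid = None
    if tid is not None:
        if tid in ontology.terms:
            return _finish_resolution(ontology, tid)
        if tid in ontology._alt_ids:
            return _finish_resolution(ontology, ontology._alt_ids[tid])
    for index in (ontology._by_name, ontology._by_synonym):
        hits = [t for t in index.get(query, [])
                if not ontology.terms[t].is_obsolete]
        if not hits:
            # allow an obsolete name hit to surface its replacement
            hits = index.get(query, [])
        hits = sorted(set(hits))
        if len(hits) > 1:
            raise AmbiguousQueryError(query, hits)
        if hits:
            return _finish_resolution(ontology, hits[0])
    raise TermNotFoundError(query)


_MACRO_KEY = "treat-xrefs-as-genus-differentia"


def derive_bridge_axioms(ontology: Ontology
                         ) -> list[tuple[TermID, TermID, Predicate, TermID]]:
    """Expand ``treat-xrefs-as-genus-differentia`` header macros.

    A macro ``CL part_of NCBITaxon:7955`` means: every term carrying an
    xref with prefix ``CL`` is equivalent to (that xref AND part_of
    ``NCBITaxon:7955``). One axiom ``(term, genus-xref, relation, filler)``
    is emitted per matching (term, xref) pair.
    """
    axioms: list[tuple[TermID, TermID, Predicate, TermID]] = []
    for clause in ontology.header.get(_MACRO_KEY, []):
        parts = clause.split()
        if len(parts) != 3:
            raise ConfigError(f"unparseable {_MACRO_KEY} clause: {clause!r}")
        prefix, rel_name, filler_text = parts
        try:
            rel = Predicate.from_name(rel_name)
            filler = TermID.parse(filler_text)
        except (KeyError, ValueError) as exc:
            raise ConfigError(
                f"unparseable {_MACRO_KEY} clause: {clause!r}") from exc
        for term in sorted(ontology.live_terms(), key=lambda t: t.id):
            for xref in sorted(term.xrefs):
                if xref.prefix == prefix:
                    axioms.append((term.id, xref, rel, filler))
    return axioms


def clone_with_prefix(ontology: Ontology, old_prefix: str,
                      new_prefix: str) -> Ontology:
    """Clone the ontology under a new id prefix.

    Every id with ``old_prefix`` is rewritten to ``new_prefix`` with the
    local number preserved, and each rewritten term gains an xref back to
    its original id (the cross-reference trail a derived ontology keeps to
    its seed). Terms with other prefixes are untouched.
    """
    present = {t.prefix for t in ontology.terms}
    if old_prefix not in present:
        raise TermNotFoundError(f"no term uses prefix {old_prefix!r}")
    if new_prefix != old_prefix and new_prefix in present:
        raise PrefixCollisionError(
            f"prefix {new_prefix!r} is already in use")

    def rewrite(tid: TermID) -> TermID:
        if tid.prefix == old_prefix:
            return TermID(new_prefix, tid.local)
        return tid

    clone = Ontology(header=ontology.header,
                     extra_stanzas=ontology.extra_stanzas)
    for term in ontology.terms.values():
        new_id = rewrite(term.id)
        xrefs = list(term.xrefs)
        if new_id != term.id and term.id not in xrefs:
            xrefs = xrefs + [term.id]
        clone.add_term(replace(
            term,
            id=new_id,
            xrefs=xrefs,
            alt_ids=[rewrite(a) for a in term.alt_ids],
            replaced_by=(rewrite(term.replaced_by)
                         if term.replaced_by else None),
            consider=[rewrite(c) for c in term.consider],
            synonyms=list(term.synonyms),
            extra_tags=list(term.extra_tags),
        ))
    for rel in ontology.relationships:
        clone.add_relationship(Relationship(
            rewrite(rel.subject), rel.predicate, rewrite(rel.object)))
    return clone
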