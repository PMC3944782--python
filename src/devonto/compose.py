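"""Post-composed classes: a genus term restricted by part_of to an anatomy term.

Rather than pre-enumerating every describable structure, curators build
classes on the fly as ``'X' that part_of some 'Y'`` where Y is an anatomy
class and X comes from the anatomy ontology itself or from a partner
ontology (spatial regions, cellular components, pathology terms, cell
types). Only the part_of relation is used, which keeps composites
logically consistent with the ontology graph: a placed composite is a
child of its genus and a part of its filler, so partonomy-driven query
expansion retrieves it beneath the filler.

External genus terms are held as opaque labelled ids; their home
hierarchies are not imported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import CompositionError, RenderError
from .model import (
    Ontology,
    OntologyTerm,
    Predicate,
    Relationship,
    TermID,
    ancestors,
)

#: id prefix of synthesized composite pseudo-terms in working graphs
COMPOSITE_PREFIX = "POST"


@dataclass(frozen=True)
class SourceRegistry:
    """Maps id prefixes to post-composition dialects.

    ``anatomy_prefixes`` are prefixes of the anatomy ontology itself
    (valid as filler and as genus); ``genus_sources`` maps external
    prefixes to their dialect label.
    """

    anatomy_prefixes: frozenset[str] = frozenset({"ZFA", "TEST"})
    genus_sources: Mapping[str, str] = field(default_factory=lambda: {
        "BSPO": "BSPO", "GO": "GO-CC", "MPATH": "MPATH", "CL": "CL"})

    def genus_source_of(self, genus: TermID) -> str:
        if genus.prefix in self.anatomy_prefixes:
            return "ZFA"
        try:
            return self.genus_sources[genus.prefix]
        except KeyError:
            raise CompositionError(
                f"unsupported post-composition dialect for genus prefix "
                f"{genus.prefix!r}") from None


DEFAULT_REGISTRY = SourceRegistry()


@dataclass(frozen=True, order=True)
class CompositeEntity:
    """``'genus' that part_of some 'filler'`` (depth-1, part_of only)."""

    genus: TermID
    filler: TermID
    genus_source: str = "ZFA"
    filler_source: str = "ZFA"

    @property
    def id(self) -> TermID:
        """Deterministic pseudo-id for use in working graphs and indexes."""
        local = (f"{self.genus.prefix}_{self.genus.local}"
                 f"__{self.filler.prefix}_{self.filler.local}")
        return TermID(COMPOSITE_PREFIX, local)


def compose(genus: TermID, filler: TermID,
            registry: SourceRegistry = DEFAULT_REGISTRY) -> CompositeEntity:
    """Build the canonical composite for a (genus, filler) pair.

    Composition is pure: equal inputs give equal (interchangeable)
    composites. The filler must be an anatomy-ontology class and
    self-composition is rejected.
    """
    if filler.prefix not in registry.anatomy_prefixes:
        raise CompositionError(
            f"filler {filler.curie} is not an anatomy-ontology class")
    if genus == filler:
        raise CompositionError(
            f"cannot compose {genus.curie} with itself")
    return CompositeEntity(genus, filler, registry.genus_source_of(genus))


def render_manchester(c: CompositeEntity,
                      names: Mapping[TermID, str]) -> str:
    """Render ``'<genus name>' that part_of some '<filler name>'``."""
    try:
        g, f = names[c.genus], names[c.filler]
    except KeyError as exc:
        raise RenderError(f"no name for {exc.args[0]}") from None
    return f"'{g}' that part_of some '{f}'"


def place(c: CompositeEntity, onto: Ontology) -> list[Relationship]:
    """Placement edges making the composite searchable.

    Two edges per composite: ``composite is_a genus`` (a cross-ontology
    subtype edge when the genus is external) and ``composite part_of
    filler``, which makes the composite a descendant of the filler for
    query expansion.
    """
    return [
        Relationship(c.id, Predicate.IS_A, c.genus),
        Relationship(c.id, Predicate.PART_OF, c.filler),
    ]


def extend_ontology(onto: Ontology, composites: Iterable[CompositeEntity],
                    labels: Mapping[TermID, str] | None = None) -> Ontology:
    """Working graph: the ontology plus placed composite pseudo-terms.

    External genus ids absent from the ontology are added as opaque
    labelled nodes so placement edges resolve.
    """
    labels = labels or {}
    ext = Ontology(header=onto.header,
                   terms=onto.terms.values(),
                   relationships=onto.relationships,
                   extra_stanzas=onto.extra_stanzas)
    for c in sorted(set(composites)):
        if c.genus not in ext:
            ext.add_term(OntologyTerm(
                id=c.genus, name=labels.get(c.genus, c.genus.curie)))
        if c.id in ext:
            raise CompositionError(
                f"composite id collision at {c.id.curie}")
        gname = (ext[c.genus].name or c.genus.curie)
        fname = (ext[c.filler].name or c.filler.curie)
        ext.add_term(OntologyTerm(
            id=c.id, name=f"{gname} part_of {fname}"))
        for rel in place(c, ext):
            ext.add_relationship(rel)
    return ext


def closure(composites: Iterable[CompositeEntity], onto: Ontology
            ) -> dict[CompositeEntity, set[TermID]]:
    """Reflexive-transitive is_a/part_of ancestor set of each composite.

    The closure of a placed composite contains the composite itself, its
    genus and every genus ancestor, and its filler and every filler
    ancestor; it is the dual of descendant-based query expansion
    (``x in closure(c)`` iff ``c in descendants(x)``).
    """
    composites = sorted(set(composites))
    ext = extend_ontology(onto, composites)
    return {c: ancestors(ext, c.id) for c in composites}
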