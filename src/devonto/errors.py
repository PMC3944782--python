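"""Exception hierarchy.

All failures raised by the package derive from :class:`DevontoError` so
callers (and the CLI) can catch one base class. Parse-time errors carry
enough position information (stanza id, line number) to locate the
offending text in the source file.
"""

from __future__ import annotations


class DevontoError(Exception):
    """Base class for all errors raised by devonto."""


class OboParseError(DevontoError):
    """Malformed OBO flat-file content."""

    def __init__(self, message: str, *, stanza: str | None = None,
                 line: int | None = None):
        self.stanza = stanza
        self.line = line
        where = []
        if stanza is not None:
            where.append(f"stanza {stanza!r}")
        if line is not None:
            where.append(f"line {line}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


class DuplicateIdError(OboParseError):
    """Two live stanzas carry the same id, or a live id collides with an alt_id."""


class UnknownPredicateError(OboParseError):
    """A relationship line names a predicate outside the supported six."""


class IsACycleError(OboParseError):
    """The is_a graph over non-obsolete terms contains a cycle."""


class TermNotFoundError(DevontoError, KeyError):
    """A query or id did not resolve to any term."""


class AmbiguousQueryError(DevontoError):
    """A name/synonym query matched more than one live term."""

    def __init__(self, query: str, candidates):
        self.query = query
        self.candidates = list(candidates)
        listing = ", ".join(str(c) for c in self.candidates)
        super().__init__(f"query {query!r} is ambiguous between: {listing}")


class ObsoleteTermError(DevontoError):
    """A query resolved to an obsolete term with no replacement."""

    def __init__(self, term_id, consider=()):
        self.term_id = term_id
        self.consider = list(consider)
        msg = f"term {term_id} is obsolete"
        if self.consider:
            msg += "; consider: " + ", ".join(str(c) for c in self.consider)
        super().__init__(msg)


class PrefixCollisionError(DevontoError):
    """Prefix cloning would collide with an existing id prefix."""


class ConfigError(DevontoError):
    """Malformed header macro or validation configuration."""


class StageSeriesError(DevontoError):
    """The stage ontology does not form a single well-ordered leaf chain."""


class IntervalError(DevontoError):
    """Base class for stage-interval extraction failures."""

    def __init__(self, message: str, term_id=None):
        self.term_id = term_id
        super().__init__(message)


class SuperStageFillerError(IntervalError):
    """A start_stage/end_stage object is a super-stage, not a leaf."""


class IncompleteStagesError(IntervalError):
    """Both interval sides are unknown or stage relations are missing."""


class InvertedIntervalError(IntervalError):
    """The start stage comes after the end stage."""


class UnknownStageError(IntervalError):
    """A stage filler id is absent from the stage series."""


class CompositionError(DevontoError):
    """Illegal post-composition request."""


class RenderError(DevontoError):
    """A name needed for rendering is missing."""


class AnnotationError(DevontoError):
    """A row of an annotation file could not be interpreted."""

    def __init__(self, message: str, *, row: int | None = None,
                 column: str | None = None):
        self.row = row
        self.column = column
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column {column!r}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


class IndexingError(DevontoError):
    """An annotation record could not be placed in the search index."""


class GenerationError(DevontoError):
    """Infeasible synthetic-ontology generator parameters."""


class InjectionError(DevontoError):
    """A requested violation could not be injected into the bundle."""
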