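"""Reader and writer for the OBO flat-file 1.2 dialect.

Supported [Term] tags: id, name, namespace, def, synonym, xref, alt_id,
is_a, relationship, is_obsolete, replaced_by, consider. All other tags are
preserved verbatim and round-tripped. Non-[Term] stanzas (e.g. [Typedef])
are kept as opaque text blocks. Header directives handled structurally:
format-version, data-version, synonymtypedef,
treat-xrefs-as-genus-differentia; other header lines are kept as (key,
value) pairs.

The writer is deterministic: stanzas sorted by id, canonical tag order,
LF line endings, UTF-8. ``write_obo(parse_obo(write_obo(o))) ==
write_obo(o)`` for any ontology ``o``.
"""

from __future__ import annotations

from .errors import IsACycleError, OboParseError, UnknownPredicateError
from .model import (
    Definition,
    Ontology,
    OntologyTerm,
    Predicate,
    Relationship,
    Synonym,
    SynonymScope,
    TermID,
)

_KNOWN_TAGS = {
    "id", "name", "namespace", "def", "synonym", "xref", "alt_id",
    "is_a", "relationship", "is_obsolete", "replaced_by", "consider",
}

_SCOPES = {s.value for s in SynonymScope}


def _strip_comment(value: str) -> str:
    """Cut an unquoted trailing ``! ...`` comment."""
    in_quote = False
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\":
            i += 2
            continue
        if c == '"':
            in_quote = not in_quote
        elif c == "!" and not in_quote:
            return value[:i].rstrip()
        i += 1
    return value.rstrip()


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _parse_quoted(value: str, *, stanza: str | None, line: int) -> tuple[str, str]:
    value = value.lstrip()
    if not value.startswith('"'):
        raise OboParseError("expected a quoted string", stanza=stanza, line=line)
    i = 1
    out = []
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            out.append(value[i + 1])
            i += 2
            continue
        if c == '"':
            return "".join(out), value[i + 1:].strip()
        out.append(c)
        i += 1
    raise OboParseError("unterminated quoted string", stanza=stanza, line=line)


def _parse_bracket_list(rest: str) -> tuple[tuple[str, ...], str]:
    rest = rest.lstrip()
    if not rest.startswith("["):
        return (), rest
    close = rest.index("]")
    inner = rest[1:close].strip()
    items = tuple(x.strip() for x in inner.split(",") if x.strip()) if inner else ()
    return items, rest[close + 1:].strip()


def _parse_id(text: str, *, stanza: str | None, line: int,
              canonical: bool = True) -> TermID:
    try:
        return TermID.parse(text, require_canonical=canonical)
    except ValueError as exc:
        raise OboParseError(str(exc), stanza=stanza, line=line) from None


def parse_obo(text: str) -> Ontology:
    """Parse OBO flat-file content into an :class:`Ontology`.

    Raises :class:`OboParseError` (with stanza id and line number) for a
    stanza without an id, a duplicate live id, or a relationship line whose
    predicate is not one of the six supported relations; an is_a cycle over
    live terms raises :class:`IsACycleError`.
    """
    onto = Ontology()
    lines = text.splitlines()

    # header: everything before the first stanza marker
    i = 0
    while i < len(lines) and not lines[i].lstrip().startswith("["):
        raw = lines[i].strip()
        i += 1
        if not raw or raw.startswith("!"):
            continue
        if ":" not in raw:
            raise OboParseError(f"malformed header line {raw!r}", line=i)
        key, _, value = raw.partition(":")
        onto.header.setdefault(key.strip(), []).append(value.strip())

    # stanzas
    while i < len(lines):
        marker = lines[i].strip()
        start = i
        i += 1
        body: list[tuple[int, str]] = []
        while i < len(lines) and not lines[i].lstrip().startswith("["):
            if lines[i].strip():
                body.append((i + 1, lines[i].strip()))
            i += 1
        if marker != "[Term]":
            block = [marker] + [raw for _, raw in body]
            onto.extra_stanzas.append("\n".join(block))
            continue
        _parse_term_stanza(onto, body, start_line=start + 1)

    if not onto.is_a_is_acyclic():
        raise IsACycleError("is_a graph over non-obsolete terms has a cycle")
    return onto


def _parse_term_stanza(onto: Ontology, body: list[tuple[int, str]],
                       start_line: int) -> None:
    term_id: TermID | None = None
    fields: dict = {
        "name": "", "namespace": None, "definition": None,
        "synonyms": [], "xrefs": [], "alt_ids": [],
        "is_obsolete": False, "replaced_by": None, "consider": [],
        "extra_tags": [],
    }
    rels: list[Relationship] = []
    stanza_label: str | None = None

    for lineno, raw in body:
        if ":" not in raw:
            raise OboParseError(f"malformed tag line {raw!r}",
                                stanza=stanza_label, line=lineno)
        tag, _, value = raw.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag not in _KNOWN_TAGS:
            fields["extra_tags"].append((tag, value))
            continue
        value = _strip_comment(value)
        if tag == "id":
            term_id = _parse_id(value, stanza=None, line=lineno)
            stanza_label = term_id.curie
        elif tag == "name":
            fields["name"] = value
        elif tag == "namespace":
            fields["namespace"] = value
        elif tag == "def":
            dtext, rest = _parse_quoted(value, stanza=stanza_label, line=lineno)
            xrefs, _ = _parse_bracket_list(rest)
            fields["definition"] = Definition(dtext, xrefs)
        elif tag == "synonym":
            stext, rest = _parse_quoted(value, stanza=stanza_label, line=lineno)
            tokens = rest.split("[", 1)[0].split()
            scope = SynonymScope.EXACT
            syn_type = None
            if tokens and tokens[0] in _SCOPES:
                scope = SynonymScope(tokens[0])
                tokens = tokens[1:]
            if tokens:
                syn_type = tokens[0]
            xrefs, _ = _parse_bracket_list(rest[rest.index("["):]
                                           if "[" in rest else "")
            try:
                fields["synonyms"].append(
                    Synonym(stext, scope, syn_type, xrefs))
            except ValueError as exc:
                raise OboParseError(str(exc), stanza=stanza_label,
                                    line=lineno) from None
        elif tag == "xref":
            # an xref may carry a quoted label after the id; keep the id
            fields["xrefs"].append(_parse_id(value.split()[0],
                                             stanza=stanza_label,
                                             line=lineno, canonical=False))
        elif tag == "alt_id":
            fields["alt_ids"].append(_parse_id(value, stanza=stanza_label,
                                               line=lineno))
        elif tag == "is_obsolete":
            fields["is_obsolete"] = value.lower() == "true"
        elif tag == "replaced_by":
            fields["replaced_by"] = _parse_id(value, stanza=stanza_label,
                                              line=lineno)
        elif tag == "consider":
            fields["consider"].append(_parse_id(value, stanza=stanza_label,
                                                line=lineno))
        elif tag == "is_a":
            obj = _parse_id(value, stanza=stanza_label, line=lineno)
            rels.append((Predicate.IS_A, obj, lineno))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"malformed relationship line {raw!r}",
                                    stanza=stanza_label, line=lineno)
            try:
                pred = Predicate.from_name(parts[0])
            except KeyError:
                raise UnknownPredicateError(
                    f"unsupported predicate {parts[0]!r}",
                    stanza=stanza_label, line=lineno) from None
            rels.append((pred, _parse_id(parts[1], stanza=stanza_label,
                                         line=lineno), lineno))

    if term_id is None:
        first = body[0][0] if body else start_line
        raise OboParseError("[Term] stanza without an id tag", line=first)
    onto.add_term(OntologyTerm(id=term_id, **fields))
    for pred, obj, _ in rels:
        onto.add_relationship(Relationship(term_id, pred, obj))


def write_obo(ontology: Ontology) -> str:
    """Serialize an :class:`Ontology` deterministically (sorted by id)."""
    out: list[str] = []

    def header_lines(key):
        for value in ontology.header.get(key, []):
            out.append(f"{key}: {value}")

    emitted = {"format-version", "data-version", "synonymtypedef",
               "treat-xrefs-as-genus-differentia"}
    if "format-version" not in ontology.header:
        out.append("format-version: 1.2")
    header_lines("format-version")
    header_lines("data-version")
    header_lines("synonymtypedef")
    header_lines("treat-xrefs-as-genus-differentia")
    for key in sorted(k for k in ontology.header if k not in emitted):
        header_lines(key)

    for term in sorted(ontology.terms.values(), key=lambda t: t.id):
        out.append("")
        out.append("[Term]")
        out.append(f"id: {term.id.curie}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        if term.definition is not None:
            xr = ", ".join(term.definition.xrefs)
            out.append(f'def: "{_escape(term.definition.text)}" [{xr}]')
        for syn in sorted(term.synonyms):
            parts = [f'synonym: "{_escape(syn.text)}"', syn.scope.value]
            if syn.synonym_type:
                parts.append(syn.synonym_type)
            parts.append("[" + ", ".join(syn.xrefs) + "]")
            out.append(" ".join(parts))
        for xref in sorted(term.xrefs):
            out.append(f"xref: {xref.curie}")
        for alt in sorted(term.alt_ids):
            out.append(f"alt_id: {alt.curie}")
        rels = sorted(r for r in ontology.out_edges(term.id))
        for rel in rels:
            if rel.predicate is Predicate.IS_A:
                out.append(f"is_a: {rel.object.curie}")
        for rel in rels:
            if rel.predicate is not Predicate.IS_A:
                out.append(
                    f"relationship: {rel.predicate.value} {rel.object.curie}")
        if term.is_obsolete:
            out.append("is_obsolete: true")
        if term.replaced_by is not None:
            out.append(f"replaced_by: {term.replaced_by.curie}")
        for c in sorted(term.consider):
            out.append(f"consider: {c.curie}")
        for tag, value in term.extra_tags:
            out.append(f"{tag}: {value}")

    for stanza in ontology.extra_stanzas:
        out.append("")
        out.append(stanza)
    return "\n".join(out) + "\n"


def structurally_equal(a: Ontology, b: Ontology) -> bool:
    """Same term set (all fields), relationship multiset and header macros."""
    if sorted(a.terms) != sorted(b.terms):
        return False
    for tid in a.terms:
        if a.terms[tid] != b.terms[tid]:
            return False
    if sorted(a.relationships) != sorted(b.relationships):
        return False
    key = "treat-xrefs-as-genus-differentia"
    return sorted(a.header.get(key, [])) == sorted(b.header.get(key, []))
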