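"""Release-gate consistency checks over an anatomy ontology + stage series.

Five check families are run before a release:

* ``SUB-STAGE`` — an ``is_a`` child's existence window must lie within its
  parent's window.
* ``PART-STAGE`` — the same containment over the partonomy (``part_of``).
* ``DF-JUNCTION`` — a structure must start during (overlapping) or one
  stage after (abutting) the end of the structure it develops from; a gap
  or a premature start is flagged.
* ``STAGE-COMPLETE`` / ``STAGE-LEAF`` — every anatomical class needs a
  known start or end stage, and stage fillers must be leaf stages, never
  super-stages.
* ``META-*`` — editorial policy: definitions required (``META-DEF``),
  obsolete classes must carry no relationships and valid replacements
  (``META-OBS``), class names are singular (``META-SINGULAR``, heuristic).

Containment checks walk asserted direct edges only; a term violating its
grandparent is caught when the intermediate edge is checked, which keeps
the blame local to one edge per report. Unknown interval sides are
permissive throughout: a violation is reported only when provable from
known ordinals.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import (
    ConfigError,
    IncompleteStagesError,
    IntervalError,
    InvertedIntervalError,
    SuperStageFillerError,
    UnknownStageError,
)
from .model import Ontology, Predicate, TermID
from .stages import (
    StageInterval,
    StageSeries,
    TemporalRelation,
    build_stage_series,
    contains,
    interval_of,
    junction,
)


class Rule(str, enum.Enum):
    SUB_STAGE = "SUB-STAGE"
    PART_STAGE = "PART-STAGE"
    DF_JUNCTION = "DF-JUNCTION"
    STAGE_COMPLETE = "STAGE-COMPLETE"
    STAGE_LEAF = "STAGE-LEAF"
    META_DEF = "META-DEF"
    META_OBS = "META-OBS"
    META_SINGULAR = "META-SINGULAR"
    EXPR_STAGE = "EXPR-STAGE"  # annotation-gating, never blocks the ontology


class Severity(str, enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


_DEFAULT_SEVERITY = {
    Rule.SUB_STAGE: Severity.ERROR,
    Rule.PART_STAGE: Severity.ERROR,
    Rule.DF_JUNCTION: Severity.ERROR,
    Rule.STAGE_COMPLETE: Severity.ERROR,
    Rule.STAGE_LEAF: Severity.ERROR,
    Rule.META_DEF: Severity.WARNING,
    Rule.META_OBS: Severity.ERROR,
    Rule.META_SINGULAR: Severity.WARNING,
    Rule.EXPR_STAGE: Severity.ERROR,
}


@dataclass
class Violation:
    rule_id: Rule
    subject: TermID
    related: tuple[TermID, ...]
    severity: Severity
    message: str

    def sort_key(self):
        return (self.rule_id.value, self.subject.curie,
                tuple(t.curie for t in self.related))


@dataclass
class ValidationConfig:
    """Per-rule severity overrides and exemptions.

    ``premature_is_warning`` downgrades PREMATURE develops_from junctions
    (successor starting before the predecessor ends) from ERROR to
    WARNING, for curation styles where an extended overlap is tolerated.
    ``ignore`` maps a rule id to subject ids exempted from that rule.
    """

    severity_overrides: dict[Rule, Severity] = field(default_factory=dict)
    premature_is_warning: bool = False
    ignore: dict[Rule, set[TermID]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, text: str) -> "ValidationConfig":
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"bad YAML: {exc}") from exc
        try:
            overrides = {Rule(k): Severity(v)
                         for k, v in (data.get("severity") or {}).items()}
            ignore = {Rule(k): {TermID.parse(t) for t in v}
                      for k, v in (data.get("ignore") or {}).items()}
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        return cls(severity_overrides=overrides,
                   premature_is_warning=bool(
                       data.get("premature_is_warning", False)),
                   ignore=ignore)

    def severity_for(self, rule: Rule) -> Severity:
        return self.severity_overrides.get(rule, _DEFAULT_SEVERITY[rule])

    def is_ignored(self, rule: Rule, subject: TermID) -> bool:
        return subject in self.ignore.get(rule, ())


@dataclass
class QCReport:
    ontology_version: str
    violations: list[Violation]
    counts: dict[str, int]
    passed: bool

    def to_json(self) -> str:
        return json.dumps({
            "ontology_version": self.ontology_version,
            "passed": self.passed,
            "counts": dict(sorted(self.counts.items())),
            "violations": [
                {"rule_id": v.rule_id.value, "subject": v.subject.curie,
                 "related": [t.curie for t in v.related],
                 "severity": v.severity.value, "message": v.message}
                for v in self.violations],
        }, indent=2, sort_keys=True) + "\n"

    def to_tsv(self) -> str:
        lines = ["rule_id\tsubject\trelated\tseverity\tmessage"]
        for v in self.violations:
            related = ",".join(t.curie for t in v.related)
            lines.append(f"{v.rule_id.value}\t{v.subject.curie}\t{related}"
                         f"\t{v.severity.value}\t{v.message}")
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        lines = [f"ontology version: {self.ontology_version}",
                 f"violations: {len(self.violations)}"]
        for v in self.violations:
            lines.append(f"  [{v.severity.value}] {v.rule_id.value} "
                         f"{v.subject.curie}: {v.message}")
        lines.append("PASSED" if self.passed else "FAILED")
        return "\n".join(lines) + "\n"


def _interval_map(onto: Ontology, series: StageSeries,
                  config: ValidationConfig
                  ) -> tuple[dict[TermID, StageInterval], list[Violation]]:
    """Per-term intervals; extraction failures become stage violations."""
    intervals: dict[TermID, StageInterval] = {}
    violations: list[Violation] = []

    def flag(rule: Rule, tid: TermID, message: str):
        if not config.is_ignored(rule, tid):
            violations.append(Violation(rule, tid, (),
                                        config.severity_for(rule), message))

    for term in onto.live_terms():
        try:
            intervals[term.id] = interval_of(onto, series, term.id)
        except SuperStageFillerError as exc:
            flag(Rule.STAGE_LEAF, term.id, str(exc))
        except (IncompleteStagesError, InvertedIntervalError,
                UnknownStageError) as exc:
            flag(Rule.STAGE_COMPLETE, term.id, str(exc))
        except IntervalError as exc:
            flag(Rule.STAGE_COMPLETE, term.id, str(exc))
    return intervals, violations


def _check_containment(onto: Ontology, series: StageSeries, rule: Rule,
                       predicate: Predicate, config: ValidationConfig,
                       intervals: dict[TermID, StageInterval] | None = None,
                       ) -> list[Violation]:
    if intervals is None:
        intervals, _ = _interval_map(onto, series, config)
    label = "is_a parent" if predicate is Predicate.IS_A else "whole"
    out = []
    for rel in onto.relationships:
        if rel.predicate is not predicate:
            continue
        child = intervals.get(rel.subject)
        parent = intervals.get(rel.object)
        if child is None or parent is None:
            continue  # extraction failure already reported separately
        if contains(parent, child):
            continue
        if config.is_ignored(rule, rel.subject):
            continue
        msg = (f"'{_name(onto, rel.subject)}' ({child.render(series)}) is "
               f"not contained in the window of its {label} "
               f"'{_name(onto, rel.object)}' ({parent.render(series)})")
        out.append(Violation(rule, rel.subject, (rel.object,),
                             config.severity_for(rule), msg))
    return out


def _name(onto: Ontology, tid: TermID) -> str:
    term = onto.terms.get(tid)
    return term.name if term is not None and term.name else tid.curie


def check_subclass_stages(onto: Ontology, series: StageSeries,
                          config: ValidationConfig | None = None
                          ) -> list[Violation]:
    """Child classes must exist within their is_a parent's stage window."""
    return _check_containment(onto, series, Rule.SUB_STAGE, Predicate.IS_A,
                              config or ValidationConfig())


def check_partonomy_stages(onto: Ontology, series: StageSeries,
                           config: ValidationConfig | None = None
                           ) -> list[Violation]:
    """Parts must exist within the stage window of their whole."""
    return _check_containment(onto, series, Rule.PART_STAGE,
                              Predicate.PART_OF, config or ValidationConfig())


def check_develops_from(onto: Ontology, series: StageSeries,
                        config: ValidationConfig | None = None,
                        intervals: dict[TermID, StageInterval] | None = None,
                        ) -> list[Violation]:
    """A structure must start overlapping or abutting its progenitor's end."""
    config = config or ValidationConfig()
    if intervals is None:
        intervals, _ = _interval_map(onto, series, config)
    out = []
    for rel in onto.relationships:
        if rel.predicate is not Predicate.DEVELOPS_FROM:
            continue
        succ = intervals.get(rel.subject)
        pred = intervals.get(rel.object)
        if succ is None or pred is None:
            continue
        kind = junction(pred, succ)
        if kind in (TemporalRelation.OVERLAPPING, TemporalRelation.ABUTTING,
                    TemporalRelation.UNDETERMINED):
            continue
        if config.is_ignored(Rule.DF_JUNCTION, rel.subject):
            continue
        severity = config.severity_for(Rule.DF_JUNCTION)
        if kind is TemporalRelation.PREMATURE and config.premature_is_warning:
            severity = Severity.WARNING
        msg = (f"{kind.value}: '{_name(onto, rel.subject)}' starts at "
               f"{series.name_of(succ.start)} but develops_from "
               f"'{_name(onto, rel.object)}' ending at "
               f"{series.name_of(pred.end)}")
        out.append(Violation(Rule.DF_JUNCTION, rel.subject, (rel.object,),
                             severity, msg))
    return out


def check_stage_completeness(onto: Ontology, series: StageSeries,
                             config: ValidationConfig | None = None
                             ) -> list[Violation]:
    """Every class needs a known stage side, tied to leaf stages only."""
    _, violations = _interval_map(onto, series, config or ValidationConfig())
    return violations


_PLURAL_OK_SUFFIXES = ("ss", "us", "is", "os")


def _looks_plural(name: str) -> bool:
    last = name.split()[-1].lower() if name.split() else ""
    return (last.endswith("s") and len(last) > 2
            and not last.endswith(_PLURAL_OK_SUFFIXES))


def check_metadata_policy(onto: Ontology,
                          config: ValidationConfig | None = None
                          ) -> list[Violation]:
    """Definitions required; obsoletes inert; names singular (heuristic)."""
    config = config or ValidationConfig()
    out = []

    def flag(rule, tid, related, message):
        if not config.is_ignored(rule, tid):
            out.append(Violation(rule, tid, related,
                                 config.severity_for(rule), message))

    for term in onto.terms.values():
        if term.is_obsolete:
            rels = onto.out_edges(term.id)
            if rels:
                flag(Rule.META_OBS, term.id,
                     tuple(sorted({r.object for r in rels})),
                     f"obsolete term '{_name(onto, term.id)}' retains "
                     f"{len(rels)} relationship(s)")
            if term.replaced_by is not None:
                target = onto.terms.get(term.replaced_by)
                if target is None or target.is_obsolete:
                    flag(Rule.META_OBS, term.id, (term.replaced_by,),
                         f"replaced_by of {term.id.curie} points at "
                         f"{'an obsolete' if target else 'an unknown'} term "
                         f"{term.replaced_by.curie}")
            continue
        if term.definition is None or not term.definition.text:
            flag(Rule.META_DEF, term.id, (),
                 f"'{_name(onto, term.id)}' has no definition")
        if _looks_plural(term.name) and not any(
                s.synonym_type == "PLURAL" for s in term.synonyms):
            flag(Rule.META_SINGULAR, term.id, (),
                 f"name '{term.name}' looks plural; class names are "
                 "singular (use a PLURAL synonym for the plural form)")
    return out


def validate(onto: Ontology, stage_onto: Ontology,
             config: ValidationConfig | None = None) -> QCReport:
    """Run every release-gate check and aggregate a deterministic report.

    ``passed`` is true iff no ERROR-severity violation was found. A stage
    series that cannot be built (branching/cyclic/disconnected chain)
    aborts with :class:`StageSeriesError` — the ontology cannot be
    meaningfully checked without a total stage order.
    """
    config = config or ValidationConfig()
    series = build_stage_series(stage_onto)
    intervals, violations = _interval_map(onto, series, config)
    violations = list(violations)
    violations += _check_containment(onto, series, Rule.SUB_STAGE,
                                     Predicate.IS_A, config, intervals)
    violations += _check_containment(onto, series, Rule.PART_STAGE,
                                     Predicate.PART_OF, config, intervals)
    violations += check_develops_from(onto, series, config, intervals)
    violations += check_metadata_policy(onto, config)
    violations.sort(key=Violation.sort_key)
    counts: dict[str, int] = {}
    for v in violations:
        counts[v.rule_id.value] = counts.get(v.rule_id.value, 0) + 1
    version = (onto.header.get("data-version") or ["unknown"])[0]
    passed = not any(v.severity is Severity.ERROR for v in violations)
    return QCReport(version, violations, counts, passed)
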