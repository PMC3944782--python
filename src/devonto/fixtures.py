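"""Programmatic mini-ontologies, annotation sets, and randomized bundles.

Three hand-built bundles encode canonical worked examples of the model:

* :func:`heart_fixture` — the heart developmental chain (primitive heart
  tube -> heart tube -> heart) with one overlapping and one abutting
  stage junction.
* :func:`neural_ap_fixture` — anterior/posterior progression of the
  midline neural tissue (plate -> keel -> rod -> tube), each structure
  with spatially localized part_of children whose windows nest in the
  parent's.
* :func:`swim_bladder_fixture` — the swim-bladder partonomy with the
  expression and phenotype records used to illustrate query expansion,
  including a post-composed (smooth muscle part_of tunica interna)
  entity.

:func:`generate_valid` emits seed-deterministic random ontologies that
pass every release-gate check, and :func:`inject_violations` mutates a
valid bundle to create an exact, independent set of known violations with
a ground-truth manifest.

Only ids printed in canonical reference material are reused (ZFS:0000000,
ZFS:0000029/31/32 and the ZFA ids of the worked examples); all invented
anatomy terms use the reserved ``TEST:`` prefix and invented stage terms
the ``TSTG:`` prefix, so fixtures can never collide with real ontology
ids.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .annotations import (
    Annotation,
    ExpressionAnnotation,
    PhenotypeAnnotation,
    write_annotations,
)
from .compose import CompositeEntity, compose
from .errors import GenerationError, InjectionError, IntervalError
from .model import (
    Definition,
    Ontology,
    OntologyTerm,
    Predicate,
    Relationship,
    TermID,
    ancestors,
)
from .obo import write_obo
from .stages import (
    StageInterval,
    StageSeries,
    build_stage_series,
    contains,
    interval_of,
    set_stage,
)


@dataclass
class FixtureBundle:
    """An anatomy + stage ontology pair with annotations and ground truth."""

    anatomy: Ontology
    stages: Ontology
    annotations: list[Annotation] = field(default_factory=list)
    composites: list[CompositeEntity] = field(default_factory=list)
    #: expected ERROR violations as (rule_id, subject); empty when valid
    manifest: list[tuple[str, TermID]] = field(default_factory=list)

    def series(self) -> StageSeries:
        return build_stage_series(self.stages)

    def write(self, directory: str | Path) -> None:
        """Write anatomy.obo, stages.obo, annotations.tsv, manifest.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "anatomy.obo").write_text(write_obo(self.anatomy),
                                               encoding="utf-8")
        (directory / "stages.obo").write_text(write_obo(self.stages),
                                              encoding="utf-8")
        (directory / "annotations.tsv").write_text(
            write_annotations(self.annotations, self.series()),
            encoding="utf-8")
        manifest = [[rule, tid.curie] for rule, tid in self.manifest]
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8")


# -- shared stage series ----------------------------------------------------

UNKNOWN_STAGE = TermID("ZFS", "0000000")

#: (name, id) of the standard fixture staging series, in order
STANDARD_STAGES: list[tuple[str, TermID]] = [
    ("Prim-5", TermID("ZFS", "0000029")),
    ("Prim-15", TermID("TSTG", "0000002")),
    ("Prim-25", TermID("ZFS", "0000031")),
    ("High-pec", TermID("ZFS", "0000032")),
    ("Long-pec", TermID("TSTG", "0000005")),
    ("Protruding-mouth", TermID("TSTG", "0000006")),
    ("Day 4", TermID("TSTG", "0000007")),
    ("Day 5", TermID("TSTG", "0000008")),
    ("Juvenile", TermID("TSTG", "0000009")),
    ("Adult", TermID("TSTG", "0000010")),
]

#: super-stage name -> (id, first member name, last member name)
_STANDARD_SUPERS = {
    "Pharyngula": (TermID("TSTG", "0000011"), "Prim-5", "High-pec"),
    "Larva": (TermID("TSTG", "0000012"), "Protruding-mouth", "Day 5"),
}


def _stage_term(onto: Ontology, tid: TermID, name: str) -> None:
    onto.add_term(OntologyTerm(
        id=tid, name=name,
        definition=Definition(f"The {name} developmental stage.")))


def standard_stage_ontology() -> Ontology:
    """Ten chained leaf stages, two super-stages, and the unknown sentinel."""
    onto = Ontology(header={"format-version": ["1.2"]})
    _stage_term(onto, UNKNOWN_STAGE, "unknown")
    by_name = {}
    for name, tid in STANDARD_STAGES:
        _stage_term(onto, tid, name)
        by_name[name] = tid
    for (_, earlier), (_, later) in zip(STANDARD_STAGES, STANDARD_STAGES[1:]):
        onto.add_relationship(Relationship(
            later, Predicate.IMMEDIATELY_PRECEDED_BY, earlier))
    names = [n for n, _ in STANDARD_STAGES]
    for sup_name, (sup_id, first, last) in _STANDARD_SUPERS.items():
        _stage_term(onto, sup_id, sup_name)
        for member in names[names.index(first):names.index(last) + 1]:
            onto.add_relationship(Relationship(
                by_name[member], Predicate.PART_OF, sup_id))
    return onto


def stage_id(name: str) -> TermID:
    """Leaf-stage id of the standard series by name."""
    for n, tid in STANDARD_STAGES:
        if n == name:
            return tid
    raise KeyError(name)


# -- hand-built bundles -----------------------------------------------------

def _add(onto: Ontology, tid: TermID, name: str, defn: str,
         start: TermID | None, end: TermID | None, *,
         is_a: list[TermID] = (), part_of: list[TermID] = (),
         develops_from: list[TermID] = ()) -> TermID:
    onto.add_term(OntologyTerm(id=tid, name=name,
                               definition=Definition(defn)))
    if start is not None:
        onto.add_relationship(Relationship(tid, Predicate.START_STAGE, start))
    if end is not None:
        onto.add_relationship(Relationship(tid, Predicate.END_STAGE, end))
    for obj in is_a:
        onto.add_relationship(Relationship(tid, Predicate.IS_A, obj))
    for obj in part_of:
        onto.add_relationship(Relationship(tid, Predicate.PART_OF, obj))
    for obj in develops_from:
        onto.add_relationship(Relationship(tid, Predicate.DEVELOPS_FROM, obj))
    return tid


ROOT = TermID("TEST", "0000001")

HEART = TermID("ZFA", "0000114")
HEART_TUBE = TermID("ZFA", "0000360")
PRIMITIVE_HEART_TUBE = TermID("ZFA", "0000149")
CAVITATED_COMPOUND_ORGAN = TermID("TEST", "0000002")
CARDIOVASCULAR_SYSTEM = TermID("TEST", "0000003")


def heart_fixture() -> FixtureBundle:
    """Heart development: overlapping then abutting stage junctions.

    The primitive heart tube ends at Prim-5, the stage during which the
    heart tube starts (overlapping); the heart tube ends at Prim-25 and
    the heart starts one stage later at High-pec (abutting). The heart is
    a cavitated compound organ and part of the cardiovascular system.
    """
    stages = standard_stage_ontology()
    a = Ontology(header={"format-version": ["1.2"],
                         "data-version": ["fixtures/heart"]})
    s = stage_id
    _add(a, ROOT, "anatomical structure",
         "Material anatomical entity with inherent 3D shape.",
         s("Prim-5"), s("Adult"))
    _add(a, CAVITATED_COMPOUND_ORGAN, "cavitated compound organ",
         "Organ containing one or more macroscopic cavities.",
         s("Prim-5"), s("Adult"), is_a=[ROOT])
    _add(a, CARDIOVASCULAR_SYSTEM, "cardiovascular system",
         "Anatomical system that circulates blood.",
         s("Prim-5"), s("Adult"), is_a=[ROOT])
    _add(a, PRIMITIVE_HEART_TUBE, "primitive heart tube",
         "Early midline tube formed by fusion of bilateral cardiac fields.",
         s("Prim-5"), s("Prim-5"), is_a=[ROOT])
    _add(a, HEART_TUBE, "heart tube",
         "Tubular heart primordium that loops and chambers.",
         s("Prim-5"), s("Prim-25"), is_a=[ROOT],
         develops_from=[PRIMITIVE_HEART_TUBE])
    _add(a, HEART, "heart",
         "Muscular pump of the cardiovascular system.",
         s("High-pec"), s("Adult"),
         is_a=[CAVITATED_COMPOUND_ORGAN], part_of=[CARDIOVASCULAR_SYSTEM],
         develops_from=[HEART_TUBE])
    return FixtureBundle(anatomy=a, stages=stages)


def neural_ap_fixture() -> FixtureBundle:
    """Anterior/posterior neural midline progression.

    Plate -> keel -> rod -> tube, with overlapping or abutting junctions;
    each structure has anterior/posterior part_of children whose windows
    nest inside the parent's, the anterior child starting no later than
    the posterior one (the posterior end of the axis lags by whole
    stages).
    """
    stages = standard_stage_ontology()
    a = Ontology(header={"format-version": ["1.2"],
                         "data-version": ["fixtures/neural"]})
    leaves = [tid for _, tid in STANDARD_STAGES]
    _add(a, ROOT, "anatomical structure",
         "Material anatomical entity with inherent 3D shape.",
         leaves[0], leaves[-1])

    # (name, local, window, develops_from local)
    chain = [
        ("neural plate", "0000010", (0, 2), None),
        ("neural keel", "0000013", (2, 4), "0000010"),   # overlapping
        ("neural rod", "0000016", (5, 7), "0000013"),    # abutting
        ("neural tube", "0000019", (7, 9), "0000016"),   # overlapping
    ]
    for name, local, (lo, hi), df in chain:
        tid = TermID("TEST", local)
        _add(a, tid, name, f"Midline neural tissue: the {name}.",
             leaves[lo], leaves[hi], is_a=[ROOT],
             develops_from=[TermID("TEST", df)] if df else [])
        mid = (lo + hi) // 2
        ant = TermID("TEST", f"{int(local) + 1:07d}")
        post = TermID("TEST", f"{int(local) + 2:07d}")
        _add(a, ant, f"anterior {name}",
             f"Anterior portion of the {name}.",
             leaves[lo], leaves[mid], is_a=[ROOT], part_of=[tid])
        _add(a, post, f"posterior {name}",
             f"Posterior portion of the {name}.",
             leaves[mid], leaves[hi], is_a=[ROOT], part_of=[tid])
    return FixtureBundle(anatomy=a, stages=stages)


SWIM_BLADDER = TermID("TEST", "0000030")
ASB_BUD = TermID("TEST", "0000031")
TUNICA_INTERNA = TermID("TEST", "0000032")
SB_EPITHELIUM = TermID("TEST", "0000033")
ANTERIOR_CHAMBER_SB = TermID("TEST", "0000034")
SMOOTH_MUSCLE = TermID("TEST", "0000035")


def swim_bladder_fixture() -> FixtureBundle:
    """Swim-bladder partonomy with the query-expansion annotation set."""
    stages = standard_stage_ontology()
    a = Ontology(header={"format-version": ["1.2"],
                         "data-version": ["fixtures/swim-bladder"]})
    s = stage_id
    _add(a, ROOT, "anatomical structure",
         "Material anatomical entity with inherent 3D shape.",
         s("Prim-5"), s("Adult"))
    _add(a, SWIM_BLADDER, "swim bladder",
         "Gas-filled buoyancy organ dorsal to the gut.",
         s("Protruding-mouth"), s("Adult"), is_a=[ROOT])
    _add(a, ASB_BUD, "anterior swim bladder bud",
         "Bud giving rise to the anterior swim bladder chamber.",
         s("Protruding-mouth"), s("Day 4"), is_a=[ROOT],
         part_of=[SWIM_BLADDER])
    _add(a, TUNICA_INTERNA, "tunica interna",
         "Inner wall layer of the swim bladder.",
         s("Protruding-mouth"), s("Adult"), is_a=[ROOT],
         part_of=[SWIM_BLADDER])
    _add(a, SB_EPITHELIUM, "swim bladder epithelium",
         "Epithelial lining of the swim bladder.",
         s("Protruding-mouth"), s("Adult"), is_a=[ROOT],
         part_of=[SWIM_BLADDER])
    _add(a, ANTERIOR_CHAMBER_SB, "anterior chamber swim bladder",
         "Anterior chamber of the two-chambered adult swim bladder.",
         s("Day 4"), s("Adult"), is_a=[ROOT], part_of=[SWIM_BLADDER])
    _add(a, SMOOTH_MUSCLE, "smooth muscle",
         "Non-striated contractile tissue.",
         s("Protruding-mouth"), s("Adult"), is_a=[ROOT])

    sm_in_ti = compose(SMOOTH_MUSCLE, TUNICA_INTERNA)

    def window(name: str) -> StageInterval:
        ordinals = [n for n, _ in STANDARD_STAGES]
        o = ordinals.index(name)
        return StageInterval(o, o)

    annotations: list[Annotation] = [
        ExpressionAnnotation("opa3", SWIM_BLADDER, window("Day 5")),
        ExpressionAnnotation("wif1", ASB_BUD, window("Protruding-mouth")),
        ExpressionAnnotation("acta2", TUNICA_INTERNA,
                             window("Protruding-mouth")),
        PhenotypeAnnotation(SB_EPITHELIUM, "PATO:0000587", "decreased size",
                            stage=window("Day 5"),
                            genotype="ihha^hu213/hu213"),
        PhenotypeAnnotation(ANTERIOR_CHAMBER_SB, "PATO:0000462", "absent",
                            stage=window("Day 5"),
                            genotype="ihha^hu213/hu213"),
        PhenotypeAnnotation(sm_in_ti, "PATO:0000462", "absent",
                            stage=window("Day 5"),
                            genotype="WT + MO2-wif1"),
    ]
    return FixtureBundle(anatomy=a, stages=stages,
                         annotations=annotations, composites=[sm_in_ti])


# -- random valid ontologies ------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random-ontology generator; the seed fixes the output."""

    n_terms: int = 50
    n_stages: int = 10
    max_depth: int = 8
    p_part_of: float = 0.3
    p_develops_from: float = 0.2
    p_unknown_start: float = 0.1
    p_unknown_end: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_part_of, self.p_develops_from,
                  self.p_unknown_start, self.p_unknown_end):
            if not 0.0 <= p <= 1.0:
                raise GenerationError("probabilities must lie in [0, 1]")
        if self.n_terms < 1 or self.n_stages < 1 or self.max_depth < 1:
            raise GenerationError("counts must be positive")
        if self.p_develops_from > 0 and self.n_stages < 2:
            raise GenerationError(
                "develops_from edges need at least 2 stages")


def _generated_stage_ontology(n_stages: int) -> Ontology:
    onto = Ontology(header={"format-version": ["1.2"]})
    _stage_term(onto, TermID("TSTG", "0000000"), "unknown")
    leaves = [TermID("TSTG", f"{i + 1:07d}") for i in range(n_stages)]
    for i, tid in enumerate(leaves):
        _stage_term(onto, tid, f"stage {i + 1}")
    for earlier, later in zip(leaves, leaves[1:]):
        onto.add_relationship(Relationship(
            later, Predicate.IMMEDIATELY_PRECEDED_BY, earlier))
    # one or two contiguous super-stages for querying and STAGE-LEAF tests
    half = max(1, n_stages // 2)
    blocks = [("early period", TermID("TSTG", "0000101"), leaves[:half])]
    if n_stages > half:
        blocks.append(("late period", TermID("TSTG", "0000102"),
                       leaves[half:]))
    for name, sup, members in blocks:
        _stage_term(onto, sup, name)
        for m in members:
            onto.add_relationship(Relationship(m, Predicate.PART_OF, sup))
    return onto


def generate_valid(params: GeneratorParams) -> FixtureBundle:
    """Seed-deterministic random ontology passing every release check.

    A rooted is_a tree over ``n_terms`` classes whose stage windows nest
    inside their parent's; part_of edges are added only to wholes whose
    window contains the part's, develops_from edges only where the
    junction is overlapping or abutting; a known side may then be
    replaced by the unknown sentinel (permissive everywhere, so never a
    violation).
    """
    rng = random.Random(params.seed)
    stages = _generated_stage_ontology(params.n_stages)
    unknown = TermID("TSTG", "0000000")
    leaves = [TermID("TSTG", f"{i + 1:07d}") for i in range(params.n_stages)]
    a = Ontology(header={
        "format-version": ["1.2"],
        "data-version": [f"fixtures/random-{params.seed}"]})

    ids = [TermID("TEST", f"{i + 1:07d}") for i in range(params.n_terms)]
    window: dict[TermID, tuple[int, int]] = {}
    depth: dict[TermID, int] = {}

    def emit(i: int, name_stub: str, lo: int, hi: int,
             is_a=(), part_of=(), develops_from=()):
        tid = ids[i]
        _add(a, tid, f"{name_stub} {i + 1}",
             f"Synthetic anatomical class number {i + 1}.",
             leaves[lo], leaves[hi], is_a=list(is_a), part_of=list(part_of),
             develops_from=list(develops_from))
        window[tid] = (lo, hi)

    emit(0, "structure", 0, params.n_stages - 1)
    depth[ids[0]] = 1
    for i in range(1, params.n_terms):
        shallow = [j for j in range(i) if depth[ids[j]] < params.max_depth]
        parent = ids[rng.choice(shallow)]
        plo, phi = window[parent]
        lo = rng.randint(plo, phi)
        hi = rng.randint(lo, phi)
        part_of = []
        if rng.random() < params.p_part_of:
            wholes = [ids[k] for k in range(i)
                      if ids[k] != parent
                      and window[ids[k]][0] <= lo and hi <= window[ids[k]][1]]
            if wholes:
                part_of = [rng.choice(wholes)]
        develops_from = []
        if rng.random() < params.p_develops_from:
            preds = [ids[k] for k in range(i)
                     if window[ids[k]][1] in (lo, lo - 1)]
            if preds:
                develops_from = [rng.choice(preds)]
        emit(i, "structure", lo, hi, is_a=[parent], part_of=part_of,
             develops_from=develops_from)
        depth[ids[i]] = depth[parent] + 1

    # blur some window sides to 'unknown' (always permissive, never an error)
    for tid in ids:
        drop_start = rng.random() < params.p_unknown_start
        drop_end = rng.random() < params.p_unknown_end
        if drop_start and not drop_end:
            set_stage(a, tid, "start", unknown)
        elif drop_end and not drop_start:
            set_stage(a, tid, "end", unknown)
    return FixtureBundle(anatomy=a, stages=stages)


# -- violation injection ----------------------------------------------------

def _live_intervals(onto: Ontology, series: StageSeries):
    out: dict[TermID, StageInterval] = {}
    for term in onto.live_terms():
        try:
            out[term.id] = interval_of(onto, series, term.id)
        except IntervalError:
            pass
    return out


def _out_preds(onto: Ontology, tid: TermID, predicate: Predicate):
    return [r for r in onto.out_edges(tid, {predicate})]


def inject_violations(bundle: FixtureBundle, spec: dict[str, int],
                      seed: int) -> FixtureBundle:
    """Mutate a valid bundle to create exactly the requested violations.

    Each mutation touches terms disjoint from every other mutation's, so
    no injected defect can mask another: the validator's ERROR report on
    the returned bundle equals the manifest exactly. Raises
    :class:`InjectionError` naming the first rule for which no safe
    mutation site exists.
    """
    b = FixtureBundle(anatomy=copy.deepcopy(bundle.anatomy),
                      stages=copy.deepcopy(bundle.stages),
                      annotations=list(bundle.annotations),
                      composites=list(bundle.composites),
                      manifest=list(bundle.manifest))
    rng = random.Random(seed)
    series = b.series()
    onto = b.anatomy
    n = len(series)
    frozen: set[TermID] = set()

    handlers = {
        "SUB-STAGE": lambda iv: _inject_containment(
            onto, series, iv, frozen, Predicate.IS_A, rng),
        "PART-STAGE": lambda iv: _inject_containment(
            onto, series, iv, frozen, Predicate.PART_OF, rng),
        "DF-JUNCTION": lambda iv: _inject_junction(
            onto, series, iv, frozen, rng),
        "STAGE-COMPLETE": lambda iv: _inject_incomplete(
            onto, series, iv, frozen, rng),
        "STAGE-LEAF": lambda iv: _inject_super_filler(
            onto, series, iv, frozen, rng),
    }
    for rule in sorted(spec):
        if rule not in handlers:
            raise InjectionError(f"unknown rule {rule!r}")
        for _ in range(spec[rule]):
            intervals = _live_intervals(onto, series)
            subject = handlers[rule](intervals)
            if subject is None:
                raise InjectionError(
                    f"no safe mutation site left for rule {rule}")
            b.manifest.append((rule, subject))
    b.manifest.sort(key=lambda m: (m[0], m[1].curie))
    return b


def _containment_parents(onto, c):
    return (_out_preds(onto, c, Predicate.IS_A)
            + _out_preds(onto, c, Predicate.PART_OF))


def _safe_set(onto, iv, n_leaves, term, side, new_ord, target_edge):
    """True iff setting ``term``'s interval side provably breaks only
    ``target_edge`` and nothing else in any check.

    Examines every asserted edge touching ``term``: containment edges in
    both roles, develops_from junctions where the mutated side feeds the
    comparison, and the term's own interval sanity.
    """
    if not 0 <= new_ord <= n_leaves - 1:
        return False
    t = iv[term]
    if side == "start" and t.end is not None and new_ord > t.end:
        return False
    if side == "end" and t.start is not None and new_ord < t.start:
        return False
    for r in _containment_parents(onto, term):
        if r == target_edge:
            continue
        if r.object not in iv:
            return False
        p = iv[r.object]
        if side == "start" and p.start is not None and new_ord < p.start:
            return False
        if side == "end" and p.end is not None and new_ord > p.end:
            return False
    for r in onto.in_edges(term, {Predicate.IS_A, Predicate.PART_OF}):
        if r == target_edge:
            continue
        if r.subject not in iv:
            return False
        ch = iv[r.subject]
        if side == "start" and ch.start is not None and ch.start < new_ord:
            return False
        if side == "end" and ch.end is not None and ch.end > new_ord:
            return False
    if side == "start":
        # term's start feeds junctions where it is the successor
        for r in _out_preds(onto, term, Predicate.DEVELOPS_FROM):
            if r == target_edge:
                continue
            if r.object not in iv:
                return False
            e = iv[r.object].end
            if e is not None and new_ord not in (e, e + 1):
                return False
    else:
        # term's end feeds junctions where it is the predecessor
        for r in onto.in_edges(term, {Predicate.DEVELOPS_FROM}):
            if r == target_edge:
                continue
            if r.subject not in iv:
                return False
            s = iv[r.subject].start
            if s is not None and s not in (new_ord, new_ord + 1):
                return False
    return True


def _inject_containment(onto, series, iv, frozen, predicate, rng):
    """Push a part/child window provably outside its whole/parent window.

    Four mutation variants per edge: move the child's start or end just
    past the parent's bound, or shrink the parent's bound just past the
    child's. The first variant that breaks only the targeted edge is a
    candidate site.
    """
    n = len(series)
    cands = []
    for rel in sorted(onto.relationships):
        if rel.predicate is not predicate:
            continue
        c, p = rel.subject, rel.object
        if c in frozen or p in frozen or c not in iv or p not in iv:
            continue
        ic, ip = iv[c], iv[p]
        variants = []
        if ip.start is not None:
            variants.append((c, "start", ip.start - 1))
        if ip.end is not None:
            variants.append((c, "end", ip.end + 1))
        if ic.start is not None:
            variants.append((p, "start", ic.start + 1))
        if ic.end is not None:
            variants.append((p, "end", ic.end - 1))
        for term, side, new_ord in variants:
            if _safe_set(onto, iv, n, term, side, new_ord, rel):
                cands.append((c, p, term, side, new_ord))
                break
    if not cands:
        return _inject_containment_edge(onto, iv, frozen, predicate, rng)
    c, p, term, side, ordinal = cands[rng.randrange(len(cands))]
    set_stage(onto, term, side, series.leaves[ordinal])
    frozen.update({c, p})
    return c


def _inject_containment_edge(onto, iv, frozen, predicate, rng):
    """Fallback: assert a new is_a/part_of edge whose windows conflict.

    Adding an edge leaves every stage assignment intact, so the only
    check it can affect is the containment check on the edge itself.
    """
    existing = {(r.subject, r.object) for r in onto.relationships
                if r.predicate is predicate}
    pairs = []
    for c in sorted(iv):
        if c in frozen:
            continue
        ic = iv[c]
        for p in sorted(iv):
            if p == c or p in frozen or (c, p) in existing:
                continue
            ip = iv[p]
            provably_out = (
                (ic.start is not None and ip.start is not None
                 and ic.start < ip.start)
                or (ic.end is not None and ip.end is not None
                    and ic.end > ip.end))
            if not provably_out:
                continue
            if predicate is Predicate.IS_A and \
                    c in ancestors(onto, p, {Predicate.IS_A}):
                continue  # would close an is_a cycle
            pairs.append((c, p))
    if not pairs:
        return None
    c, p = pairs[rng.randrange(len(pairs))]
    onto.add_relationship(Relationship(c, predicate, p))
    frozen.update({c, p})
    return c


def _inject_junction(onto, series, iv, frozen, rng):
    """Break a develops_from junction into a GAP or PREMATURE one.

    Variants: push the successor's start two stages past the
    predecessor's end (GAP), pull the predecessor's end two stages below
    the successor's start (GAP), or cross the two by one stage
    (PREMATURE), whichever breaks only the targeted edge.
    """
    n = len(series)
    cands = []
    for rel in sorted(onto.relationships):
        if rel.predicate is not Predicate.DEVELOPS_FROM:
            continue
        s, pred = rel.subject, rel.object
        if s in frozen or pred in frozen or s not in iv or pred not in iv:
            continue
        e, st = iv[pred].end, iv[s].start
        variants = []
        if e is not None:
            variants.append((s, "start", e + 2))    # GAP
            variants.append((s, "start", e - 1))    # PREMATURE
        if st is not None:
            variants.append((pred, "end", st - 2))  # GAP
            variants.append((pred, "end", st + 1))  # PREMATURE
        for term, side, new_ord in variants:
            if _safe_set(onto, iv, n, term, side, new_ord, rel):
                cands.append((s, pred, term, side, new_ord))
                break
    if not cands:
        return _inject_junction_edge(onto, iv, frozen, rng)
    s, pred, term, side, ordinal = cands[rng.randrange(len(cands))]
    set_stage(onto, term, side, series.leaves[ordinal])
    frozen.update({s, pred})
    return s


def _inject_junction_edge(onto, iv, frozen, rng):
    """Fallback: assert a new develops_from edge with an illegal junction."""
    existing = {(r.subject, r.object) for r in onto.relationships
                if r.predicate is Predicate.DEVELOPS_FROM}
    pairs = []
    for s in sorted(iv):
        if s in frozen or iv[s].start is None:
            continue
        st = iv[s].start
        for pred in sorted(iv):
            if pred == s or pred in frozen or (s, pred) in existing:
                continue
            e = iv[pred].end
            if e is None or st in (e, e + 1):
                continue  # junction unknown or legal
            pairs.append((s, pred))
    if not pairs:
        return None
    s, pred = pairs[rng.randrange(len(pairs))]
    onto.add_relationship(Relationship(s, Predicate.DEVELOPS_FROM, pred))
    frozen.update({s, pred})
    return s


def _inject_incomplete(onto, series, iv, frozen, rng):
    """Rewrite a term to start and end 'unknown'."""
    unknown = series.unknown_id
    if unknown is None:
        raise InjectionError("stage ontology lacks an 'unknown' sentinel")
    cands = sorted(t for t in iv if t not in frozen)
    if not cands:
        return None
    t = cands[rng.randrange(len(cands))]
    set_stage(onto, t, "start", unknown)
    set_stage(onto, t, "end", unknown)
    frozen.add(t)
    return t


def _inject_super_filler(onto, series, iv, frozen, rng):
    """Point a term's start_stage at a super-stage."""
    if not series.super_stages:
        raise InjectionError(
            "stage ontology has no super-stage to misuse")
    sup = sorted(series.super_stages)[0]
    cands = sorted(t for t in iv if t not in frozen)
    if not cands:
        return None
    t = cands[rng.randrange(len(cands))]
    set_stage(onto, t, "start", sup)
    frozen.add(t)
    return t
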