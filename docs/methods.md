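# Methods

## The model

An anatomy ontology is a set of classes connected by six relation types:
`is_a`, `part_of` (BFO:0000050), `develops_from` (RO:0002202),
`start_stage` (RO:0002091), `end_stage` (RO:0002093) and
`immediately_preceded_by` (RO:0002087). The first three build the
subsumption, partonomy and developmental hierarchies; the stage relations
tie each anatomical class to a companion staging-series ontology in which
`immediately_preceded_by` chains the leaf stages into a single total
order. Super-stages group consecutive leaves through `part_of` and exist
only for querying; stage relations of anatomical classes must point at
leaves. An `unknown` sentinel stage, spanning the entire series, encodes
curatorial ignorance of one interval side; a class may leave either its
start or its end unknown but never both.

Internally a class's existence window is a `StageInterval` of 0-based
leaf ordinals with `None` for an unknown side. Ordinals are bookkeeping
only: every report and rendered message names stages by name.

## Temporal consistency semantics

Three interval predicates drive all checks:

- **containment** — `inner` lies within `outer` iff `inner.start >=
  outer.start` and `inner.end <= outer.end`. An unknown side of the outer
  interval is unbounded; an unknown side of the inner interval is taken
  to satisfy its bound. The rule is thus *permissive under ignorance*: a
  violation is reported only when provable from known ordinals. This is a
  deliberate design choice — `unknown` records missing knowledge, not a
  constraint, and a release gate that flagged unprovable conflicts would
  punish honesty about ignorance.
- **junction** — for a `develops_from` pair, the successor's start is
  compared to the predecessor's **end** (the successor of a developmental
  transformation appears as its progenitor disappears, not as it
  appears): equal = OVERLAPPING, one later = ABUTTING, two or more later
  = GAP, earlier = PREMATURE, UNDETERMINED if either side is unknown.
  The five kinds are exhaustive and mutually exclusive over ordinal
  pairs. OVERLAPPING is defined as *exact* coincidence of the shared
  stage; a successor starting strictly before the predecessor's end is
  classified PREMATURE and flagged, with a configuration switch
  (`premature_is_warning`) to downgrade it to a warning for curation
  styles that tolerate extended overlap.
- **intersection** — used only by search-time stage filtering, where a
  query at a stage should find anything observed then; validation always
  uses containment.

## Release-gate checks

`validate()` aggregates five rule families into one deterministic report
(violations sorted by rule id then subject; counts per rule; `passed`
iff no ERROR-severity finding):

| rule | meaning | default severity |
|---|---|---|
| SUB-STAGE | `is_a` child's window escapes its parent's | ERROR |
| PART-STAGE | part's window escapes its whole's | ERROR |
| DF-JUNCTION | `develops_from` junction is GAP or PREMATURE | ERROR |
| STAGE-COMPLETE | both sides unknown / missing / inverted window | ERROR |
| STAGE-LEAF | stage filler is a super-stage | ERROR |
| META-DEF | class lacks a definition | WARNING |
| META-OBS | obsolete class retains edges or a dead `replaced_by` | ERROR |
| META-SINGULAR | plural-looking name without a PLURAL synonym (heuristic) | WARNING |

The stage-hierarchy rules gate a release; the metadata rules are
editorial practice, so they warn except for obsolete classes that still
participate in the graph. Containment is checked over **asserted direct
edges only**: a class violating its grandparent but not its parent is
caught when the intermediate edge is checked, which localizes blame to
one edge per report. Whether `develops_from` chains should additionally
satisfy transitive (grandparent) junction constraints is an open design
question; only direct edges are checked here.

A YAML `ValidationConfig` supports per-rule severity overrides, the
PREMATURE downgrade, and per-rule subject ignore lists.

The expression-annotation check (rule id EXPR-STAGE) is deliberately
outside the ontology's `passed` flag: it gates annotations, not the
ontology. An expression record conflicts when its observed window is not
**contained** in the entity's existence window (mere overlap is not
enough: a structure must exist at every stage where its expression is
asserted; an `mode="overlap"` alternative is provided). For a composite
entity with an external genus the filler's window is used — spatial,
cellular-component and pathology partners carry no stages — while
anatomy×anatomy composites use the intersection of both windows.
Phenotype records are exempt unconditionally, because phenotypes often
involve the delayed development of a structure: an "absent swim bladder"
at day 5 is precisely an observation at a stage where the intact
structure would exist, and must never be flagged.

## Post-composition and search

A composite is a depth-1 pair: genus `X` restricted by `part_of` to an
anatomy filler `Y`, rendered `'X' that part_of some 'Y'`. Only `part_of`
relates the pair, which keeps composites consistent with the ontology
graph. Placement adds exactly two edges — `composite is_a genus` and
`composite part_of filler` — so a placed composite is retrieved beneath
its filler (and beneath its genus) by expansion. External genus terms
are opaque labelled ids; their home hierarchies are not imported, since
they serve only as differentia labels. Closure (the reflexive-transitive
`is_a`∪`part_of` ancestor set of a composite) is the exact dual of
descendant expansion: `t ∈ closure(c)` iff `c ∈ descendants(t)`, a
property-tested invariant.

Query expansion uses `is_a` ∪ `part_of` only. `develops_from` is
excluded: a progenitor is a distinct structure, not a sub-structure, so
annotations to it should not surface under its product. For EQE
phenotype records, retrieval is driven by the affected entity (entity1);
the second entity of a relational quality does not trigger retrieval by
default (an opt-in flag exists), matching how such data is searched by
affected structure.

## Synthetic fixtures

The three worked-example bundles encode the canonical scenarios at the
stage series Prim-5 < Prim-15 < Prim-25 < High-pec < Long-pec <
Protruding-mouth < Day 4 < Day 5 < Juvenile < Adult (ten leaves, two
super-stages, `unknown` sentinel). The heart chain demonstrates one
overlapping and one abutting junction; the neural
plate→keel→rod→tube fixture adds anterior/posterior `part_of` children
whose windows nest inside the parent's with the anterior child starting
no later than the posterior (axis lag is quantized to whole stages,
since sub-stage timing differences are not representable); the
swim-bladder fixture carries the expression/phenotype records and the
(smooth muscle × tunica interna) composite used by the search tests.
The neural windows are chosen to satisfy the required
overlap/abut/containment pattern; their absolute positions are a free
choice. Only ids printed in canonical reference material are reused;
invented anatomy classes use the reserved `TEST:` prefix and invented
stage classes `TSTG:`, so fixture ids can never shadow real ontology
ids.

`generate_valid(params)` emits a seed-deterministic random bundle: a
stage chain of `n_stages` leaves, a rooted `is_a` tree of `n_terms`
classes whose windows nest in their parent's, `part_of` edges only to
wholes whose window contains the part's (probability `p_part_of` per
term, default 0.3), `develops_from` edges only where the junction is
overlapping or abutting (probability `p_develops_from`, default 0.2),
and a post-pass that blurs some sides to `unknown` (10% of starts, 5% of
ends) — always sound, because unknown is permissive in every check. The
defaults (50 terms, 10 stages, `max_depth` 8) give graphs with roughly a
dozen partonomy and a dozen developmental edges: desk-scale, but
exercising every rule. What the generator does **not** emulate: the
scale (thousands of classes) and depth (~20 levels) of a real curated
ontology, multiple inheritance, xref density, or biologically meaningful
names — so passing tests demonstrate the correctness of the calculus and
the checks, not robustness to real curation history.

`inject_violations(bundle, spec, seed)` mutates a valid bundle to create
**exactly** the requested violations with a ground-truth manifest.
Safety is the crux: each candidate mutation (moving one interval side of
the child or the parent just past the other's bound; crossing or
separating a junction from either end) is accepted only if a whole-graph
scan proves it breaks the one targeted edge and nothing else, and each
mutation's terms are disjoint from every other mutation's, so no
injected defect can mask another. When no stage mutation is safe, the
injector falls back to asserting a *new* violating edge (which, leaving
all stage assignments intact, can only affect its own check; `is_a`
additions are cycle-checked). The validator's ERROR report on the result
equals the manifest exactly — precision and recall 1.0 — which is the
completeness half of the validator's test harness; soundness is the
zero-findings guarantee on unmutated bundles.

## Numerical and representational choices

- OBO writer: stanzas sorted by id, fixed tag order, LF, UTF-8;
  `write ∘ parse ∘ write = write` (idempotence after one normalization
  pass). Unsupported tags and non-Term stanzas are preserved verbatim.
- Ids: native stanza ids must be `PREFIX:NNNNNNN` (7 digits, compared
  case-sensitively); externally referenced ids (xrefs, macro fillers,
  quality terms — e.g. `MPATH:359`, `NCBITaxon:7955`) may use any local
  token. Ids resolve to PURLs as `http://purl.obolibrary.org/obo/`
  + `PREFIX_NNNNNNN`.
- `is_a` cycles over live terms are a hard parse error; `part_of` cycles
  are left to curation (dirty data must remain loadable for QC).
- `resolve()` priority: live id > alt id > name > exact synonym
  (PLURAL synonyms included). An alt-id hit returns the merge survivor.
  A hit on an obsolete class follows `replaced_by` when present —
  mirroring alt-id semantics, since both arise from the same
  retire-and-redirect workflow — and otherwise raises a structured error
  carrying the `consider` candidates; ambiguous synonyms raise with the
  candidate list.
- Prefix cloning (the seed-ontology workflow) preserves each class's
  local number and adds an xref back to the original id; edge structure
  is preserved up to renaming. Fresh renumbering is a conceivable
  alternative reading of that workflow, not implemented.
- Degenerate inputs: a one-stage series is legal; an empty anatomy
  ontology validates trivially; a stage ontology whose chain branches,
  cycles or fragments aborts validation with an error naming the
  offending stages, since no check is meaningful without a total order.

## Known limitations

- No OWL serialization or DL reasoning; bridge axioms are emitted as
  tuples for downstream reasoners, not reasoned over here.
- Composites are depth-1 only (no composite-of-composite), matching how
  they are used in annotation practice.
- Absolute developmental time (hours post fertilization) is out of
  scope; the calculus is ordinal, and stage lengths are not modeled.
- The singular-name check is a suffix heuristic and warning-only; it
  will miss irregular plurals and flag some Latin singulars.
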