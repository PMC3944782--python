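# devonto

Toolkit for **stage-aware developmental anatomy ontologies**: the
representational machinery used by model-organism databases (zebrafish
being the canonical case) to describe gross and cellular anatomy across
development and to annotate gene-expression and phenotype data against
it.

An anatomy ontology in this model carries three hierarchies — subsumption
(`is_a`), a partonomy (`part_of`, BFO:0000050) and a developmental
hierarchy (`develops_from`, RO:0002202) — and ties every anatomical class
to a companion stage ontology through `start_stage` (RO:0002091) and
`end_stage` (RO:0002093) relations. The stage ontology orders its leaf
stages into a single chain with `immediately_preceded_by` (RO:0002087),
groups consecutive leaves into super-stages used only for querying, and
provides an `unknown` sentinel spanning the whole life cycle.

devonto implements, for that model:

- **OBO 1.2 dialect I/O** — a deterministic reader/writer with structured
  parse errors, obsoletion/merge metadata (`replaced_by`, `consider`,
  `alt_id`), typed synonyms including the `PLURAL` synonym type, and
  `treat-xrefs-as-genus-differentia` bridge-axiom expansion.
- **Stage algebra** — the total stage order, existence intervals, and the
  junction classification for developmental successions: a structure must
  start during the stage its progenitor ends in (*overlapping*) or one
  stage later (*abutting*); anything else is a *gap* or a *premature*
  start.
- **Release-gate QC** — every check run before an ontology release:
  `is_a`/`part_of` children must exist within their parent's stage window,
  `develops_from` junctions must overlap or abut, every class needs a
  known start or end stage tied to leaf stages (never super-stages), plus
  editorial metadata policy (definitions required, obsoletes inert,
  singular names). Reports are machine-readable and deterministic.
- **Post-composition** — classes built on the fly as
  `'X' that part_of some 'Y'` (anatomy×anatomy, spatial×anatomy,
  cellular-component×anatomy, pathology×anatomy), placed into the graph
  so query expansion retrieves them beneath their anatomy filler.
- **Annotation semantics** — expression records (gene, entity, stage
  window, assay) and EQ/EQE phenotype records; the release-time check
  that expression is never annotated at stages where the entity does not
  exist — with phenotype records exempt by design, since phenotypes often
  involve delayed development.
- **Query expansion** — a search for a term returns annotations to the
  term and every `is_a`/`part_of` descendant, including placed
  composites.
- **Synthetic fixtures** — hand-built worked-example bundles (heart
  chain, anterior/posterior neural progression, swim-bladder search
  scenario) and a seeded generator of random valid ontologies with exact
  ground-truth violation injection.

## Worked example

```python
import devonto as d
from devonto.fixtures import HEART, stage_id

bundle = d.heart_fixture()          # primitive heart tube -> heart tube -> heart
print(d.validate(bundle.anatomy, bundle.stages).to_text())
```

```
ontology version: fixtures/heart
violations: 0
PASSED
```

The chain is legal: the primitive heart tube ends at Prim-5, the stage
during which the heart tube starts (overlapping), and the heart tube ends
at Prim-25 with the heart starting one stage later at High-pec
(abutting). Break the second junction by pushing the heart's start two
stages too late:

```python
d.set_stage(bundle.anatomy, HEART, "start", stage_id("Long-pec"))
print(d.validate(bundle.anatomy, bundle.stages).to_text())
```

```
ontology version: fixtures/heart
violations: 1
  [ERROR] DF-JUNCTION ZFA:0000114: GAP: 'heart' starts at Long-pec but develops_from 'heart tube' ending at Prim-25
FAILED
```

The single ERROR-severity finding names the rule (`DF-JUNCTION`), the
offending class, and the stages by name; its presence flips the release
gate to FAILED.

The same machinery is scriptable from the shell:

```sh
devonto fixtures --name swimbladder --out bundle/
devonto validate --anatomy bundle/anatomy.obo --stages bundle/stages.obo
devonto query --anatomy bundle/anatomy.obo --stages bundle/stages.obo \
    --annotations bundle/annotations.tsv --term "swim bladder"
```

The query returns three expression records — one annotated directly to
the swim bladder and two annotated to its parts (`anterior swim bladder
bud`, `tunica interna`), retrieved through `part_of` expansion.

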