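# Methods

## The provenance model

provgraph records the provenance of bioinformatics workflow executions as
directed, typed graphs in the style of the W3C PROV-DM conceptual model.
Two container elements extend the core vocabulary for genome-project use:
a **project** joins the repeated executions of one workflow (each run with
different programs, versions, parameters or inputs), and an **account**
captures a single execution as one provenance graph.  Graph nodes are
**agents** (people, institutions or services acting in the experiment),
**activities** (program runs — the only nodes with their own start and end
times), **entities** (single data objects) and **collections** (entity-like
nodes with `size > 1`, e.g. a FASTA file of many sequences).  Edges are the
relations `used` (activity → input), `wasGeneratedBy` (output → activity),
`wasAssociatedWith` (agent → activity), `wasDerivedFrom` (derived →
original) and `memberOf` (entity → collection).  Edges point from the newer
element toward its origin, so lineage questions are answered by walking
edges forward from a product back to its raw data.

Provenance is kept at two granularities.  Level 1 is the graph itself — a
few kilobytes of metadata per execution.  Level 2 is the payload data
(raw reads, filtered sets, alignments, figures), which stays where the
workflow wrote it and is referenced by each entity's `location` field.
The two levels stay linked but independent: deleting payloads never
corrupts the graph, it only changes its functional validity (below).

### Automatic derivation maintenance

`wasDerivedFrom` edges are not entered by hand.  Whenever some activity *A*
has `wasGeneratedBy(Y → A)` and `used(A → X)`, the engine materialises
`wasDerivedFrom(Y → X)`; when the supporting pair disappears, so does the
derived edge.  The maintained set is exactly

    { (Y, X) : ∃A  wasGeneratedBy(Y → A) ∧ used(A → X),  Y ≠ X }

The `Y ≠ X` guard excludes self-derivations, which are structurally
forbidden.  Auto-maintained edges are flagged `auto_derived`, cannot be
deleted directly, and default to derivation type `other`; users may
reclassify one as `filtering`, `ordering` or `mixing` without losing it to
maintenance (surviving edges keep their identifier and type).  A manually
added `wasDerivedFrom` for the same (source, target) shadows the automatic
one.  Because each entity has at most one generating activity and duplicate
relations are forbidden, every maintained pair has exactly one supporting
(`wasGeneratedBy`, `used`) edge pair — removing either support removes the
derived edge.

## Restrictions and validity

Validity is judged on three independent axes; an account is valid on an
axis exactly when no rule of that axis is breached, and a project is valid
on an axis when its own window rules pass and every account is valid on
that axis.  The checkers re-verify stored state rather than trusting the
creation API, so hand-edited or corrupt XML is caught after loading.
Violations are data (axis, rule code, elements, message), returned in a
stable order (rule code, then element ids) so reports diff cleanly.  The
rule codes S1–S6, T1–T6, P1, P2 and F1 are fixed; the catalogue is listed
in `provgraph/validation.py`.

Temporal semantics and their edge cases:

* Activities must start **strictly** before they end (T1); account and
  project windows are **non-strict** (start ≤ end).  This mirrors the
  asymmetry in how the rules are usually stated: a process takes time, a
  bracketing window may be a single instant.
* An entity or collection has no clock of its own; its start time is
  defined operationally as the end time of its generating activity.  Raw
  workflow inputs have no generator, hence no start time, and every rule
  needing one is vacuously satisfied for them.  An account with no entity
  that is both generated and used therefore passes the relation-timing
  rules automatically.
* T2 ("an entity may only be used after its generator finished") and T3
  ("an activity may only use an entity that already exists") are the
  generation-side and use-side readings of the same ordering constraint,
  reported on the `wasGeneratedBy` and `used` edge respectively.  One
  timing fault always produces both violations; the violation-injection
  generator documents this pair as the expected co-set.
* T4 requires a derivation's original to be strictly older than the
  derived element's generation.  Along automatically maintained edges this
  is implied by T2/T3 plus T1, so T4 can only fail independently on
  manually asserted derivations.
* Window containment (T6 for activities in accounts, P2 for accounts in
  projects) is only judged against a well-formed window: when the window
  itself is inverted (T5/P1), containment is skipped rather than reported
  against a meaningless interval.  Accounts or projects with an absent end
  bound are treated as in progress: only the start bound is enforced.
* A consequence of these rules: in a temporally valid account the
  `wasDerivedFrom` subgraph restricted to *generated* elements is acyclic,
  because generation times strictly increase along each derivation.  A
  cycle confined to raw inputs (no generators, hence no times) is not
  temporally detectable — there is nothing to order it by.

Functional validity checks that every located payload still resolves to an
existing file.  A missing payload is deliberately not an error: the
account remains a faithful record of what happened, it just can no longer
be re-executed.  Locations are resolved through a `PayloadResolver` with a
configurable base directory, because account XML travels between machines
far more easily than terabyte payloads; a project directory records its
payload base in `project.json`.

## Persistence

Accounts are stored one-per-file in a small XML dialect (schema in
`docs/account.xsd`): Table-style metadata as attributes, collections as
entities with a `size` attribute, relations with their role, derivation
type and `auto_derived` flag, annotations as children.  Node and edge
lists are emitted in sorted identifier order, making serialisation
deterministic: save → load → save is byte-identical apart from the version
stamps.  Every save re-checks the structural rules and refuses to persist
a structurally invalid graph; temporal and functional violations are
recorded inside the document (`<recorded-violations>`) but never block a
save, matching their advisory character.  Each save increments the version
by one and restamps `version_date` — versioning is by save, not by content
change, so the version counts how often the record was touched.  A JSON
registry per project directory lists every saved execution file with its
version and date.

Rendering delegates to GraphViz: the DOT text is the deterministic,
contract-tested artifact (agents as houses, activities as boxes, entities
as ellipses, collections double-bordered; associations dotted; machine-
maintained derivations dashed; roles as edge labels and annotations as
gray boxes on request), while gif/png/svg output is a thin `dot`
invocation and is only smoke-tested, since renderer bytes are not stable
across GraphViz versions.

## The case-study fixture

`build_case_study()` reconstructs, through the ordinary creation API, the
provenance of one execution of a *Bacillus cereus* genome-project
workflow: the isolate's alpha-amylase families 13 and 57 are each
filtered, joined with the ORFs predicted on the assembly contigs, multiply
aligned, and plotted.  The graph has 2 agents, 11 collections and 8
activities connected by 40 edges: 10 `used`, 8 `wasGeneratedBy`, 12
`wasAssociatedWith` (the executing student associated to all eight
activities with role *Execution*; the validating researcher to the four
alignment/graphic activities with role *Validation*), and 10
`wasDerivedFrom` — all ten produced by the automatic maintenance rule,
none placed by hand.  The validating researcher keeps her published
identifier `C002_Taina` even though it breaks the `AG` prefix convention
used for agents elsewhere; identifiers are opaque, so only literal
collisions matter, and `C002_Taina` ≠ `C002_Family57`.

Choices where the narrative is silent:

* **Timestamps are fabricated.**  Each activity occupies a one-hour slot
  in workflow order from 2012-03-01 08:00; the account window spans
  08:00–16:00 and the project window 2012-01-01 – 2013-01-01.  This makes
  temporal validity deterministic and the times readable.
* **Family-57 identifiers** (`A002`, `A004`, `C004`, `C007`, `C009`,
  `C011`) mirror the Family-13 chain, which is described explicitly.
* **Groups**: nodes are tagged `Family 13` / `Family 57` along each
  family's chain, plus stage groups `Filter`, `Mix`, `Multiple Alignment`,
  `Graphic`.  The shared ORF collection belongs only to `Mix`, so a
  single-family view shows that family's chain without the shared input.
  The executor belongs to every group, the validator to the family groups
  and the two stages she validated — so filtered views retain their
  responsible agents.
* **Payloads are synthetic placeholders**: two-record FASTA stubs (and
  small text stand-ins for alignment/graphic outputs), written on demand
  so functional checking and the level-2 linkage work offline.  Roles on
  data edges are `input`/`output`; the literal role strings `Execution`
  and `Validation` are used on associations.

## The random-account generator

`generate_account(GeneratorParams(...))` builds workflow-shaped accounts
for property testing: `n_chains` parallel chains of `chain_length`
activities (filter → transform → analyze), each consuming the previous
stage's output plus occasionally one of `fan_in` shared raw collections,
with `n_agents` agents (the first associated to every activity).
Activities run for one hour every two hours in chain-major order, so all
timing rules hold with strict slack.  Defaults (2 chains × 3 stages, 2
agents, fan-in 2) keep each account at ~15 nodes — large enough to contain
every structural motif, small enough that hundreds of accounts and their
brute-force derivation closures are checked in seconds.  Everything is
driven by one `random.Random(seed)`, so accounts are bit-reproducible.

With `violation=<rule code>` the generator injects exactly one breach of
that rule and nothing else: structural breaches are planted by direct
mutation of the stored graph (mimicking corrupt XML, since the creation
API would refuse them), temporal ones retime a single element, `F1` points
one collection at a non-existent file.  Injecting T2 or T3 produces the
documented {T2, T3} pair; every other code produces exactly itself.
`generate_project` wraps an account for the project-window codes P1/P2.

What the generator does **not** emulate: real payload contents, `memberOf`
membership structure (supported by the model, exercised in unit tests,
but absent from generated graphs as from the case study), multi-account
projects with shared lineage, or clock skew between machines.  Passing
property tests therefore demonstrate the engine's bookkeeping — closure
maintenance, rule detection, round-trips — not robustness to messy
real-world metadata entry.

## Known limitations

* Derivation is scoped to one account; lineage across executions of a
  project is not modelled.
* Temporal rules cannot order elements that lack a generating activity, so
  derivation cycles among raw inputs go undetected (see above).
* Versioning counts saves, not content changes; saving an untouched
  account still bumps the version.
* Provenance must be entered (via the API or CLI); there is no automatic
  capture from running workflows, and no PROV-N/PROV-O/RDF export.
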