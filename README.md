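# provgraph

Provenance graphs for bioinformatics workflow executions.

Genome and transcriptome projects run the same workflow many times —
different programs, versions, parameters, or inputs — and the details of
each run (what was used, what was produced, by which program, run by whom)
are easily lost.  provgraph records each execution as a typed provenance
graph in the W3C PROV-DM style, so biologists and bioinformaticians can
reconstruct exactly how any file was produced, compare executions, and
check whether an old experiment is still reproducible.

Each **project** joins the executions of one workflow; each execution is
an **account**: a directed graph of **agents**, **activities** (the only
elements with start/end times), **entities** and **collections** (entities
with `size > 1`, e.g. a multi-record FASTA file), connected by the
relations `used`, `wasGeneratedBy`, `wasAssociatedWith`, `wasDerivedFrom`
and `memberOf`.  The engine provides:

- **automatic lineage**: `wasDerivedFrom(Y → X)` is materialised whenever
  one activity generated *Y* and used *X*, and disappears when that
  support does — derivation edges are machine-kept, never hand-entered;
- **three-axis validation**: *structural* rules (unique identifiers,
  well-typed endpoints, no duplicate relations, one generating activity
  per entity, no self-derivation), *temporal* rules (activities start
  before they end; data is used only after it was generated; account and
  project windows contain their contents), and a *functional* rule (every
  referenced payload file still exists — if not, the experiment is intact
  as a record but can no longer be re-executed);
- **two-level granularity**: the graph is a few kB of metadata (level 1)
  linked to the payload files in place (level 2) via `location` fields;
- **versioned XML persistence** with a per-project registry — every save
  re-checks structure, bumps the version and restamps the date;
- **group-filtered GraphViz views**: every node carries group labels, and
  a view keeps the nodes in at least one selected group, with optional
  role labels and annotation boxes.

## Worked example

The package ships a reference graph: one execution of a *Bacillus cereus*
genome-project workflow in which the isolate's alpha-amylase families 13
and 57 are each quality-filtered, joined with the ORFs predicted on the
assembly contigs, multiply aligned, and plotted, executed by one student
and validated by one researcher.

```sh
$ prov fixture case-study --dir bcereus
wrote case study to bcereus
  2 agents, 11 collections, 8 activities, 40 edges
```

The 40 edges are 10 `used` + 8 `wasGeneratedBy` + 12 `wasAssociatedWith`
entered through the API, plus 10 `wasDerivedFrom` created by the automatic
maintenance rule.  The account validates cleanly on all three axes:

```sh
$ prov validate bcereus/WE001_Multiple_Alignment.xml --payload-base bcereus/payloads
structural: valid
temporal: valid
functional: valid
```

Deleting a payload file (`rm bcereus/payloads/family13.fasta`) flips
exactly the functional axis — the record is intact, the experiment is no
longer re-executable — and `prov validate` then exits nonzero with an `F1`
violation naming `C001_Family13`.

Group-filtered views select sub-experiments; here the Family-57 chain:

```sh
$ prov render bcereus/WE001_Multiple_Alignment.xml --groups "Family 57" --out f57.dot
wrote f57.dot
$ head -6 f57.dot
digraph provenance {
  label="Multiple Alignment";
  labelloc=t;
  "A002_Family57_Filter" [shape=box, label="A002_Family57_Filter"];
  "A004_Family57_Mix" [shape=box, label="A004_Family57_Mix"];
  "A006_Family57_Alignment" [shape=box, label="A006_Family57_Alignment"];
```

The same operations are available as a library:

```python
from provgraph import build_case_study, infer_account_validity, PayloadResolver

project = build_case_study(payload_dir="payloads")
account = project.accounts[0]
status = infer_account_validity(account, PayloadResolver("payloads"))
assert status.all_valid
```

`prov add`, `prov link`, `prov unlink` and `prov annotate` edit account
files in place (each edit re-saves and bumps the version); `prov show`
prints a node/edge summary including the machine-maintained derivations.

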