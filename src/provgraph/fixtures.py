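"""Reference provenance graphs: the B. cereus case study and random accounts.

:func:`build_case_study` reconstructs, through the ordinary creation API,
the provenance graph of one execution of a *Bacillus cereus* genome-project
workflow that compares the isolate's alpha-amylase families 13 and 57
against related Bacillus species.  Each family's FASTA collection is
filtered, joined with the isolate's predicted ORFs, multiply aligned, and
plotted; a student executes every activity and a researcher validates the
alignment and graphic steps.  The resulting account has 2 agents, 11
collections and 8 activities joined by 40 edges — 10 ``used``, 8
``wasGeneratedBy``, 12 ``wasAssociatedWith`` and 10 automatically derived
``wasDerivedFrom``.

Timestamps are fabricated (the narrative gives none): each activity
occupies a one-hour slot in workflow order starting 2012-03-01 08:00,
which makes temporal validity deterministic and the times human-readable.
Tiny placeholder FASTA/alignment payload files (synthetic stand-ins for
the real UNIPROT and isolate data) can be written so functional checks and
the level-2 linkage are exercisable offline.

:func:`generate_account` produces pseudo-random workflow-shaped accounts —
parallel chains of filter/transform/analyse activities over collections —
that are valid on all three axes, or that breach exactly one named
restriction, for property testing of the validators.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

from .model import (
    Account,
    ActivityFields,
    AgentFields,
    CollectionFields,
    DerivationType,
    NodeKind,
    ProvenanceProject,
    RelationEdge,
    RelationKind,
    new_account,
    new_project,
)

__all__ = [
    "GeneratorParams",
    "build_case_study",
    "case_study_payload_files",
    "generate_account",
    "generate_project",
    "EXPECTED_RULES",
    "INJECTABLE_ACCOUNT_RULES",
]


# ---------------------------------------------------------------------------
# case study
# ---------------------------------------------------------------------------

_PAYLOADS = {
    "C001_Family13": "family13.fasta",
    "C002_Family57": "family57.fasta",
    "C005_ORFS": "orfs.fasta",
    "C003_Family13_Filtered": "family13_filtered.fasta",
    "C004_Family57_Filtered": "family57_filtered.fasta",
    "C006_Family13_ORFS": "family13_orfs.fasta",
    "C007_Family57_ORFS": "family57_orfs.fasta",
    "C008_Family13_Alignments": "family13_alignments.aln",
    "C009_Family57_Alignments": "family57_alignments.aln",
    "C010_Family13_Graph": "family13_graph.txt",
    "C011_Family57_Graph": "family57_graph.txt",
}

_FASTA_STUB = (
    ">{name}_seq1 synthetic placeholder\n"
    "ATGGCTAAAGGTCTGATTGACG\n"
    ">{name}_seq2 synthetic placeholder\n"
    "ATGAAACCGGGTTTACGTGAAC\n"
)


def case_study_payload_files() -> list[str]:
    """Relative payload file names referenced by the case-study collections."""
    return sorted(_PAYLOADS.values())


def _write_payloads(payload_dir: Path) -> None:
    payload_dir.mkdir(parents=True, exist_ok=True)
    for node_id, fname in _PAYLOADS.items():
        path = payload_dir / fname
        if fname.endswith(".fasta"):
            path.write_text(_FASTA_STUB.format(name=node_id), encoding="utf-8")
        else:
            path.write_text(
                f"synthetic placeholder output for {node_id}\n", encoding="utf-8"
            )


def build_case_study(
    payload_dir: Optional[Path | str] = None,
) -> ProvenanceProject:
    """The B. cereus alpha-amylase comparison as a one-account project.

    When ``payload_dir`` is given, placeholder payload files are written
    there and the collections' relative locations resolve against it (pass
    ``PayloadResolver(payload_dir)`` to the functional checker).
    """
    t0 = datetime(2012, 3, 1, 8, 0)
    hour = timedelta(hours=1)

    project = new_project(
        "B. cereus genome",
        id="P001_BCereus",
        description=(
            "Identification of alpha-amylase genes in a Brazilian Bacillus "
            "cereus isolate and comparison with related Bacillus species"
        ),
        funding_institutions=["UnB"],
        partner_institutions=["UnB Molecular Biology Laboratory"],
        coordinator="M. E. Walter",
        start_date=datetime(2012, 1, 1),
        end_date=datetime(2013, 1, 1),
    )
    acc = new_account(
        project,
        "Multiple Alignment",
        id="WE001_Multiple_Alignment",
        description=(
            "Multiple alignment of the isolate's alpha-amylase families 13 "
            "and 57 against related Bacillus sequences, with graphics"
        ),
        location="UnB bioinformatics laboratory",
        execution_date=t0,
        start_time=t0,
        end_time=t0 + 8 * hour,
    )

    acc.add_node(
        NodeKind.AGENT,
        AgentFields(
            name="Joao",
            institution="UnB - Department of Computer Science",
            position="Student",
            function="Executed every activity of the workflow",
        ),
        groups={"Family 13", "Family 57", "Filter", "Mix", "Multiple Alignment", "Graphic"},
        id="AG001_Joao",
    )
    # the validating researcher keeps her published identifier, whose C
    # prefix breaks the AG convention used elsewhere
    acc.add_node(
        NodeKind.AGENT,
        AgentFields(
            name="Taina",
            institution="UnB - Department of Cellular Biology",
            position="Researcher",
            function="Validated the alignment and graphic activities",
        ),
        groups={"Family 13", "Family 57", "Multiple Alignment", "Graphic"},
        id="C002_Taina",
    )

    collections = {
        # id: (size, description, groups)
        "C001_Family13": (40, "UNIPROT alpha-amylase family 13 sequences", {"Family 13", "Filter"}),
        "C002_Family57": (35, "UNIPROT alpha-amylase family 57 sequences", {"Family 57", "Filter"}),
        "C005_ORFS": (120, "Putative proteins predicted on the isolate's contigs", {"Mix"}),
        "C003_Family13_Filtered": (28, "Family 13 sequences passing the quality filter", {"Family 13", "Filter", "Mix"}),
        "C004_Family57_Filtered": (24, "Family 57 sequences passing the quality filter", {"Family 57", "Filter", "Mix"}),
        "C006_Family13_ORFS": (148, "Family 13 sequences joined with the isolate ORFs", {"Family 13", "Mix", "Multiple Alignment"}),
        "C007_Family57_ORFS": (144, "Family 57 sequences joined with the isolate ORFs", {"Family 57", "Mix", "Multiple Alignment"}),
        "C008_Family13_Alignments": (148, "Multiple alignment of the family 13 set", {"Family 13", "Multiple Alignment", "Graphic"}),
        "C009_Family57_Alignments": (144, "Multiple alignment of the family 57 set", {"Family 57", "Multiple Alignment", "Graphic"}),
        "C010_Family13_Graph": (3, "Graphics drawn from the family 13 alignment", {"Family 13", "Graphic"}),
        "C011_Family57_Graph": (3, "Graphics drawn from the family 57 alignment", {"Family 57", "Graphic"}),
    }
    for cid, (size, description, groups) in collections.items():
        acc.add_node(
            NodeKind.COLLECTION,
            CollectionFields(
                name=cid.split("_", 1)[1],
                size=size,
                description=description,
                location=_PAYLOADS[cid],
            ),
            groups=groups,
            id=cid,
        )

    activities = [
        # (id, program, function, slot, groups)
        ("A001_Family13_Filter", "seqfilter", "Quality-filter the family 13 sequences", 0, {"Family 13", "Filter"}),
        ("A002_Family57_Filter", "seqfilter", "Quality-filter the family 57 sequences", 1, {"Family 57", "Filter"}),
        ("A003_Family13_Mix", "seqmix", "Join filtered family 13 with the isolate ORFs", 2, {"Family 13", "Mix"}),
        ("A004_Family57_Mix", "seqmix", "Join filtered family 57 with the isolate ORFs", 3, {"Family 57", "Mix"}),
        ("A005_Family13_Alignment", "multalign", "Multiple alignment of the family 13 set", 4, {"Family 13", "Multiple Alignment"}),
        ("A006_Family57_Alignment", "multalign", "Multiple alignment of the family 57 set", 5, {"Family 57", "Multiple Alignment"}),
        ("A007_Family13_Graph", "alignplot", "Draw graphics for the family 13 alignment", 6, {"Family 13", "Graphic"}),
        ("A008_Family57_Graph", "alignplot", "Draw graphics for the family 57 alignment", 7, {"Family 57", "Graphic"}),
    ]
    for aid, program, function, slot, groups in activities:
        acc.add_node(
            NodeKind.ACTIVITY,
            ActivityFields(
                name=aid.split("_", 1)[1],
                program=program,
                program_version="1.0",
                command_line=f"{program} {_PAYLOADS[_inputs_of(aid)[0]]}",
                function=function,
                start_time=t0 + slot * hour,
                end_time=t0 + (slot + 1) * hour,
                environment="Linux x86_64",
            ),
            groups=groups,
            id=aid,
        )

    for aid, _, _, _, _ in activities:
        for cid in _inputs_of(aid):
            acc.add_relation(RelationKind.USED, aid, cid, role="input")
        acc.add_relation(RelationKind.WAS_GENERATED_BY, _output_of(aid), aid, role="output")

    for aid, _, _, _, _ in activities:
        acc.add_relation(RelationKind.WAS_ASSOCIATED_WITH, "AG001_Joao", aid, role="Execution")
    for aid in (
        "A005_Family13_Alignment",
        "A006_Family57_Alignment",
        "A007_Family13_Graph",
        "A008_Family57_Graph",
    ):
        acc.add_relation(RelationKind.WAS_ASSOCIATED_WITH, "C002_Taina", aid, role="Validation")

    # reclassify the machine-derived lineage where the process type is known
    _reclassify(acc, "C003_Family13_Filtered", "C001_Family13", DerivationType.FILTERING)
    _reclassify(acc, "C004_Family57_Filtered", "C002_Family57", DerivationType.FILTERING)
    for derived in ("C006_Family13_ORFS", "C007_Family57_ORFS"):
        for edge in list(acc.edges.values()):
            if edge.auto_derived and edge.source == derived:
                edge.derivation_type = DerivationType.MIXING

    acc.annotate("C001_Family13", "origin", "UNIPROT")
    acc.annotate("C002_Family57", "origin", "UNIPROT")
    acc.annotate("C005_ORFS", "origin", "B. cereus isolate contigs")
    acc.annotate("A005_Family13_Alignment", "program", "multalign 1.0")
    acc.annotate("A006_Family57_Alignment", "program", "multalign 1.0")

    if payload_dir is not None:
        _write_payloads(Path(payload_dir))
    return project


_CHAINS = {
    "A001_Family13_Filter": (["C001_Family13"], "C003_Family13_Filtered"),
    "A002_Family57_Filter": (["C002_Family57"], "C004_Family57_Filtered"),
    "A003_Family13_Mix": (["C003_Family13_Filtered", "C005_ORFS"], "C006_Family13_ORFS"),
    "A004_Family57_Mix": (["C004_Family57_Filtered", "C005_ORFS"], "C007_Family57_ORFS"),
    "A005_Family13_Alignment": (["C006_Family13_ORFS"], "C008_Family13_Alignments"),
    "A006_Family57_Alignment": (["C007_Family57_ORFS"], "C009_Family57_Alignments"),
    "A007_Family13_Graph": (["C008_Family13_Alignments"], "C010_Family13_Graph"),
    "A008_Family57_Graph": (["C009_Family57_Alignments"], "C011_Family57_Graph"),
}


def _inputs_of(activity_id: str) -> list[str]:
    return _CHAINS[activity_id][0]


def _output_of(activity_id: str) -> str:
    return _CHAINS[activity_id][1]


def _reclassify(acc: Account, source: str, target: str, dtype: DerivationType) -> None:
    for edge in acc.edges.values():
        if edge.auto_derived and edge.source == source and edge.target == target:
            edge.derivation_type = dtype
            return
    raise AssertionError(f"no auto-derived edge {source} -> {target}")


# ---------------------------------------------------------------------------
# random accounts with optional violation injection
# ---------------------------------------------------------------------------

#: Rule codes generate_account can inject.  T2 and T3 are two views of the
#: same timing fault, so injecting either produces both violations.
INJECTABLE_ACCOUNT_RULES = (
    "S1", "S2", "S3", "S4", "S5", "S6",
    "T1", "T2", "T3", "T4", "T5", "T6",
    "F1",
)

#: Violation rule codes expected from each injection (the co-set an
#: injection deterministically produces).
EXPECTED_RULES: dict[str, frozenset[str]] = {
    **{code: frozenset({code}) for code in INJECTABLE_ACCOUNT_RULES},
    "T2": frozenset({"T2", "T3"}),
    "T3": frozenset({"T2", "T3"}),
    "P1": frozenset({"P1"}),
    "P2": frozenset({"P2"}),
}


@dataclass
class GeneratorParams:
    """Shape of the random workflow accounts used for property testing."""

    n_chains: int = 2
    chain_length: int = 3
    n_agents: int = 2
    fan_in: int = 2
    seed: int = 0
    violation: Optional[str] = None

    def __post_init__(self):
        for name in ("n_chains", "chain_length", "n_agents", "fan_in"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.violation is not None and self.violation not in EXPECTED_RULES:
            raise ValueError(
                f"unknown violation code {self.violation!r}; expected one of "
                + ", ".join(sorted(EXPECTED_RULES))
            )


def generate_account(params: GeneratorParams) -> Account:
    """A pseudo-random workflow-shaped account, reproducible from the seed.

    Without a ``violation`` the account is valid on all three axes: chains
    of activities over collections with strictly increasing hourly time
    slots, every activity associated to at least one agent.  With a
    ``violation`` exactly one breach of that rule is injected (structural
    breaches bypass the creation API the way a corrupt XML file would).
    """
    if params.violation in ("P1", "P2"):
        raise ValueError(
            f"{params.violation} is a project-level rule; use generate_project"
        )
    rng = random.Random(params.seed)
    hour = timedelta(hours=1)
    t0 = datetime(2020, 1, 6, 8, 0)
    n_slots = params.n_chains * params.chain_length

    acc = Account(
        id=f"WEGEN_{params.seed}",
        name=f"generated workflow {params.seed}",
        execution_date=t0,
        start_time=t0 - hour,
        end_time=t0 + (2 * n_slots + 1) * hour,
    )

    raws = [
        acc.add_node(
            NodeKind.COLLECTION,
            CollectionFields(name=f"raw{k}", size=rng.randint(2, 500)),
            groups={"raw"},
        )
        for k in range(params.fan_in)
    ]
    agents = [
        acc.add_node(NodeKind.AGENT, AgentFields(name=f"agent{k}"))
        for k in range(params.n_agents)
    ]

    stage_kinds = ["filter", "transform", "analyze"]
    activities: list[str] = []
    chain_outputs: list[list[str]] = []
    for chain in range(params.n_chains):
        outputs: list[str] = []
        previous: Optional[str] = None
        for stage in range(params.chain_length):
            slot = chain * params.chain_length + stage
            kind_name = stage_kinds[stage % len(stage_kinds)]
            aid = acc.add_node(
                NodeKind.ACTIVITY,
                ActivityFields(
                    name=f"chain{chain}_{kind_name}{stage}",
                    program=kind_name,
                    program_version="1.0",
                    # one-hour run every two hours: successive stages then
                    # start strictly after their input's generator ended
                    start_time=t0 + 2 * slot * hour,
                    end_time=t0 + (2 * slot + 1) * hour,
                ),
                groups={f"chain{chain}", f"stage{stage}"},
            )
            activities.append(aid)
            inputs = [previous] if previous is not None else list(raws)
            if previous is not None and rng.random() < 0.3:
                inputs.append(rng.choice(raws))
            for cid in dict.fromkeys(inputs):
                acc.add_relation(RelationKind.USED, aid, cid, role="input")
            out = acc.add_node(
                NodeKind.COLLECTION,
                CollectionFields(
                    name=f"chain{chain}_out{stage}", size=rng.randint(2, 500)
                ),
                groups={f"chain{chain}"},
            )
            acc.add_relation(RelationKind.WAS_GENERATED_BY, out, aid, role="output")
            outputs.append(out)
            previous = out
        chain_outputs.append(outputs)

    for aid in activities:
        acc.add_relation(
            RelationKind.WAS_ASSOCIATED_WITH, agents[0], aid, role="Execution"
        )
        for other in agents[1:]:
            if rng.random() < 0.4:
                acc.add_relation(
                    RelationKind.WAS_ASSOCIATED_WITH, other, aid, role="Validation"
                )

    if params.violation is not None:
        _inject(acc, params, raws, activities, chain_outputs)
    return acc


def _inject(
    acc: Account,
    params: GeneratorParams,
    raws: list[str],
    activities: list[str],
    chain_outputs: list[list[str]],
) -> None:
    """Breach exactly one rule, leaving every other rule satisfied.

    Structural breaches are planted by direct mutation, mimicking what a
    corrupt or hand-edited XML document could contain; temporal and
    functional ones retime or relocate a single element.
    """
    code = params.violation
    first_activity = activities[0]

    if code == "S1":
        acc.id = sorted(acc.nodes)[0]
    elif code == "S2":
        acc.edges["X900"] = RelationEdge(
            id="X900",
            kind=RelationKind.USED,
            source=first_activity,
            target="GHOST",
        )
    elif code == "S3":
        agent = next(n.id for n in acc.nodes.values() if n.kind is NodeKind.AGENT)
        acc.edges["X900"] = RelationEdge(
            id="X900", kind=RelationKind.USED, source=agent, target=raws[0]
        )
    elif code == "S4":
        original = next(e for e in acc.edges.values() if e.kind is RelationKind.USED)
        acc.edges["X900"] = RelationEdge(
            id="X900",
            kind=RelationKind.USED,
            source=original.source,
            target=original.target,
        )
    elif code == "S5":
        extra = acc.add_node(
            NodeKind.COLLECTION, CollectionFields(name="extra", size=2)
        )
        # two generating activities; both edges planted directly so no
        # derivation maintenance runs and no other rule is disturbed
        acc.edges["X900"] = RelationEdge(
            id="X900",
            kind=RelationKind.WAS_GENERATED_BY,
            source=extra,
            target=activities[-1],
        )
        acc.edges["X901"] = RelationEdge(
            id="X901",
            kind=RelationKind.WAS_GENERATED_BY,
            source=extra,
            target=first_activity,
        )
    elif code == "S6":
        extra = acc.add_node(
            NodeKind.COLLECTION, CollectionFields(name="extra", size=2)
        )
        acc.edges["X900"] = RelationEdge(
            id="X900",
            kind=RelationKind.WAS_DERIVED_FROM,
            source=extra,
            target=extra,
        )
    elif code == "T1":
        fields = acc.nodes[first_activity].fields
        fields.start_time = fields.end_time
    elif code in ("T2", "T3"):
        # a stage-1 activity starts exactly when its input's generator ended
        late_user = activities[1] if params.chain_length > 1 else None
        if late_user is None:
            raise ValueError("T2/T3 injection needs chain_length >= 2")
        generator = acc.nodes[activities[0]].fields
        acc.nodes[late_user].fields.start_time = generator.end_time
    elif code == "T4":
        # earliest output "derived from" the latest one: original not older
        acc.add_relation(
            RelationKind.WAS_DERIVED_FROM,
            chain_outputs[0][0],
            chain_outputs[-1][-1],
            derivation_type=DerivationType.OTHER,
        )
    elif code == "T5":
        acc.start_time, acc.end_time = acc.end_time, acc.start_time
    elif code == "T6":
        fields = acc.nodes[first_activity].fields
        fields.start_time = acc.start_time - timedelta(hours=1)
    elif code == "F1":
        raw = acc.nodes[raws[0]]
        raw.fields.location = f"missing_payload_{params.seed}.fasta"
    else:  # pragma: no cover - guarded by GeneratorParams
        raise ValueError(f"unknown violation code {code!r}")


def generate_project(params: GeneratorParams) -> ProvenanceProject:
    """A one-account project, optionally breaching a project-window rule.

    Account-level codes are passed through to :func:`generate_account`;
    ``P1`` inverts the project window (containment is then not judged) and
    ``P2`` moves the window so the account falls outside it.
    """
    account_violation = (
        params.violation if params.violation not in ("P1", "P2") else None
    )
    account = generate_account(
        GeneratorParams(
            n_chains=params.n_chains,
            chain_length=params.chain_length,
            n_agents=params.n_agents,
            fan_in=params.fan_in,
            seed=params.seed,
            violation=account_violation,
        )
    )
    day = timedelta(days=1)
    project = new_project(
        f"generated project {params.seed}",
        id=f"PGEN_{params.seed}",
        start_date=account.start_time - day,
        end_date=account.end_time + day,
    )
    project.accounts.append(account)
    if params.violation == "P1":
        project.start_date, project.end_date = project.end_date, project.start_date
    elif params.violation == "P2":
        project.start_date = account.start_time - 10 * day
        project.end_date = account.start_time - 5 * day
    return project
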