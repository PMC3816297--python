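"""Structural, temporal and functional restriction checking and validity inference.

Restrictions fall on three independent axes, and an account (or a whole
project) is *valid* on an axis exactly when no restriction of that axis is
breached:

structural
    Identifier uniqueness, edges anchored on existing nodes of the kinds
    the relation expects, no duplicate relations, a single generating
    activity per entity/collection, and distinct endpoints for
    ``wasDerivedFrom``.  Checks re-verify stored state, so graphs
    deserialised from corrupt files are caught even though creation-time
    checks would have rejected them.

temporal
    Activities must start strictly before they end; an entity's implicit
    start time is the end time of its generating activity, and every use or
    derivation must respect those times; account and project windows bound
    their activities and accounts (non-strictly).  Rules involving an
    entity's start time are vacuously satisfied when the entity has no
    generator (raw workflow inputs have no start time of their own).

functional
    Every entity or collection that names a payload location must point at
    a resolvable file.  A missing payload is not an *error* in the
    experiment — it means the execution can no longer be reproduced — but
    it makes the account functionally invalid.

Violations are data, never exceptions; checkers are pure and return stable,
sorted lists so reports are diffable.

Rule codes
----------
======  ==============================================================
S1      identifier shared between the account, a node, or an edge
S2      edge endpoint does not exist
S3      edge endpoint kinds do not match the relation signature
S4      two relations share (kind, source, target)
S5      entity/collection with more than one wasGeneratedBy
S6      wasDerivedFrom with origin equal to destination
T1      activity start time not strictly before its end time
T2      entity used by an activity starting before its generator ended
T3      activity using an entity whose generator had not finished
T4      derivation whose original is not strictly older than the derived
T5      account start time after its end time
T6      activity outside the account's time window
P1      project start date after its end date
P2      account outside the project's time window
F1      payload location does not resolve to an existing file
======  ==============================================================

T2 and T3 inspect the same timing fault from the two edges involved (the
``wasGeneratedBy`` of the entity and the ``used`` of the late activity), so
they always fire together — mirroring how the generation and use rules are
two readings of one ordering constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import (
    Account,
    ENDPOINT_SIGNATURES,
    NodeKind,
    ProvenanceProject,
    RelationKind,
)

__all__ = [
    "Violation",
    "ValidityStatus",
    "PayloadResolver",
    "STRUCTURAL_RULES",
    "TEMPORAL_RULES",
    "PROJECT_RULES",
    "FUNCTIONAL_RULES",
    "ALL_RULES",
    "check_structural",
    "check_temporal",
    "check_project_temporal",
    "check_functional",
    "infer_account_validity",
    "infer_project_validity",
]

STRUCTURAL_RULES = ("S1", "S2", "S3", "S4", "S5", "S6")
TEMPORAL_RULES = ("T1", "T2", "T3", "T4", "T5", "T6")
PROJECT_RULES = ("P1", "P2")
FUNCTIONAL_RULES = ("F1",)
ALL_RULES = STRUCTURAL_RULES + TEMPORAL_RULES + PROJECT_RULES + FUNCTIONAL_RULES

_AXIS_OF_RULE = {
    **{r: "structural" for r in STRUCTURAL_RULES},
    **{r: "temporal" for r in TEMPORAL_RULES},
    **{r: "temporal" for r in PROJECT_RULES},
    **{r: "functional" for r in FUNCTIONAL_RULES},
}


@dataclass(frozen=True)
class Violation:
    """One breach of one restriction, naming the elements involved."""

    axis: str
    rule: str
    elements: tuple[str, ...]
    message: str

    def __post_init__(self):
        if self.rule not in _AXIS_OF_RULE:
            raise ValueError(f"unknown rule code {self.rule!r}")
        if _AXIS_OF_RULE[self.rule] != self.axis:
            raise ValueError(f"rule {self.rule} does not belong to axis {self.axis}")
        if not self.elements:
            raise ValueError("a violation must name at least one element")


@dataclass
class ValidityStatus:
    """Three-axis verdict for an account or project, with the evidence."""

    structural_valid: bool
    temporal_valid: bool
    functional_valid: bool
    violations: list[Violation] = field(default_factory=list)

    @classmethod
    def from_violations(cls, violations: list[Violation]) -> "ValidityStatus":
        axes = {v.axis for v in violations}
        return cls(
            structural_valid="structural" not in axes,
            temporal_valid="temporal" not in axes,
            functional_valid="functional" not in axes,
            violations=sorted(violations, key=lambda v: (v.rule, v.elements)),
        )

    @property
    def all_valid(self) -> bool:
        return self.structural_valid and self.temporal_valid and self.functional_valid


class PayloadResolver:
    """Maps ``location`` text to checkable filesystem paths.

    Locations are the level-2 half of the model: the provenance graph holds
    a few bytes of metadata while the payload files stay in place, linked
    by these locations.  Because account XML moves between machines more
    easily than terabyte payloads do, relative locations are resolved
    against a configurable base directory.
    """

    def __init__(self, base_dir: Optional[Path | str] = None):
        self.base_dir = Path(base_dir) if base_dir is not None else Path(".")

    def resolve(self, location: str) -> Path:
        p = Path(location)
        return p if p.is_absolute() else self.base_dir / p

    def exists(self, location: str) -> bool:
        return self.resolve(location).exists()


def _sorted(violations: list[Violation]) -> list[Violation]:
    return sorted(violations, key=lambda v: (v.rule, v.elements))


# ---------------------------------------------------------------------------
# structural
# ---------------------------------------------------------------------------


def check_structural(account: Account) -> list[Violation]:
    """All structural violations in ``account``, sorted by rule then element."""
    out: list[Violation] = []

    node_ids = set(account.nodes)
    edge_ids = set(account.edges)
    if account.id in node_ids or account.id in edge_ids:
        out.append(
            Violation(
                "structural",
                "S1",
                (account.id,),
                f"identifier {account.id!r} names both the account and another "
                "element; each element of the graph must have a single identifier",
            )
        )
    for shared in sorted(node_ids & edge_ids):
        out.append(
            Violation(
                "structural",
                "S1",
                (shared,),
                f"identifier {shared!r} names both a node and an edge",
            )
        )

    triples: dict[tuple[str, str, str], list[str]] = {}
    generated_by: dict[str, list[str]] = {}
    for eid in sorted(account.edges):
        e = account.edges[eid]
        dangling = [ep for ep in (e.source, e.target) if ep not in account.nodes]
        if dangling:
            out.append(
                Violation(
                    "structural",
                    "S2",
                    (eid, *dangling),
                    f"edge {eid} ({e.kind.value}) references nonexistent "
                    f"node(s) {', '.join(repr(d) for d in dangling)}",
                )
            )
            continue
        src_kinds, tgt_kinds = ENDPOINT_SIGNATURES[e.kind]
        src_kind = account.nodes[e.source].kind
        tgt_kind = account.nodes[e.target].kind
        if src_kind not in src_kinds or tgt_kind not in tgt_kinds:
            out.append(
                Violation(
                    "structural",
                    "S3",
                    (eid, e.source, e.target),
                    f"invalid endpoint kind for {e.kind.value}: "
                    f"{src_kind.value} -> {tgt_kind.value}",
                )
            )
        triples.setdefault(e.triple(), []).append(eid)
        if e.kind is RelationKind.WAS_GENERATED_BY:
            generated_by.setdefault(e.source, []).append(eid)
        if e.kind is RelationKind.WAS_DERIVED_FROM and e.source == e.target:
            out.append(
                Violation(
                    "structural",
                    "S6",
                    (eid, e.source),
                    f"wasDerivedFrom edge {eid} has origin equal to destination "
                    f"({e.source!r})",
                )
            )

    for triple, eids in sorted(triples.items()):
        if len(eids) > 1:
            out.append(
                Violation(
                    "structural",
                    "S4",
                    tuple(sorted(eids)),
                    "identical relationships {} ({}: {} -> {})".format(
                        ", ".join(sorted(eids)), *triple
                    ),
                )
            )
    for node_id, eids in sorted(generated_by.items()):
        if len(eids) > 1:
            out.append(
                Violation(
                    "structural",
                    "S5",
                    (node_id, *sorted(eids)),
                    f"{node_id!r} carries {len(eids)} wasGeneratedBy relationships; "
                    "only one generating activity is allowed",
                )
            )
    return _sorted(out)


# ---------------------------------------------------------------------------
# temporal
# ---------------------------------------------------------------------------


def _activity_times(account: Account, node_id: str):
    node = account.nodes.get(node_id)
    if node is None or node.kind is not NodeKind.ACTIVITY:
        return None, None
    return node.fields.start_time, node.fields.end_time


def _entity_start(account: Account, node_id: str):
    """An entity's start time: the end time of its generating activity.

    Raw inputs (no generator) have no start time; rules that need one are
    vacuously satisfied for them.
    """
    gen = account.generator_of(node_id)
    if gen is None:
        return None
    _, end = _activity_times(account, gen.target)
    return end


def check_temporal(account: Account) -> list[Violation]:
    """All temporal violations in ``account``, sorted by rule then element.

    Edges with dangling endpoints are skipped here — they are structural
    faults and are reported by :func:`check_structural`.
    """
    out: list[Violation] = []

    for nid in sorted(account.nodes):
        node = account.nodes[nid]
        if node.kind is not NodeKind.ACTIVITY:
            continue
        start, end = node.fields.start_time, node.fields.end_time
        if start is not None and end is not None and start >= end:
            out.append(
                Violation(
                    "temporal",
                    "T1",
                    (nid,),
                    f"activity {nid} start time {start.isoformat()} is not "
                    f"strictly before its end time {end.isoformat()}",
                )
            )

    # T2/T3: an activity may only use an entity after its generator finished.
    used_edges = [
        e
        for e in account.edges.values()
        if e.kind is RelationKind.USED
        and e.source in account.nodes
        and e.target in account.nodes
    ]
    for e in sorted(used_edges, key=lambda e: e.id):
        user_start, _ = _activity_times(account, e.source)
        gen = account.generator_of(e.target)
        if gen is None or user_start is None:
            continue
        _, gen_end = _activity_times(account, gen.target)
        if gen_end is None:
            continue
        if user_start <= gen_end:
            out.append(
                Violation(
                    "temporal",
                    "T2",
                    (gen.id, e.target, e.source),
                    f"{e.target} is used by {e.source} starting "
                    f"{user_start.isoformat()}, not after its generator "
                    f"{gen.target} ended ({gen_end.isoformat()})",
                )
            )
            out.append(
                Violation(
                    "temporal",
                    "T3",
                    (e.id, e.source, e.target),
                    f"activity {e.source} uses {e.target} but starts "
                    f"{user_start.isoformat()}, before its generator "
                    f"{gen.target} ended ({gen_end.isoformat()})",
                )
            )

    # T4: the original must be strictly older than the derived entity.
    for e in sorted(account.edges_of_kind(RelationKind.WAS_DERIVED_FROM), key=lambda e: e.id):
        if e.source not in account.nodes or e.target not in account.nodes:
            continue
        original_start = _entity_start(account, e.target)
        derived_generation = _entity_start(account, e.source)
        if original_start is None or derived_generation is None:
            continue
        if original_start >= derived_generation:
            out.append(
                Violation(
                    "temporal",
                    "T4",
                    (e.id, e.source, e.target),
                    f"{e.source} derives from {e.target}, but the original's "
                    f"start time ({original_start.isoformat()}) is not before "
                    f"the derived one's generation ({derived_generation.isoformat()})",
                )
            )

    # T5/T6: account window consistency and containment.  Containment is
    # only judged against a well-formed window.
    window_ok = True
    if (
        account.start_time is not None
        and account.end_time is not None
        and account.start_time > account.end_time
    ):
        window_ok = False
        out.append(
            Violation(
                "temporal",
                "T5",
                (account.id,),
                f"account {account.id} start time "
                f"{account.start_time.isoformat()} is after its end time "
                f"{account.end_time.isoformat()}",
            )
        )
    if window_ok:
        for nid in sorted(account.nodes):
            node = account.nodes[nid]
            if node.kind is not NodeKind.ACTIVITY:
                continue
            start, end = node.fields.start_time, node.fields.end_time
            too_early = (
                account.start_time is not None
                and start is not None
                and start < account.start_time
            )
            too_late = (
                account.end_time is not None
                and end is not None
                and end > account.end_time
            )
            if too_early or too_late:
                out.append(
                    Violation(
                        "temporal",
                        "T6",
                        (nid, account.id),
                        f"activity {nid} runs outside the account window of "
                        f"{account.id}",
                    )
                )
    return _sorted(out)


def check_project_temporal(project: ProvenanceProject) -> list[Violation]:
    """Project-window violations: P1 (inverted window), P2 (stray account)."""
    out: list[Violation] = []
    window_ok = True
    if (
        project.start_date is not None
        and project.end_date is not None
        and project.start_date > project.end_date
    ):
        window_ok = False
        out.append(
            Violation(
                "temporal",
                "P1",
                (project.id,),
                f"project {project.id} start date "
                f"{project.start_date.isoformat()} is after its end date "
                f"{project.end_date.isoformat()}",
            )
        )
    if window_ok:
        for acc in project.accounts:
            too_early = (
                project.start_date is not None
                and acc.start_time is not None
                and acc.start_time < project.start_date
            )
            too_late = (
                project.end_date is not None
                and acc.end_time is not None
                and acc.end_time > project.end_date
            )
            if too_early or too_late:
                out.append(
                    Violation(
                        "temporal",
                        "P2",
                        (acc.id, project.id),
                        f"account {acc.id} was executed outside the window of "
                        f"project {project.id}",
                    )
                )
    return _sorted(out)


# ---------------------------------------------------------------------------
# functional
# ---------------------------------------------------------------------------


def check_functional(
    account: Account, resolver: Optional[PayloadResolver] = None
) -> list[Violation]:
    """F1 violations: located payloads that no longer resolve to files.

    Entities and collections without a location are skipped — not every
    node links level-2 data.
    """
    resolver = resolver or PayloadResolver()
    out: list[Violation] = []
    for nid in sorted(account.nodes):
        node = account.nodes[nid]
        if node.kind not in (NodeKind.ENTITY, NodeKind.COLLECTION):
            continue
        location = node.fields.location
        if not location:
            continue
        if not resolver.exists(location):
            out.append(
                Violation(
                    "functional",
                    "F1",
                    (nid,),
                    f"{nid} points at payload {location!r}, which does not "
                    f"resolve under {resolver.base_dir}; the experiment cannot "
                    "be re-executed from this account",
                )
            )
    return _sorted(out)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def infer_account_validity(
    account: Account, resolver: Optional[PayloadResolver] = None
) -> ValidityStatus:
    """Run all three checkers and fold the results into a three-axis verdict."""
    violations = (
        check_structural(account)
        + check_temporal(account)
        + check_functional(account, resolver)
    )
    return ValidityStatus.from_violations(violations)


def infer_project_validity(
    project: ProvenanceProject, resolver: Optional[PayloadResolver] = None
) -> ValidityStatus:
    """Project validity: project-level checks plus every account's verdict.

    A single account invalid on an axis makes the whole project invalid on
    that axis; an empty project with a consistent window is valid on all
    three axes.
    """
    violations: list[Violation] = list(check_project_temporal(project))
    seen_ids: set[str] = set()
    for acc in project.accounts:
        if acc.id in seen_ids:
            violations.append(
                Violation(
                    "structural",
                    "S1",
                    (acc.id, project.id),
                    f"identifier {acc.id!r} names two accounts of project "
                    f"{project.id!r}",
                )
            )
        seen_ids.add(acc.id)
        violations.extend(infer_account_validity(acc, resolver).violations)
    return ValidityStatus.from_violations(violations)
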