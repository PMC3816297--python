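"""Typed provenance-graph model for bioinformatics workflow executions.

The in-memory model follows the PROV-DM core vocabulary as specialised for
genome-project workflows: a :class:`ProvenanceProject` joins the repeated
executions of one project's workflow, each execution being an
:class:`Account` — a directed, typed provenance graph.  Graph nodes are
agents (people or services), activities (program runs, the only nodes with
start/end times), entities (single data objects) and collections (entities
with more than one member, e.g. a multi-record FASTA file).  Edges are the
PROV-DM relations ``used``, ``wasGeneratedBy``, ``wasAssociatedWith``,
``wasDerivedFrom`` and ``memberOf``.

Two behaviours distinguish the model from a plain labelled digraph:

* creation-time structural rules (identifier uniqueness, endpoint-kind
  signatures, no duplicate relations, a single generating activity per
  entity, no self-derivation) are enforced when nodes and edges are added;
* ``wasDerivedFrom`` lineage is maintained automatically: whenever an
  activity both generated Y and used X, the edge Y → X exists, and it
  disappears when the supporting ``used`` / ``wasGeneratedBy`` pair does.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Union

from .errors import ProvenanceError, StructuralError, TemporalError

__all__ = [
    "NodeKind",
    "RelationKind",
    "DerivationType",
    "Annotation",
    "AgentFields",
    "ActivityFields",
    "EntityFields",
    "CollectionFields",
    "Node",
    "RelationEdge",
    "Account",
    "ProvenanceProject",
    "new_project",
    "new_account",
]


class NodeKind(str, enum.Enum):
    AGENT = "agent"
    ACTIVITY = "activity"
    ENTITY = "entity"
    COLLECTION = "collection"


class RelationKind(str, enum.Enum):
    USED = "used"
    WAS_GENERATED_BY = "wasGeneratedBy"
    WAS_ASSOCIATED_WITH = "wasAssociatedWith"
    WAS_DERIVED_FROM = "wasDerivedFrom"
    MEMBER_OF = "memberOf"


class DerivationType(str, enum.Enum):
    """How a derived collection relates to its original.

    ``filtering``: derived by discarding records; ``ordering``: rearranged
    by some criterion; ``mixing``: the derived data has a different format
    or composition than the original; ``other``: anything else (the default
    for automatically maintained derivation edges).
    """

    FILTERING = "filtering"
    ORDERING = "ordering"
    MIXING = "mixing"
    OTHER = "other"


#: (allowed source kinds, allowed target kinds) per relation kind.  Edges
#: point from the newer element toward its origin, so lineage is read by
#: walking edges: used goes activity -> input, wasGeneratedBy goes
#: output -> activity, wasAssociatedWith goes agent -> activity.
ENDPOINT_SIGNATURES: dict[RelationKind, tuple[frozenset, frozenset]] = {
    RelationKind.USED: (
        frozenset({NodeKind.ACTIVITY}),
        frozenset({NodeKind.ENTITY, NodeKind.COLLECTION}),
    ),
    RelationKind.WAS_GENERATED_BY: (
        frozenset({NodeKind.ENTITY, NodeKind.COLLECTION}),
        frozenset({NodeKind.ACTIVITY}),
    ),
    RelationKind.WAS_ASSOCIATED_WITH: (
        frozenset({NodeKind.AGENT}),
        frozenset({NodeKind.ACTIVITY}),
    ),
    RelationKind.WAS_DERIVED_FROM: (
        frozenset({NodeKind.ENTITY, NodeKind.COLLECTION}),
        frozenset({NodeKind.ENTITY, NodeKind.COLLECTION}),
    ),
    RelationKind.MEMBER_OF: (
        frozenset({NodeKind.ENTITY}),
        frozenset({NodeKind.COLLECTION}),
    ),
}


@dataclass
class Annotation:
    """Free-form key/text note attachable to any element of the graph."""

    key: str
    text: str


@dataclass
class AgentFields:
    name: str
    institution: str = ""
    position: str = ""
    function: str = ""
    notes: str = ""


@dataclass
class ActivityFields:
    name: str
    program: str = ""
    program_version: str = ""
    command_line: str = ""
    function: str = ""
    start_time: Optional[datetime] = None
    end_time: Optional[datetime] = None
    environment: str = ""
    notes: str = ""


@dataclass
class EntityFields:
    name: str
    description: str = ""
    location: str = ""
    notes: str = ""


@dataclass
class CollectionFields:
    """A collection is an entity-like node whose ``size`` exceeds 1."""

    name: str
    size: int = 2
    description: str = ""
    location: str = ""
    notes: str = ""


FieldRecord = Union[AgentFields, ActivityFields, EntityFields, CollectionFields]

_FIELDS_BY_KIND = {
    NodeKind.AGENT: AgentFields,
    NodeKind.ACTIVITY: ActivityFields,
    NodeKind.ENTITY: EntityFields,
    NodeKind.COLLECTION: CollectionFields,
}

_ID_PREFIX = {
    NodeKind.AGENT: "AG",
    NodeKind.ACTIVITY: "A",
    NodeKind.ENTITY: "C",
    NodeKind.COLLECTION: "C",
}


@dataclass
class Node:
    id: str
    kind: NodeKind
    fields: FieldRecord
    groups: set[str] = field(default_factory=set)
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class RelationEdge:
    id: str
    kind: RelationKind
    source: str
    target: str
    role: Optional[str] = None
    derivation_type: Optional[DerivationType] = None
    auto_derived: bool = False
    annotations: list[Annotation] = field(default_factory=list)

    def triple(self) -> tuple[str, str, str]:
        return (self.kind.value, self.source, self.target)


class Account:
    """One workflow execution: a provenance graph plus execution metadata.

    Nodes and edges are keyed by identifier.  All mutation goes through
    :meth:`add_node`, :meth:`add_relation`, :meth:`remove_relation` and
    :meth:`annotate`, which enforce the creation-time structural rules and
    keep the automatically derived ``wasDerivedFrom`` edges consistent.
    """

    def __init__(
        self,
        id: str,
        name: str,
        description: str = "",
        location: str = "",
        execution_date: Optional[datetime] = None,
        start_time: Optional[datetime] = None,
        end_time: Optional[datetime] = None,
        notes: str = "",
        version: int = 1,
        version_date: Optional[datetime] = None,
    ):
        if not id:
            raise StructuralError("account identifier must be nonempty")
        if start_time is not None and end_time is not None and start_time > end_time:
            raise TemporalError(
                "account start time must be less than or equal to its end time"
            )
        self.id = id
        self.name = name
        self.description = description
        self.location = location
        self.execution_date = execution_date
        self.start_time = start_time
        self.end_time = end_time
        self.notes = notes
        self.version = version
        self.version_date = version_date
        self.nodes: dict[str, Node] = {}
        self.edges: dict[str, RelationEdge] = {}
        self.annotations: list[Annotation] = []

    # -- identifier helpers -------------------------------------------------

    def _known_ids(self) -> set[str]:
        return {self.id} | set(self.nodes) | set(self.edges)

    def _fresh_id(self, prefix: str) -> str:
        pat = re.compile(re.escape(prefix) + r"(\d+)$")
        taken = self._known_ids()
        n = 1
        for known in taken:
            m = pat.match(known)
            if m:
                n = max(n, int(m.group(1)) + 1)
        while f"{prefix}{n:03d}" in taken:  # defensive; suffixes may be non-numeric
            n += 1
        return f"{prefix}{n:03d}"

    # -- nodes --------------------------------------------------------------

    def add_node(
        self,
        kind: NodeKind | str,
        fields: FieldRecord,
        groups: Iterable[str] = (),
        id: Optional[str] = None,
    ) -> str:
        """Insert a node, returning its identifier.

        User-supplied identifiers are taken verbatim; generated ones follow
        the AG###/A###/C### convention.  Rejects duplicate identifiers and
        collections whose size does not exceed 1.
        """
        kind = NodeKind(kind)
        expected = _FIELDS_BY_KIND[kind]
        if not isinstance(fields, expected):
            raise StructuralError(
                f"{kind.value} node requires {expected.__name__}, got "
                f"{type(fields).__name__}"
            )
        if not fields.name:
            raise StructuralError(f"{kind.value} name must be nonempty")
        if kind is NodeKind.COLLECTION and fields.size <= 1:
            raise StructuralError(
                "a collection is an entity with size greater than 1; "
                f"got size {fields.size}"
            )
        if id is None:
            id = self._fresh_id(_ID_PREFIX[kind])
        if id in self._known_ids():
            raise StructuralError(
                f"identifier {id!r} already used in account {self.id!r}; "
                "each element of the graph must have a single identifier"
            )
        self.nodes[id] = Node(id=id, kind=kind, fields=fields, groups=set(groups))
        return id

    # -- relations ----------------------------------------------------------

    def _check_relation(
        self,
        kind: RelationKind,
        source: str,
        target: str,
    ) -> None:
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise StructuralError(
                    f"nonexistent node {endpoint!r}: relationships can only be "
                    "created from existing nodes"
                )
        src_kinds, tgt_kinds = ENDPOINT_SIGNATURES[kind]
        if (
            self.nodes[source].kind not in src_kinds
            or self.nodes[target].kind not in tgt_kinds
        ):
            raise StructuralError(
                f"invalid endpoint kind for {kind.value}: "
                f"{self.nodes[source].kind.value} -> {self.nodes[target].kind.value}"
            )
        if any(e.triple() == (kind.value, source, target) for e in self.edges.values()):
            raise StructuralError(
                f"identical relationship exists: {kind.value}({source} -> {target})"
            )
        if kind is RelationKind.WAS_GENERATED_BY and any(
            e.kind is RelationKind.WAS_GENERATED_BY and e.source == source
            for e in self.edges.values()
        ):
            raise StructuralError(
                f"entity already generated: {source!r} may carry only one "
                "wasGeneratedBy relationship"
            )
        if kind is RelationKind.WAS_DERIVED_FROM and source == target:
            raise StructuralError(
                "origin equals destination: wasDerivedFrom endpoints must differ"
            )

    def add_relation(
        self,
        kind: RelationKind | str,
        source: str,
        target: str,
        role: Optional[str] = None,
        derivation_type: Optional[DerivationType | str] = None,
        id: Optional[str] = None,
    ) -> str:
        """Insert an edge, returning its identifier.

        Triggers derivation maintenance, so adding a ``used`` or
        ``wasGeneratedBy`` edge may create ``wasDerivedFrom`` edges as a
        side effect.
        """
        kind = RelationKind(kind)
        self._check_relation(kind, source, target)
        if derivation_type is not None:
            derivation_type = DerivationType(derivation_type)
            if kind is not RelationKind.WAS_DERIVED_FROM:
                raise StructuralError(
                    "derivation_type is only meaningful for wasDerivedFrom"
                )
        if id is None:
            id = self._fresh_id("R")
        elif id in self._known_ids():
            raise StructuralError(f"identifier {id!r} already used")
        self.edges[id] = RelationEdge(
            id=id,
            kind=kind,
            source=source,
            target=target,
            role=role,
            derivation_type=derivation_type,
            auto_derived=False,
        )
        self.derive_was_derived_from()
        return id

    def remove_relation(self, edge_id: str) -> None:
        """Remove an edge and re-run derivation maintenance.

        Automatically derived edges cannot be removed directly — they vanish
        only when a supporting ``used``/``wasGeneratedBy`` pair does.
        """
        edge = self.edges.get(edge_id)
        if edge is None:
            raise ProvenanceError(f"unknown edge {edge_id!r}")
        if edge.auto_derived:
            raise StructuralError(
                "auto-derived wasDerivedFrom edges are maintained automatically "
                "and cannot be removed directly; remove the supporting used/"
                "wasGeneratedBy relation instead"
            )
        del self.edges[edge_id]
        self.derive_was_derived_from()

    # -- derivation maintenance ---------------------------------------------

    def _derivation_pairs(self) -> set[tuple[str, str]]:
        """All (generated, used) pairs implied by the graph.

        Y -> X is implied when one activity A has wasGeneratedBy(Y -> A) and
        used(A -> X).  Pairs with Y == X are excluded: a self-derivation
        would itself be structurally invalid.  Edges with dangling endpoints
        (possible after deserialising a corrupt file) contribute nothing.
        """
        generated: dict[str, list[str]] = {}
        used: dict[str, list[str]] = {}
        for e in self.edges.values():
            if e.source not in self.nodes or e.target not in self.nodes:
                continue
            if e.kind is RelationKind.WAS_GENERATED_BY:
                generated.setdefault(e.target, []).append(e.source)
            elif e.kind is RelationKind.USED:
                used.setdefault(e.source, []).append(e.target)
        return {
            (y, x)
            for activity, outputs in generated.items()
            for y in outputs
            for x in used.get(activity, ())
            if y != x
        }

    def derive_was_derived_from(self) -> set[str]:
        """Bring the auto-derived ``wasDerivedFrom`` set up to date.

        Idempotent.  Manually added derivation edges are preserved and
        shadow the auto edge for the same (source, target); surviving auto
        edges keep their identifier and any user-reclassified derivation
        type; new ones default to type ``other``.  Returns the ids of the
        auto-derived edges after maintenance.
        """
        pairs = self._derivation_pairs()
        manual = {
            (e.source, e.target)
            for e in self.edges.values()
            if e.kind is RelationKind.WAS_DERIVED_FROM and not e.auto_derived
        }
        stale = [
            eid
            for eid, e in self.edges.items()
            if e.auto_derived
            and ((e.source, e.target) not in pairs or (e.source, e.target) in manual)
        ]
        for eid in stale:
            del self.edges[eid]
        present = {
            (e.source, e.target)
            for e in self.edges.values()
            if e.kind is RelationKind.WAS_DERIVED_FROM
        }
        for y, x in sorted(pairs - present):
            eid = self._fresh_id("R")
            self.edges[eid] = RelationEdge(
                id=eid,
                kind=RelationKind.WAS_DERIVED_FROM,
                source=y,
                target=x,
                derivation_type=DerivationType.OTHER,
                auto_derived=True,
            )
        return {eid for eid, e in self.edges.items() if e.auto_derived}

    # -- annotations ---------------------------------------------------------

    def annotate(self, element_id: str, key: str, text: str) -> None:
        """Append an annotation to a node, an edge, or the account itself."""
        if element_id == self.id:
            self.annotations.append(Annotation(key, text))
        elif element_id in self.nodes:
            self.nodes[element_id].annotations.append(Annotation(key, text))
        elif element_id in self.edges:
            self.edges[element_id].annotations.append(Annotation(key, text))
        else:
            raise ProvenanceError(
                f"unknown element {element_id!r}: annotations attach to existing "
                "nodes, edges or the account"
            )

    # -- queries -------------------------------------------------------------

    def nodes_of_kind(self, kind: NodeKind | str) -> list[Node]:
        kind = NodeKind(kind)
        return [n for n in self.nodes.values() if n.kind is kind]

    def edges_of_kind(self, kind: RelationKind | str) -> list[RelationEdge]:
        kind = RelationKind(kind)
        return [e for e in self.edges.values() if e.kind is kind]

    def generator_of(self, node_id: str) -> Optional[RelationEdge]:
        """The wasGeneratedBy edge leaving ``node_id``, if any.

        A well-formed graph has at most one; on corrupt graphs the edge with
        the smallest identifier is returned so downstream checks stay
        deterministic.
        """
        candidates = sorted(
            (
                e
                for e in self.edges.values()
                if e.kind is RelationKind.WAS_GENERATED_BY and e.source == node_id
            ),
            key=lambda e: e.id,
        )
        return candidates[0] if candidates else None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Account {self.id!r} v{self.version}: {len(self.nodes)} nodes, "
            f"{len(self.edges)} edges>"
        )


class ProvenanceProject:
    """Top-level container joining the workflow executions of one project."""

    def __init__(
        self,
        id: str,
        name: str,
        description: str = "",
        funding_institutions: Optional[list[str]] = None,
        partner_institutions: Optional[list[str]] = None,
        coordinator: str = "",
        start_date: Optional[datetime] = None,
        end_date: Optional[datetime] = None,
    ):
        if not name:
            raise ProvenanceError("project name must be nonempty")
        if start_date is not None and end_date is not None and start_date > end_date:
            raise TemporalError(
                "project start date must be less than or equal to its end date"
            )
        self.id = id
        self.name = name
        self.description = description
        self.funding_institutions = list(funding_institutions or [])
        self.partner_institutions = list(partner_institutions or [])
        self.coordinator = coordinator
        self.start_date = start_date
        self.end_date = end_date
        self.accounts: list[Account] = []

    def account(self, account_id: str) -> Account:
        for acc in self.accounts:
            if acc.id == account_id:
                return acc
        raise ProvenanceError(f"no account {account_id!r} in project {self.id!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ProvenanceProject {self.id!r}: {len(self.accounts)} accounts>"


def new_project(
    name: str,
    id: Optional[str] = None,
    **metadata,
) -> ProvenanceProject:
    """Create an empty project; the identifier defaults to a slug of the name."""
    if id is None:
        id = "P_" + re.sub(r"\W+", "_", name).strip("_")
    return ProvenanceProject(id=id, name=name, **metadata)


def new_account(
    project: ProvenanceProject,
    name: str,
    id: Optional[str] = None,
    **metadata,
) -> Account:
    """Append a fresh workflow-execution account (version 1) to a project."""
    if id is None:
        id = "WE{:03d}_{}".format(
            len(project.accounts) + 1, re.sub(r"\W+", "_", name).strip("_")
        )
    if any(acc.id == id for acc in project.accounts):
        raise StructuralError(
            f"identifier {id!r} already names an account in project "
            f"{project.id!r}; each graph must have a single identifier"
        )
    account = Account(id=id, name=name, version=1, **metadata)
    project.accounts.append(account)
    return account
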