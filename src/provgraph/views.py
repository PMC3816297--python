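"""Group-filtered subgraph views and deterministic DOT emission.

Every node carries a (possibly empty) set of group labels; a view selects a
set of groups and keeps exactly the nodes belonging to at least one of
them, plus the edges whose two endpoints survive.  Selecting ``"all"``
keeps everything, including nodes in no group.

DOT output is the contract-tested artifact: nodes and edges are emitted in
sorted identifier order so the same account and options always yield
byte-identical text.  Shapes follow the OPM/PROV community convention —
agents as houses (pentagons), activities as rectangles, entities as
ellipses, collections as double-bordered ellipses.  ``wasAssociatedWith``
edges are dotted; automatically maintained ``wasDerivedFrom`` edges are
dashed so machine-kept lineage is visually distinct.  Roles appear as edge
labels and annotations as attached gray rectangles when the corresponding
options are on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import networkx as nx

from .model import Account, NodeKind, RelationKind

__all__ = ["ViewOptions", "filter_by_groups", "to_dot", "to_networkx"]

_SHAPE = {
    NodeKind.AGENT: 'shape=house',
    NodeKind.ACTIVITY: 'shape=box',
    NodeKind.ENTITY: 'shape=ellipse',
    NodeKind.COLLECTION: 'shape=ellipse, peripheries=2',
}


@dataclass
class ViewOptions:
    """Which groups to show and whether to draw roles and annotations."""

    selected_groups: Union[str, frozenset[str], set[str]] = "all"
    show_roles: bool = False
    show_annotations: bool = False

    def __post_init__(self):
        if self.selected_groups != "all":
            self.selected_groups = frozenset(self.selected_groups)
            if not self.selected_groups:
                raise ValueError(
                    'selected_groups must be nonempty or the literal "all"'
                )

    @property
    def select_all(self) -> bool:
        return self.selected_groups == "all"


def filter_by_groups(
    account: Account, options: ViewOptions | None = None
) -> tuple[set[str], set[str]]:
    """Node and edge id sets of the view selected by ``options``.

    A node is kept iff it belongs to at least one selected group; an edge is
    kept iff both endpoints are.  Unknown group names select nothing and are
    reported as a warning.  With ``"all"`` this is the identity view.
    """
    options = options or ViewOptions()
    if options.select_all:
        return set(account.nodes), set(account.edges)
    known_groups = set().union(*(n.groups for n in account.nodes.values()), set())
    unknown = options.selected_groups - known_groups
    if unknown:
        warnings.warn(
            "unknown group(s) selected: " + ", ".join(sorted(unknown)),
            stacklevel=2,
        )
    nodes = {
        nid
        for nid, node in account.nodes.items()
        if node.groups & options.selected_groups
    }
    edges = {
        eid
        for eid, e in account.edges.items()
        if e.source in nodes and e.target in nodes
    }
    return nodes, edges


def to_networkx(account: Account) -> nx.MultiDiGraph:
    """The account as a networkx multidigraph, edges keyed by identifier."""
    g = nx.MultiDiGraph(account_id=account.id, name=account.name)
    for nid, node in account.nodes.items():
        g.add_node(nid, kind=node.kind.value, groups=sorted(node.groups))
    for eid, e in account.edges.items():
        if e.source in account.nodes and e.target in account.nodes:
            g.add_edge(
                e.source,
                e.target,
                key=eid,
                kind=e.kind.value,
                role=e.role,
                auto_derived=e.auto_derived,
            )
    return g


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(account: Account, options: ViewOptions | None = None) -> str:
    """Deterministic DOT text for the selected view of ``account``."""
    options = options or ViewOptions()
    nodes, edges = filter_by_groups(account, options)
    lines = [
        "digraph provenance {",
        f"  label={_quote(account.name)};",
        "  labelloc=t;",
    ]
    for nid in sorted(nodes):
        node = account.nodes[nid]
        lines.append(f"  {_quote(nid)} [{_SHAPE[node.kind]}, label={_quote(nid)}];")
        if options.show_annotations:
            for i, ann in enumerate(node.annotations):
                ann_id = f"ann::{nid}::{i}"
                label = f"{ann.key}: {ann.text}"
                lines.append(
                    f"  {_quote(ann_id)} [shape=box, style=filled, "
                    f"fillcolor=gray90, fontsize=10, label={_quote(label)}];"
                )
                lines.append(
                    f"  {_quote(ann_id)} -> {_quote(nid)} "
                    "[style=dotted, arrowhead=none];"
                )
    for eid in sorted(edges):
        e = account.edges[eid]
        attrs = []
        if e.kind is RelationKind.WAS_ASSOCIATED_WITH:
            attrs.append("style=dotted")
        elif e.kind is RelationKind.WAS_DERIVED_FROM and e.auto_derived:
            attrs.append("style=dashed")
        if options.show_roles and e.role:
            attrs.append(f"label={_quote(e.role)}")
        attr_text = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote(e.source)} -> {_quote(e.target)}{attr_text};")
    lines.append("}")
    return "\n".join(lines) + "\n"
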