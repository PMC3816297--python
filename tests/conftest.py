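"""Shared fixtures and the independent derivation oracle."""

import pytest

from provgraph.errors import StructuralError
from provgraph.fixtures import build_case_study
from provgraph.model import NodeKind, RelationKind


def brute_force_derived(account):
    """Reference derivation closure, independent of the maintenance code.

    Enumerates every (wasGeneratedBy, used) edge pair sharing an activity
    by a double loop over the edge list — no indexing, no incremental
    state — and returns the implied {(generated, used)} pairs.
    """
    pairs = set()
    for g in account.edges.values():
        if g.kind is not RelationKind.WAS_GENERATED_BY:
            continue
        if g.source not in account.nodes or g.target not in account.nodes:
            continue
        for u in account.edges.values():
            if u.kind is not RelationKind.USED:
                continue
            if u.source != g.target or u.target not in account.nodes:
                continue
            if u.target == g.source:
                continue
            pairs.add((g.source, u.target))
    return pairs


def maintained_derived(account):
    """The auto-derived pairs the engine currently maintains."""
    return {
        (e.source, e.target)
        for e in account.edges.values()
        if e.auto_derived
    }


def random_edit_sequence(account, rng, n_ops=12):
    """Random add/remove churn of used/wasGeneratedBy/association edges.

    Structurally rejected additions are simply skipped; auto-derived edges
    are never removed directly (the engine forbids it).
    """
    activities = [n.id for n in account.nodes.values() if n.kind is NodeKind.ACTIVITY]
    data = [
        n.id
        for n in account.nodes.values()
        if n.kind in (NodeKind.ENTITY, NodeKind.COLLECTION)
    ]
    for _ in range(n_ops):
        roll = rng.random()
        try:
            if roll < 0.35:
                account.add_relation(
                    RelationKind.USED, rng.choice(activities), rng.choice(data)
                )
            elif roll < 0.55:
                account.add_relation(
                    RelationKind.WAS_GENERATED_BY,
                    rng.choice(data),
                    rng.choice(activities),
                )
            else:
                removable = [
                    eid for eid, e in account.edges.items() if not e.auto_derived
                ]
                if removable:
                    account.remove_relation(rng.choice(removable))
        except StructuralError:
            pass


@pytest.fixture
def case_project(tmp_path):
    """The case-study project with payload files written under tmp."""
    return build_case_study(payload_dir=tmp_path / "payloads")


@pytest.fixture
def case_account(case_project):
    return case_project.accounts[0]


@pytest.fixture
def payloads(tmp_path, case_project):
    """Payload directory matching ``case_project`` (depends on build order)."""
    return tmp_path / "payloads"
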