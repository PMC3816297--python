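"""Creation-time structural rules and automatic derivation maintenance."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from provgraph.errors import ProvenanceError, StructuralError, TemporalError
from provgraph.fixtures import GeneratorParams, generate_account
from provgraph.model import (
    Account,
    ActivityFields,
    AgentFields,
    CollectionFields,
    DerivationType,
    EntityFields,
    NodeKind,
    RelationKind,
    new_account,
    new_project,
)

from conftest import brute_force_derived, maintained_derived, random_edit_sequence


@pytest.fixture
def tiny():
    """One activity that used X and generated Y, plus an agent."""
    acc = Account(id="WE_tiny", name="tiny")
    acc.add_node(NodeKind.AGENT, AgentFields(name="ada"), id="AG001")
    acc.add_node(NodeKind.COLLECTION, CollectionFields(name="x", size=3), id="X")
    acc.add_node(NodeKind.COLLECTION, CollectionFields(name="y", size=2), id="Y")
    acc.add_node(NodeKind.ACTIVITY, ActivityFields(name="run"), id="A1")
    acc.add_relation(RelationKind.USED, "A1", "X")
    acc.add_relation(RelationKind.WAS_GENERATED_BY, "Y", "A1")
    return acc


class TestProjectAndAccountCreation:
    def test_empty_project_has_no_accounts(self):
        from datetime import datetime

        project = new_project(
            "B. cereus genome",
            start_date=datetime(2012, 1, 1),
            end_date=datetime(2013, 1, 1),
        )
        assert project.accounts == []

    def test_inverted_project_window_rejected(self):
        from datetime import datetime

        with pytest.raises(TemporalError, match="less than or equal"):
            new_project(
                "bad", start_date=datetime(2013, 1, 1), end_date=datetime(2012, 1, 1)
            )

    def test_open_ended_project_accepted(self):
        from datetime import datetime

        project = new_project("ongoing", start_date=datetime(2012, 1, 1))
        assert project.end_date is None

    def test_accounts_keep_order_and_unique_ids(self):
        project = new_project("p")
        a = new_account(project, "first")
        b = new_account(project, "second")
        assert [acc.id for acc in project.accounts] == [a.id, b.id]
        with pytest.raises(StructuralError, match="single identifier"):
            new_account(project, "dup", id=a.id)
        assert new_account(project, "first").id != a.id  # fresh id generated


class TestAddNode:
    def test_collection_needs_size_above_one(self, tiny):
        with pytest.raises(StructuralError, match="size greater than 1"):
            tiny.add_node(NodeKind.COLLECTION, CollectionFields(name="c", size=1))

    def test_duplicate_identifier_rejected(self, tiny):
        with pytest.raises(StructuralError, match="single identifier"):
            tiny.add_node(NodeKind.AGENT, AgentFields(name="again"), id="AG001")

    def test_empty_name_rejected(self, tiny):
        with pytest.raises(StructuralError, match="nonempty"):
            tiny.add_node(NodeKind.ENTITY, EntityFields(name=""))

    def test_field_record_must_match_kind(self, tiny):
        with pytest.raises(StructuralError, match="AgentFields"):
            tiny.add_node(NodeKind.AGENT, EntityFields(name="x"))

    def test_generated_ids_follow_field_convention(self):
        acc = Account(id="WE", name="n")
        assert acc.add_node(NodeKind.AGENT, AgentFields(name="a")) == "AG001"
        assert acc.add_node(NodeKind.ACTIVITY, ActivityFields(name="b")) == "A001"
        assert acc.add_node(NodeKind.ENTITY, EntityFields(name="c")) == "C001"
        assert (
            acc.add_node(NodeKind.COLLECTION, CollectionFields(name="d", size=2))
            == "C002"
        )

    def test_groups_optional_and_multiple(self, tiny):
        nid = tiny.add_node(
            NodeKind.COLLECTION,
            CollectionFields(name="fam13", size=40, location="family13.fasta"),
            groups={"Family 13", "Filter"},
        )
        assert tiny.nodes[nid].groups == {"Family 13", "Filter"}
        agent = tiny.add_node(NodeKind.AGENT, AgentFields(name="solo"))
        assert tiny.nodes[agent].groups == set()


class TestAddRelation:
    @pytest.mark.parametrize(
        "kind,source,target,message",
        [
            (RelationKind.USED, "A1", "GHOST", "nonexistent node"),
            (RelationKind.USED, "AG001", "X", "invalid endpoint kind"),
            (RelationKind.USED, "A1", "X", "identical relationship"),
            (RelationKind.WAS_GENERATED_BY, "Y", "A1", "identical relationship"),
            (RelationKind.WAS_DERIVED_FROM, "X", "X", "origin equals destination"),
        ],
    )
    def test_structural_rejections(self, tiny, kind, source, target, message):
        with pytest.raises(StructuralError, match=message):
            tiny.add_relation(kind, source, target)

    def test_second_generation_rejected(self, tiny):
        tiny.add_node(NodeKind.ACTIVITY, ActivityFields(name="other"), id="A2")
        with pytest.raises(StructuralError, match="already generated"):
            tiny.add_relation(RelationKind.WAS_GENERATED_BY, "Y", "A2")

    def test_association_direction_is_agent_to_activity(self, tiny):
        eid = tiny.add_relation(
            RelationKind.WAS_ASSOCIATED_WITH, "AG001", "A1", role="Execution"
        )
        assert tiny.edges[eid].role == "Execution"
        with pytest.raises(StructuralError, match="invalid endpoint kind"):
            tiny.add_relation(RelationKind.WAS_ASSOCIATED_WITH, "A1", "AG001")

    def test_member_of_links_entity_to_collection(self, tiny):
        tiny.add_node(NodeKind.ENTITY, EntityFields(name="one sequence"), id="E1")
        tiny.add_relation(RelationKind.MEMBER_OF, "E1", "X")
        with pytest.raises(StructuralError, match="invalid endpoint kind"):
            tiny.add_relation(RelationKind.MEMBER_OF, "X", "Y")


class TestDerivationMaintenance:
    def test_pair_produces_derived_edge(self, tiny):
        assert maintained_derived(tiny) == {("Y", "X")}
        (edge,) = [e for e in tiny.edges.values() if e.auto_derived]
        assert edge.derivation_type is DerivationType.OTHER

    def test_empty_account_derives_nothing(self):
        acc = Account(id="WE", name="empty")
        assert acc.derive_was_derived_from() == set()

    def test_maintenance_is_idempotent(self, tiny):
        before = dict(tiny.edges)
        tiny.derive_was_derived_from()
        assert tiny.edges == before

    def test_removing_support_removes_derived_edge(self, tiny):
        used = next(
            eid for eid, e in tiny.edges.items() if e.kind is RelationKind.USED
        )
        tiny.remove_relation(used)
        assert maintained_derived(tiny) == set()

    def test_removing_association_leaves_derivations(self, tiny):
        eid = tiny.add_relation(RelationKind.WAS_ASSOCIATED_WITH, "AG001", "A1")
        tiny.remove_relation(eid)
        assert maintained_derived(tiny) == {("Y", "X")}

    def test_auto_edges_not_directly_removable(self, tiny):
        (auto_id,) = [eid for eid, e in tiny.edges.items() if e.auto_derived]
        with pytest.raises(StructuralError, match="maintained automatically"):
            tiny.remove_relation(auto_id)

    def test_manual_derivation_shadows_auto(self, tiny):
        (auto_id,) = [eid for eid, e in tiny.edges.items() if e.auto_derived]
        tiny.remove_relation(
            next(eid for eid, e in tiny.edges.items() if e.kind is RelationKind.USED)
        )
        manual = tiny.add_relation(
            RelationKind.WAS_DERIVED_FROM,
            "Y",
            "X",
            derivation_type=DerivationType.FILTERING,
        )
        # re-adding the support must not duplicate the manual edge
        tiny.add_relation(RelationKind.USED, "A1", "X")
        derived = [
            e
            for e in tiny.edges.values()
            if e.kind is RelationKind.WAS_DERIVED_FROM
        ]
        assert [e.id for e in derived] == [manual]
        assert not derived[0].auto_derived

    def test_reclassified_type_survives_maintenance(self, tiny):
        (auto,) = [e for e in tiny.edges.values() if e.auto_derived]
        auto.derivation_type = DerivationType.FILTERING
        tiny.add_relation(RelationKind.WAS_ASSOCIATED_WITH, "AG001", "A1")
        assert tiny.edges[auto.id].derivation_type is DerivationType.FILTERING

    def test_unknown_edge_removal_rejected(self, tiny):
        with pytest.raises(ProvenanceError, match="unknown edge"):
            tiny.remove_relation("nope")

    def test_case_study_has_ten_auto_derived_edges(self, case_account):
        auto = [e for e in case_account.edges.values() if e.auto_derived]
        assert len(auto) == 10
        assert maintained_derived(case_account) == brute_force_derived(case_account)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), ops_seed=st.integers(0, 10_000))
    def test_closure_matches_oracle_under_random_edits(self, seed, ops_seed):
        account = generate_account(GeneratorParams(seed=seed))
        rng = random.Random(ops_seed)
        random_edit_sequence(account, rng)
        assert maintained_derived(account) == brute_force_derived(account)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_generation_and_uniqueness_invariants(self, seed):
        account = generate_account(GeneratorParams(seed=seed))
        random_edit_sequence(account, random.Random(seed + 1))
        triples = [e.triple() for e in account.edges.values()]
        assert len(triples) == len(set(triples))
        sources = [
            e.source
            for e in account.edges.values()
            if e.kind is RelationKind.WAS_GENERATED_BY
        ]
        assert len(sources) == len(set(sources))
        ids = [account.id, *account.nodes, *account.edges]
        assert len(ids) == len(set(ids))


class TestAnnotations:
    def test_annotate_node_edge_and_account(self, tiny):
        tiny.annotate("X", "origin", "UNIPROT")
        assert tiny.nodes["X"].annotations[0].text == "UNIPROT"
        edge_id = next(iter(tiny.edges))
        tiny.annotate(edge_id, "note", "checked")
        assert tiny.edges[edge_id].annotations[0].key == "note"
        tiny.annotate(tiny.id, "status", "draft")
        assert tiny.annotations[0].key == "status"

    def test_annotations_repeatable(self, tiny):
        tiny.annotate("X", "k", "1")
        tiny.annotate("X", "k", "2")
        assert [a.text for a in tiny.nodes["X"].annotations] == ["1", "2"]

    def test_unknown_element_rejected(self, tiny):
        with pytest.raises(ProvenanceError, match="unknown element"):
            tiny.annotate("GHOST", "k", "v")
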