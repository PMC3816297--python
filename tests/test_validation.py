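"""Restriction checkers, violation catalogue coverage, and validity inference."""

from datetime import datetime, timedelta

import networkx as nx
import pytest

from provgraph.fixtures import (
    EXPECTED_RULES,
    GeneratorParams,
    INJECTABLE_ACCOUNT_RULES,
    generate_account,
    generate_project,
)
from provgraph.model import (
    Account,
    ActivityFields,
    CollectionFields,
    NodeKind,
    RelationEdge,
    RelationKind,
    new_account,
    new_project,
)
from provgraph.validation import (
    PayloadResolver,
    check_functional,
    check_project_temporal,
    check_structural,
    check_temporal,
    infer_account_validity,
    infer_project_validity,
)

HOUR = timedelta(hours=1)
T0 = datetime(2012, 3, 1, 8, 0)


def minimal_timed_account(user_start_offset=HOUR):
    """The minimal graph exercising the relation-timing rules: one entity
    generated by one activity (08:00-10:00) and used by another starting at
    10:00 + ``user_start_offset``."""
    acc = Account(id="WE_min", name="minimal", start_time=T0 - HOUR, end_time=T0 + 12 * HOUR)
    acc.add_node(
        NodeKind.ACTIVITY,
        ActivityFields(name="gen", start_time=T0, end_time=T0 + 2 * HOUR),
        id="A_gen",
    )
    acc.add_node(
        NodeKind.ACTIVITY,
        ActivityFields(
            name="use",
            start_time=T0 + 2 * HOUR + user_start_offset,
            end_time=T0 + 6 * HOUR,
        ),
        id="A_use",
    )
    acc.add_node(NodeKind.COLLECTION, CollectionFields(name="mid", size=5), id="C_mid")
    acc.add_relation(RelationKind.WAS_GENERATED_BY, "C_mid", "A_gen")
    acc.add_relation(RelationKind.USED, "A_use", "C_mid")
    return acc


class TestViolationCatalogue:
    @pytest.mark.parametrize("code", INJECTABLE_ACCOUNT_RULES)
    @pytest.mark.parametrize("seed", [0, 7])
    def test_injected_rule_is_flagged_exactly(self, code, seed, tmp_path):
        """Each injected breach is reported as exactly its documented rule
        set, and the two untouched axes stay clean (axis orthogonality)."""
        account = generate_account(GeneratorParams(seed=seed, violation=code))
        status = infer_account_validity(account, PayloadResolver(tmp_path))
        assert {v.rule for v in status.violations} == EXPECTED_RULES[code]
        expected_axis = {"S": "structural", "T": "temporal", "F": "functional"}[code[0]]
        assert {v.axis for v in status.violations} == {expected_axis}
        assert getattr(status, f"{expected_axis}_valid") is False

    @pytest.mark.parametrize("code", ["P1", "P2"])
    def test_project_window_rules(self, code, tmp_path):
        project = generate_project(GeneratorParams(seed=5, violation=code))
        assert {v.rule for v in check_project_temporal(project)} == {code}
        status = infer_project_validity(project, PayloadResolver(tmp_path))
        assert not status.temporal_valid
        assert status.structural_valid and status.functional_valid

    @pytest.mark.parametrize("seed", range(8))
    def test_clean_generated_accounts_have_no_violations(self, seed, tmp_path):
        account = generate_account(GeneratorParams(seed=seed))
        assert infer_account_validity(account, PayloadResolver(tmp_path)).all_valid


class TestStructural:
    def test_dangling_edge_reported_not_raised(self):
        acc = Account(id="WE", name="corrupt")
        acc.add_node(NodeKind.ACTIVITY, ActivityFields(name="a"), id="A1")
        acc.edges["R1"] = RelationEdge(
            id="R1", kind=RelationKind.USED, source="A1", target="GONE"
        )
        (violation,) = check_structural(acc)
        assert violation.rule == "S2"
        assert "GONE" in violation.elements

    def test_well_formed_case_study_is_clean(self, case_account):
        assert check_structural(case_account) == []

    def test_checkers_are_deterministic(self, tmp_path):
        account = generate_account(GeneratorParams(seed=4, violation="S4"))
        first = check_structural(account)
        assert check_structural(account) == first


class TestTemporal:
    def test_activity_start_equal_to_end_violates_strict_rule(self):
        acc = Account(id="WE", name="t")
        acc.add_node(
            NodeKind.ACTIVITY,
            ActivityFields(name="a", start_time=T0, end_time=T0),
            id="A1",
        )
        assert [v.rule for v in check_temporal(acc)] == ["T1"]

    def test_minimal_graph_late_generator_fires_both_rules(self):
        """Use starting before generation ended breaks the generation-side
        and use-side readings of the same ordering rule."""
        acc = minimal_timed_account(user_start_offset=-HOUR / 2)
        assert {v.rule for v in check_temporal(acc)} == {"T2", "T3"}

    def test_minimal_graph_ordered_times_pass(self):
        assert check_temporal(minimal_timed_account()) == []

    def test_rules_vacuous_without_generated_and_used_entity(self):
        acc = Account(id="WE", name="v")
        acc.add_node(NodeKind.COLLECTION, CollectionFields(name="raw", size=9), id="C1")
        acc.add_node(
            NodeKind.ACTIVITY,
            ActivityFields(name="a", start_time=T0, end_time=T0 + HOUR),
            id="A1",
        )
        acc.add_relation(RelationKind.USED, "A1", "C1")  # raw input: no generator
        assert check_temporal(acc) == []

    def test_case_study_times_are_consistent(self, case_account):
        assert check_temporal(case_account) == []

    def test_project_window_is_non_strict(self):
        instant = datetime(2012, 6, 1, 12, 0)
        project = new_project("point", start_date=instant, end_date=instant)
        new_account(project, "at-instant", start_time=instant, end_time=instant)
        assert check_project_temporal(project) == []

    def test_account_outside_project_window_flagged(self):
        project = new_project(
            "p", start_date=datetime(2012, 1, 1), end_date=datetime(2013, 1, 1)
        )
        new_account(
            project,
            "late",
            start_time=datetime(2014, 2, 1),
            end_time=datetime(2014, 2, 2),
        )
        assert [v.rule for v in check_project_temporal(project)] == ["P2"]

    def test_empty_project_is_vacuously_valid(self, tmp_path):
        project = new_project("empty")
        assert infer_project_validity(project, PayloadResolver(tmp_path)).all_valid


class TestTemporalSoundness:
    @pytest.mark.parametrize("seed", range(10))
    def test_temporally_valid_accounts_have_acyclic_derivations(self, seed):
        account = generate_account(GeneratorParams(seed=seed, chain_length=4))
        assert check_temporal(account) == []
        g = nx.DiGraph(
            (e.source, e.target)
            for e in account.edges.values()
            if e.kind is RelationKind.WAS_DERIVED_FROM
        )
        assert nx.is_directed_acyclic_graph(g)

    def test_derivation_cycle_between_generated_collections_fails(self):
        """A two-cycle of derivations between generated collections needs
        each original to predate the other — impossible, so some edge
        breaks the derivation-timing rule."""
        acc = minimal_timed_account()
        acc.add_node(
            NodeKind.COLLECTION, CollectionFields(name="late", size=4), id="C_late"
        )
        acc.add_relation(RelationKind.WAS_GENERATED_BY, "C_late", "A_use")
        acc.add_relation(RelationKind.WAS_DERIVED_FROM, "C_mid", "C_late")
        rules = {v.rule for v in check_temporal(acc)}
        assert "T4" in rules


class TestFunctional:
    def test_existing_payloads_pass(self, case_account, payloads):
        assert check_functional(case_account, PayloadResolver(payloads)) == []

    def test_deleted_payload_flips_functional_axis_only(self, case_account, payloads):
        (payloads / "family13.fasta").unlink()
        status = infer_account_validity(case_account, PayloadResolver(payloads))
        assert status.structural_valid and status.temporal_valid
        assert not status.functional_valid
        assert [v.rule for v in status.violations] == ["F1"]
        assert [v.elements for v in status.violations] == [("C001_Family13",)]

    def test_unlocated_nodes_are_skipped(self, tmp_path):
        acc = Account(id="WE", name="f")
        acc.add_node(NodeKind.COLLECTION, CollectionFields(name="c", size=2), id="C1")
        assert check_functional(acc, PayloadResolver(tmp_path)) == []


class TestInference:
    def test_case_study_fully_valid(self, case_account, payloads):
        status = infer_account_validity(case_account, PayloadResolver(payloads))
        assert (
            status.structural_valid,
            status.temporal_valid,
            status.functional_valid,
        ) == (True, True, True)

    def test_duplicated_relation_injected_post_hoc_breaks_structural(
        self, case_account, payloads
    ):
        original = next(
            e for e in case_account.edges.values() if e.kind is RelationKind.USED
        )
        case_account.edges["X999"] = RelationEdge(
            id="X999",
            kind=RelationKind.USED,
            source=original.source,
            target=original.target,
        )
        status = infer_account_validity(case_account, PayloadResolver(payloads))
        assert not status.structural_valid
        assert status.temporal_valid and status.functional_valid

    def test_one_invalid_account_invalidates_project_axis(self, tmp_path):
        project = generate_project(GeneratorParams(seed=2))
        bad = generate_account(GeneratorParams(seed=3, violation="F1"))
        bad.id = "WEGEN_other"
        project.accounts.append(bad)
        status = infer_project_validity(project, PayloadResolver(tmp_path))
        assert not status.functional_valid
        assert status.structural_valid and status.temporal_valid

    def test_project_validity_is_conjunction_of_parts(self, tmp_path):
        """Oracle: recompute each axis explicitly as project-level checks
        AND-ed with every account's verdict."""
        project = generate_project(GeneratorParams(seed=8))
        extra = generate_account(GeneratorParams(seed=9, violation="T1"))
        extra.id = "WEGEN_extra"
        project.accounts.append(extra)
        resolver = PayloadResolver(tmp_path)
        status = infer_project_validity(project, resolver)
        project_rules = check_project_temporal(project)
        per_account = [infer_account_validity(a, resolver) for a in project.accounts]
        assert status.structural_valid == all(s.structural_valid for s in per_account)
        assert status.temporal_valid == (
            not project_rules and all(s.temporal_valid for s in per_account)
        )
        assert status.functional_valid == all(s.functional_valid for s in per_account)
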