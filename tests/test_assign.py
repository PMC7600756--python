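import random

import pytest

from _oracles import closure_oracle
from hybridalleles.assign import (
    AMBIGUOUS_EQUAL_IDENTITY,
    ASSIGNED,
    NO_PREDICTION,
    SUBTHRESHOLD_IDENTITY,
    AlleleAssignment,
    CategorySummary,
    assign_parental_alleles,
    classify_summary,
    copy_numbers,
    hybrid_homolog_groups,
    propagate_via_paralogs,
    shared_function_report,
)
from hybridalleles.homology import BbhPair, HomologGroup


def _ortho(hid, gene, pident, hybrid="H", parent="A"):
    return BbhPair(hid, gene, hybrid, parent, pident, 1e-80)


def _assigned(hid, parent, gene, pident=99.0, via="ortholog"):
    return AlleleAssignment(hid, ASSIGNED, parent, gene, pident, via)


class TestAssignParentalAlleles:
    def test_highest_identity_parent_wins(self):
        out = assign_parental_alleles(
            {"A": [_ortho("h1", "a1", 98.2)], "B": [_ortho("h1", "b1", 89.0, parent="B")]},
            {"A": set(), "B": set()},
            {"h1"},
        )
        (a,) = out
        assert a.category == ASSIGNED
        assert (a.parent_label, a.parental_gene_id, a.pident) == ("A", "a1", 98.2)

    def test_equal_identity_in_both_parents_is_ambiguous(self):
        # conserved sequences (e.g. tRNAs) identical in both parents
        out = assign_parental_alleles(
            {"A": [_ortho("h1", "a1", 100.0)], "B": [_ortho("h1", "b1", 100.0, parent="B")]},
            {"A": set(), "B": set()},
            {"h1"},
        )
        assert out[0].category == AMBIGUOUS_EQUAL_IDENTITY
        assert out[0].parent_label is None

    def test_identity_tie_compared_at_two_decimals(self):
        out = assign_parental_alleles(
            {"A": [_ortho("h1", "a1", 97.123)], "B": [_ortho("h1", "b1", 97.118, parent="B")]},
            {"A": set(), "B": set()},
            {"h1"},
        )
        assert out[0].category == AMBIGUOUS_EQUAL_IDENTITY

    def test_subthreshold_when_best_hit_failed_only_identity_filter(self):
        out = assign_parental_alleles(
            {"A": [], "B": []}, {"A": {"h1"}, "B": set()}, {"h1"}
        )
        assert out[0].category == SUBTHRESHOLD_IDENTITY

    def test_no_prediction_when_nothing_found(self):
        out = assign_parental_alleles({"A": [], "B": []}, {"A": set(), "B": set()}, {"h1"})
        assert out[0].category == NO_PREDICTION

    def test_unknown_hybrid_id_in_ortholog_set_rejected(self):
        with pytest.raises(ValueError, match="absent from hybrid"):
            assign_parental_alleles(
                {"A": [_ortho("ghost", "a1", 99.0)]}, {"A": set()}, {"h1"}
            )

    def test_three_parents_argmax(self):
        out = assign_parental_alleles(
            {
                "A": [_ortho("h1", "a1", 90.0)],
                "B": [_ortho("h1", "b1", 99.0, parent="B")],
                "C": [_ortho("h1", "c1", 95.0, parent="C")],
            },
            {"A": set(), "B": set(), "C": set()},
            {"h1"},
        )
        assert out[0].parent_label == "B"

    def test_monotonic_under_parent_removal(self):
        """Dropping a parent can only move ORFs out of ASSIGNED/AMBIGUOUS."""
        rng = random.Random(31)
        ids = {f"h{i}" for i in range(40)}
        orthologs = {
            p: [
                _ortho(hid, f"{p}_{hid}", rng.choice([85.0, 92.0, 99.0]), parent=p)
                for hid in ids
                if rng.random() < 0.7
            ]
            for p in ("A", "B", "C")
        }
        subs = {p: set() for p in ("A", "B", "C")}
        full = assign_parental_alleles(orthologs, subs, ids)
        reduced = assign_parental_alleles(
            {p: orthologs[p] for p in ("A", "B")},
            {p: subs[p] for p in ("A", "B")},
            ids,
        )
        full_by = {a.hybrid_id: a for a in full}
        for a in reduced:
            if a.category == ASSIGNED:
                f = full_by[a.hybrid_id]
                assert f.category in (ASSIGNED, AMBIGUOUS_EQUAL_IDENTITY)


class TestPropagation:
    def test_unassigned_twin_inherits_parental_gene(self):
        assignments = [
            _assigned("h1", "B", "b9", 99.5),
            AlleleAssignment("h2", NO_PREDICTION),
        ]
        pairs = [BbhPair("h1", "h2", "H", "H", 99.0, 0.0)]
        out = propagate_via_paralogs(assignments, pairs)
        by = {a.hybrid_id: a for a in out}
        assert by["h2"].category == ASSIGNED
        assert by["h2"].parental_gene_id == "b9"
        assert by["h2"].via == "paralog"

    def test_ambiguous_orfs_are_left_alone(self):
        assignments = [
            _assigned("h1", "B", "b9"),
            AlleleAssignment("h2", AMBIGUOUS_EQUAL_IDENTITY),
        ]
        pairs = [BbhPair("h1", "h2", "H", "H", 99.0, 0.0)]
        out = propagate_via_paralogs(assignments, pairs)
        assert {a.hybrid_id: a.category for a in out}["h2"] == AMBIGUOUS_EQUAL_IDENTITY

    def test_isolated_orfs_keep_their_category(self):
        assignments = [AlleleAssignment("h1", NO_PREDICTION)]
        assert propagate_via_paralogs(assignments, [])[0].category == NO_PREDICTION

    def test_nearest_assigned_member_wins_over_farther_one(self):
        # chain h_far - h_mid - h2, with h_mid assigned: h2 takes h_mid's gene
        assignments = [
            _assigned("h_far", "A", "a1"),
            _assigned("h_mid", "B", "b1"),
            AlleleAssignment("h2", NO_PREDICTION),
        ]
        pairs = [
            BbhPair("h_far", "h_mid", "H", "H", 99.0, 0.0),
            BbhPair("h_mid", "h2", "H", "H", 99.0, 0.0),
        ]
        by = {a.hybrid_id: a for a in propagate_via_paralogs(assignments, pairs)}
        assert by["h2"].parental_gene_id == "b1"


class TestClassifySummary:
    def _group(self, members):
        return HomologGroup(frozenset(members), "H")

    def test_counts_and_partition(self):
        assignments = (
            [_assigned(f"hA{i}", "A", f"a{i}") for i in range(4)]
            + [_assigned(f"hB{i}", "B", f"b{i}") for i in range(3)]
            + [
                AlleleAssignment("hx", AMBIGUOUS_EQUAL_IDENTITY),
                AlleleAssignment("hy", SUBTHRESHOLD_IDENTITY),
                AlleleAssignment("hz", NO_PREDICTION),
            ]
        )
        s = classify_summary(assignments, [self._group(["hA0", "hA1"])], ["A", "B"])
        assert s.assigned == {"A": 4, "B": 3}
        assert (s.ambiguous, s.subthreshold, s.no_prediction) == (1, 1, 1)
        assert s.total == 10
        assert s.partition_sum() == s.total
        assert s.distinct_paralogs == 2

    def test_all_unassigned(self):
        assignments = [AlleleAssignment(f"h{i}", NO_PREDICTION) for i in range(5)]
        s = classify_summary(assignments, [], ["A", "B"])
        assert s.assigned == {"A": 0, "B": 0}
        assert s.no_prediction == 5
        assert s.total == 5

    def test_double_classified_orf_rejected(self):
        a = AlleleAssignment("h1", NO_PREDICTION)
        with pytest.raises(ValueError, match="more than once"):
            classify_summary([a, a], [], ["A"])

    def test_summary_invariant_violation_detected(self):
        s = CategorySummary({"A": 1}, 0, 0, 0, total=5)
        with pytest.raises(ValueError, match="sum to 1"):
            s.validate()


class TestCopyNumbers:
    def test_two_orfs_on_one_parental_gene(self):
        recs = copy_numbers(
            [_assigned("h1", "A", "YBR218C"), _assigned("h2", "A", "YBR218C")]
        )
        assert len(recs) == 1
        assert recs[0].copy_number == 2
        assert recs[0].hybrid_ids == ("h1", "h2")

    def test_singletons_have_copy_number_one(self):
        recs = copy_numbers(
            [_assigned("h1", "A", "a1"), _assigned("h2", "B", "b1")]
        )
        assert [r.copy_number for r in recs] == [1, 1]

    def test_no_assignments_yield_no_records(self):
        assert copy_numbers([AlleleAssignment("h1", NO_PREDICTION)]) == []

    def test_copy_number_conservation(self):
        rng = random.Random(7)
        assignments = [
            _assigned(f"h{i}", "A", f"a{rng.randrange(10)}") for i in range(30)
        ]
        recs = copy_numbers(assignments)
        assert sum(r.copy_number for r in recs) == 30


class TestHybridHomologGroups:
    def test_inherited_paralog_family_groups_across_both_parents(self):
        # two paralogous genes in parent A, their two orthologs in parent B,
        # one hybrid copy of each of the four: one group of 4
        assignments = [
            _assigned("h1", "A", "YGL062W"),
            _assigned("h2", "A", "YBR218C"),
            _assigned("h3", "B", "XP_018222170.1"),
            _assigned("h4", "B", "XP_018223247.1"),
        ]
        parent_pairs = {"A": [BbhPair("YGL062W", "YBR218C", "A", "A", 93.0, 0.0)],
                        "B": [BbhPair("XP_018222170.1", "XP_018223247.1", "B", "B", 92.0, 0.0)]}
        cross = [
            BbhPair("YGL062W", "XP_018222170.1", "A", "B", 85.0, 0.0),
            BbhPair("YBR218C", "XP_018223247.1", "A", "B", 84.0, 0.0),
        ]
        groups = hybrid_homolog_groups([], parent_pairs, cross, assignments)
        assert len(groups) == 1
        assert groups[0].member_ids == frozenset({"h1", "h2", "h3", "h4"})

    def test_no_edges_no_groups(self):
        assert hybrid_homolog_groups([], {}, [], []) == []

    def test_layer_selection_restricts_edges(self):
        assignments = [_assigned("h1", "A", "a1"), _assigned("h2", "A", "a2")]
        parent_pairs = {"A": [BbhPair("a1", "a2", "A", "A", 90.0, 0.0)]}
        none = hybrid_homolog_groups([], parent_pairs, [], assignments, layers=("self",))
        assert none == []
        linked = hybrid_homolog_groups(
            [], parent_pairs, [], assignments, layers=("self", "parent-paralog")
        )
        assert len(linked) == 1

    def test_random_layered_graphs_match_closure_oracle(self):
        rng = random.Random(2)
        for _ in range(5):
            edges = [
                (f"h{rng.randrange(30)}", f"h{rng.randrange(30)}")
                for _ in range(40)
            ]
            edges = [(a, b) for a, b in edges if a != b]
            pairs = [BbhPair(a, b, "H", "H", 99.0, 0.0) for a, b in edges]
            groups = hybrid_homolog_groups(pairs, {}, [], [])
            got = sorted(
                (g.member_ids for g in groups), key=lambda g: sorted(g)[0]
            )
            assert got == closure_oracle(edges)


class TestSharedFunctionReport:
    def test_both_retained_pair_counted_in_intersection(self):
        counts = shared_function_report(
            [_assigned("h1", "A", "a1"), _assigned("h2", "B", "b1")],
            [BbhPair("a1", "b1", "A", "B", 85.0, 0.0)],
            ["A", "B"],
        )
        assert counts == {"A_only": 0, "B_only": 0, "both_retained": 1}

    def test_single_parent_retention_counts_as_only(self):
        counts = shared_function_report(
            [_assigned("h1", "A", "a1")],
            [BbhPair("a1", "b1", "A", "B", 85.0, 0.0)],
            ["A", "B"],
        )
        assert counts == {"A_only": 1, "B_only": 0, "both_retained": 0}

    def test_requires_exactly_two_parents(self):
        with pytest.raises(ValueError, match="exactly 2"):
            shared_function_report([], [], ["A", "B", "C"])


def test_assignment_invariant_parent_fields_tied_to_category():
    with pytest.raises(ValueError):
        AlleleAssignment("h1", NO_PREDICTION, parent_label="A", parental_gene_id="a1")
    with pytest.raises(ValueError):
        AlleleAssignment("h1", ASSIGNED)
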