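import random

import pytest

from _oracles import bbh_oracle, best_hit_oracle, closure_oracle
from hybridalleles.align import AlignmentHit, HitTable
from hybridalleles.homology import (
    BbhPair,
    BestHit,
    BestHitMap,
    best_hits,
    bidirectional_best_hits,
    cross_parent_orthologs,
    find_orthologs,
    find_self_paralogs,
    merge_into_groups,
)


def _hit(q, s, e=1e-50, pid=95.0, length=100):
    return AlignmentHit(
        query_id=q, subject_id=s, evalue=e, pident=pid, pgaps=0.0,
        aln_len=length, score=100.0,
    )


def _table(hits, qg="H", sg="P"):
    return HitTable(qg, sg, hits)


def _random_table(rng, n_queries, n_subjects, n_hits, qg="H", sg="P"):
    # discrete value pools force ties so the tie chain is exercised
    hits = []
    seen = set()
    for _ in range(n_hits):
        q = f"q{rng.randrange(n_queries)}"
        s = f"s{rng.randrange(n_subjects)}"
        if (q, s) in seen:
            continue
        seen.add((q, s))
        hits.append(
            _hit(
                q, s,
                e=rng.choice([1e-50, 1e-40, 1e-30, 1e-20]),
                pid=rng.choice([85.0, 90.0, 95.0, 99.0]),
                length=rng.choice([100, 150, 200]),
            )
        )
    return _table(hits, qg, sg)


class TestBestHits:
    def test_minimum_evalue_wins(self):
        table = _table([_hit("q1", "s1", e=1e-50), _hit("q1", "s2", e=1e-10)])
        assert best_hits(table).by_query["q1"].subject_id == "s1"

    def test_evalue_tie_broken_by_max_pident(self):
        table = _table(
            [_hit("q1", "s1", e=1e-50, pid=90.0), _hit("q1", "s2", e=1e-50, pid=95.0)]
        )
        assert best_hits(table).by_query["q1"].subject_id == "s2"

    def test_full_tie_broken_by_smallest_subject_id(self):
        table = _table([_hit("q1", "s2"), _hit("q1", "s1")])
        assert best_hits(table).by_query["q1"].subject_id == "s1"

    def test_empty_table_gives_empty_result(self):
        assert len(best_hits(_table([]))) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = random.Random(seed)
        table = _random_table(rng, 10, 10, 100)
        got = {q: h.subject_id for q, h in best_hits(table).by_query.items()}
        expected = best_hit_oracle(
            [(h.query_id, h.subject_id, h.evalue, h.pident, h.aln_len)
             for h in table.hits]
        )
        assert got == expected


class TestBidirectionalBestHits:
    def _maps(self, fwd, rev):
        f = BestHitMap("H", "P", {
            q: BestHit(q, s, 1e-50, 95.0, 0.0, 100) for q, s in fwd.items()
        })
        r = BestHitMap("P", "H", {
            q: BestHit(q, s, 1e-50, 95.0, 0.0, 100) for q, s in rev.items()
        })
        return f, r

    def test_reciprocal_pair_is_kept(self):
        f, r = self._maps({"q1": "s1"}, {"s1": "q1"})
        pairs = bidirectional_best_hits(f, r)
        assert [(p.id_a, p.id_b) for p in pairs] == [("q1", "s1")]

    def test_non_reciprocal_pair_is_excluded(self):
        f, r = self._maps({"q1": "s1"}, {"s1": "q2"})
        assert bidirectional_best_hits(f, r) == []

    def test_mismatched_genome_labels_rejected(self):
        f, _ = self._maps({"q1": "s1"}, {})
        with pytest.raises(ValueError, match="directions do not match"):
            bidirectional_best_hits(f, f)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_cross_product_reciprocity_oracle(self, seed):
        rng = random.Random(seed)
        fwd = {f"q{i}": f"s{rng.randrange(50)}" for i in range(50)}
        rev = {f"s{i}": f"q{rng.randrange(50)}" for i in range(50)}
        f, r = self._maps(fwd, rev)
        got = {(p.id_a, p.id_b) for p in bidirectional_best_hits(f, r)}
        assert got == bbh_oracle(fwd, rev)


class TestFindOrthologs:
    def test_high_identity_reciprocal_pair_retained(self):
        fwd = _table([_hit("q1", "s1", pid=98.0)])
        rev = _table([_hit("s1", "q1", pid=98.0)], qg="P", sg="H")
        res = find_orthologs(fwd, rev)
        assert len(res.pairs) == 1
        assert res.pairs[0].pident == 98.0

    def test_exactly_eighty_percent_identity_is_discarded(self):
        # the filter is strictly 'more than 80%'
        fwd = _table([_hit("q1", "s1", pid=80.0)])
        rev = _table([_hit("s1", "q1", pid=80.0)], qg="P", sg="H")
        res = find_orthologs(fwd, rev, identity_min=80.0)
        assert res.pairs == []
        assert res.subthreshold_query_ids == {"q1"}

    def test_filter_applies_before_reciprocity_no_promotion(self):
        # q1's best hit s1 fails the filter; its second-best s2 must NOT be
        # promoted to best hit even though s2 would reciprocate
        fwd = _table([
            _hit("q1", "s1", e=1e-60, pid=79.0),
            _hit("q1", "s2", e=1e-50, pid=95.0),
        ])
        rev = _table([_hit("s2", "q1", pid=95.0)], qg="P", sg="H")
        res = find_orthologs(fwd, rev)
        assert res.pairs == []
        assert res.subthreshold_query_ids == {"q1"}

    def test_identity_min_bounds(self):
        fwd = _table([])
        rev = _table([], qg="P", sg="H")
        with pytest.raises(ValueError):
            find_orthologs(fwd, rev, identity_min=0.0)


class TestSelfParalogs:
    def test_two_identical_genes_form_one_pair(self):
        hits = [
            _hit("g1", "g1", e=0.0, pid=100.0),
            _hit("g2", "g2", e=0.0, pid=100.0),
            _hit("g1", "g2", e=1e-80, pid=100.0),
            _hit("g2", "g1", e=1e-80, pid=100.0),
        ]
        pairs = find_self_paralogs(_table(hits, qg="G", sg="G"))
        assert [(p.id_a, p.id_b) for p in pairs] == [("g1", "g2")]

    def test_unique_singletons_yield_no_pairs(self):
        hits = [_hit("g1", "g1", pid=100.0), _hit("g2", "g2", pid=100.0)]
        assert find_self_paralogs(_table(hits, qg="G", sg="G")) == []

    def test_never_returns_a_self_pair(self):
        rng = random.Random(4)
        for seed in range(5):
            table = _random_table(random.Random(seed), 15, 15, 120, qg="G", sg="G")
            for p in find_self_paralogs(table):
                assert p.id_a != p.id_b

    def test_cross_genome_table_rejected(self):
        with pytest.raises(ValueError, match="genome-vs-itself"):
            find_self_paralogs(_table([], qg="A", sg="B"))


class TestMergeIntoGroups:
    def _pairs(self, edges):
        return [
            BbhPair(a, b, "G", "G", 99.0, 1e-50) for a, b in edges
        ]

    def test_pairs_sharing_a_member_merge(self):
        groups = merge_into_groups(self._pairs([("a", "b"), ("b", "c")]))
        assert len(groups) == 1
        assert groups[0].member_ids == frozenset({"a", "b", "c"})

    def test_disjoint_pairs_stay_separate(self):
        groups = merge_into_groups(self._pairs([("a", "b"), ("c", "d")]))
        assert [sorted(g.member_ids) for g in groups] == [["a", "b"], ["c", "d"]]

    def test_groups_partition_the_vertex_set(self):
        rng = random.Random(17)
        edges = [(f"n{rng.randrange(60)}", f"n{rng.randrange(60)}") for _ in range(100)]
        edges = [(a, b) for a, b in edges if a != b]
        groups = merge_into_groups(self._pairs(edges))
        members = [m for g in groups for m in g.member_ids]
        assert len(members) == len(set(members))
        assert set(members) == {x for e in edges for x in e}

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_transitive_closure_oracle(self, seed):
        rng = random.Random(seed)
        edges = [
            (f"n{rng.randrange(40)}", f"n{rng.randrange(40)}") for _ in range(80)
        ]
        edges = [(a, b) for a, b in edges if a != b]
        groups = merge_into_groups(self._pairs(edges))
        got = sorted((g.member_ids for g in groups), key=lambda g: sorted(g)[0])
        assert got == closure_oracle(edges)


class TestCrossParentOrthologs:
    def test_identical_parents_pair_every_gene_at_full_identity(self):
        fwd = _table(
            [_hit(f"a{i}", f"b{i}", pid=100.0) for i in range(5)], qg="A", sg="B"
        )
        rev = _table(
            [_hit(f"b{i}", f"a{i}", pid=100.0) for i in range(5)], qg="B", sg="A"
        )
        res = cross_parent_orthologs(fwd, rev)
        assert len(res.pairs) == 5
        assert all(p.pident == 100.0 for p in res.pairs)

    def test_deleted_gene_is_absent_from_pairs(self):
        fwd = _table([_hit("a0", "b0", pid=99.0)], qg="A", sg="B")
        rev = _table([_hit("b0", "a0", pid=99.0)], qg="B", sg="A")
        res = cross_parent_orthologs(fwd, rev)
        assert [(p.id_a, p.id_b) for p in res.pairs] == [("a0", "b0")]


class TestBbhInvariants:
    def test_bbh_is_subset_of_both_best_hit_sets_and_one_to_one(self):
        rng = random.Random(23)
        fwd_t = _random_table(rng, 12, 12, 90, qg="H", sg="P")
        rev_t = _random_table(rng, 12, 12, 90, qg="P", sg="H")
        fwd, rev = best_hits(fwd_t), best_hits(rev_t)
        pairs = bidirectional_best_hits(fwd, rev)
        a_side = [p.id_a for p in pairs]
        b_side = [p.id_b for p in pairs]
        assert len(a_side) == len(set(a_side))
        assert len(b_side) == len(set(b_side))
        for p in pairs:
            assert fwd.by_query[p.id_a].subject_id == p.id_b
            assert rev.by_query[p.id_b].subject_id == p.id_a
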