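"""Best hits, best bidirectional hits (BBH) and homolog groups.

A *best hit* is the minimum-e-value hit of a query in a subject genome.
Two sequences that are reciprocally each other's best hit form a *best
bidirectional hit*, the operational criterion used here for 1:1 orthologs
between two genomes and for paralog pairs within one genome (after removing
identity self-hits).  Pairs sharing a member are merged transitively into
homolog groups (connected components of the pair graph).

The identity filter for orthologs is strict: a best hit qualifies only if
its percent identity is strictly greater than ``identity_min`` (default
80), and the filter is applied to best hits *before* reciprocity testing,
so a lower-ranked high-identity hit can never be promoted to best hit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .align import AlignmentHit, HitTable

__all__ = [
    "BestHit",
    "BestHitMap",
    "BbhPair",
    "HomologGroup",
    "OrthologResult",
    "best_hits",
    "bidirectional_best_hits",
    "find_orthologs",
    "find_self_paralogs",
    "cross_parent_orthologs",
    "merge_into_groups",
]


@dataclass(frozen=True)
class BestHit:
    query_id: str
    subject_id: str
    evalue: float
    pident: float
    pgaps: Optional[float]
    aln_len: int


@dataclass
class BestHitMap:
    """Per-query best hits for one directed genome pair."""

    query_genome: str
    subject_genome: str
    by_query: Dict[str, BestHit] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.by_query)

    def __iter__(self):
        return iter(self.by_query.values())


@dataclass(frozen=True)
class BbhPair:
    """A best bidirectional hit: ortholog (across genomes) or paralog (within).

    ``pident``/``evalue`` are those of the forward-direction best hit (for
    hybrid-vs-parent jobs the hybrid is the forward query, which is the
    authoritative identity for allele assignment).
    """

    id_a: str
    id_b: str
    genome_a: str
    genome_b: str
    pident: float
    evalue: float


@dataclass
class HomologGroup:
    member_ids: frozenset
    genome: str
    evidence: Tuple[BbhPair, ...] = ()

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class OrthologResult:
    """BBH ortholog pairs plus the queries that failed only the identity filter."""

    pairs: List[BbhPair]
    subthreshold_query_ids: Set[str]


def _hit_rank(h: AlignmentHit) -> tuple:
    # minimize evalue; ties: max pident, then max aln_len, then smallest
    # subject id — a fixed, documented chain so outputs are reproducible
    return (h.evalue, -h.pident, -h.aln_len, h.subject_id)


def best_hits(table: HitTable) -> BestHitMap:
    """Reduce a hit table to one best hit per query."""
    best: Dict[str, AlignmentHit] = {}
    for h in table.hits:
        prev = best.get(h.query_id)
        if prev is None or _hit_rank(h) < _hit_rank(prev):
            best[h.query_id] = h
    return BestHitMap(
        table.query_genome,
        table.subject_genome,
        {
            q: BestHit(h.query_id, h.subject_id, h.evalue, h.pident, h.pgaps, h.aln_len)
            for q, h in best.items()
        },
    )


def bidirectional_best_hits(
    forward: BestHitMap, reverse: BestHitMap
) -> List[BbhPair]:
    """Keep (x, y) iff x's best hit is y and y's best hit is x."""
    if (
        forward.query_genome != reverse.subject_genome
        or forward.subject_genome != reverse.query_genome
    ):
        raise ValueError(
            f"directions do not match: {forward.query_genome}->"
            f"{forward.subject_genome} vs {reverse.query_genome}->"
            f"{reverse.subject_genome}"
        )
    pairs: List[BbhPair] = []
    for qid in sorted(forward.by_query):
        fh = forward.by_query[qid]
        rh = reverse.by_query.get(fh.subject_id)
        if rh is not None and rh.subject_id == qid:
            pairs.append(
                BbhPair(
                    id_a=qid,
                    id_b=fh.subject_id,
                    genome_a=forward.query_genome,
                    genome_b=forward.subject_genome,
                    pident=fh.pident,
                    evalue=fh.evalue,
                )
            )
    return pairs


def _filter_identity(
    bmap: BestHitMap, identity_min: float, evalue_keep: float
) -> Tuple[BestHitMap, Set[str]]:
    kept: Dict[str, BestHit] = {}
    failed: Set[str] = set()
    for qid, h in bmap.by_query.items():
        if h.evalue > evalue_keep:
            continue
        if h.pident > identity_min:
            kept[qid] = h
        else:
            failed.add(qid)
    return BestHitMap(bmap.query_genome, bmap.subject_genome, kept), failed


def find_orthologs(
    hybrid_vs_parent: HitTable,
    parent_vs_hybrid: HitTable,
    identity_min: float = 80.0,
    evalue_keep: float = 0.05,
) -> OrthologResult:
    """1:1 orthologs between hybrid and one parent by filtered BBH.

    Best hits at pident <= ``identity_min`` are discarded *before*
    reciprocity testing ("more than 80% identity" is strict: a pair at
    exactly 80.0 is rejected).  The returned ``subthreshold_query_ids``
    are the forward queries (hybrid ORFs) whose best hit existed but
    failed only the identity filter — needed downstream to distinguish
    "sub-threshold identity" from "no prediction at all".
    """
    if not 0.0 < identity_min < 100.0:
        raise ValueError("identity_min must be in (0, 100)")
    fwd = best_hits(hybrid_vs_parent)
    rev = best_hits(parent_vs_hybrid)
    fwd_kept, fwd_failed = _filter_identity(fwd, identity_min, evalue_keep)
    rev_kept, _ = _filter_identity(rev, identity_min, evalue_keep)
    pairs = bidirectional_best_hits(fwd_kept, rev_kept)
    return OrthologResult(pairs=pairs, subthreshold_query_ids=fwd_failed)


def cross_parent_orthologs(
    parent_a_vs_b: HitTable,
    parent_b_vs_a: HitTable,
    identity_min: float = 80.0,
    evalue_keep: float = 0.05,
) -> OrthologResult:
    """1:1 orthologs between two parental genomes (same criterion)."""
    return find_orthologs(parent_a_vs_b, parent_b_vs_a, identity_min, evalue_keep)


def find_self_paralogs(self_hits: HitTable) -> List[BbhPair]:
    """Within-genome paralog pairs: BBH after removing identity self-hits."""
    if self_hits.query_genome != self_hits.subject_genome:
        raise ValueError(
            "self-paralog detection requires a genome-vs-itself hit table"
        )
    pruned = HitTable(
        self_hits.query_genome,
        self_hits.subject_genome,
        [h for h in self_hits.hits if h.query_id != h.subject_id],
    )
    bmap = best_hits(pruned)
    pairs = bidirectional_best_hits(bmap, bmap)
    canonical: Dict[Tuple[str, str], BbhPair] = {}
    for p in pairs:
        a, b = sorted((p.id_a, p.id_b))
        if (a, b) not in canonical:
            canonical[(a, b)] = BbhPair(
                id_a=a,
                id_b=b,
                genome_a=p.genome_a,
                genome_b=p.genome_b,
                pident=p.pident,
                evalue=p.evalue,
            )
    return [canonical[k] for k in sorted(canonical)]


def merge_into_groups(
    pairs: Iterable[BbhPair], genome: Optional[str] = None
) -> List[HomologGroup]:
    """Merge pairs sharing a member into groups (connected components).

    Two pairs of homologs that share one gene belong to one group; applied
    transitively this makes groups the connected components of the pair
    graph.  Output is ordered by smallest member id.
    """
    pairs = list(pairs)
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.id_a, p.id_b)
    edge_index: Dict[frozenset, List[BbhPair]] = defaultdict(list)
    for p in pairs:
        edge_index[frozenset((p.id_a, p.id_b))].append(p)
    groups: List[HomologGroup] = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        evidence = tuple(
            p
            for key, plist in edge_index.items()
            if key <= members
            for p in plist
        )
        label = genome if genome is not None else evidence[0].genome_a
        groups.append(HomologGroup(member_ids=members, genome=label, evidence=evidence))
    groups.sort(key=lambda g: min(g.member_ids))
    return groups
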