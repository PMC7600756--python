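"""Parental allele assignment, category summary, copy numbers, groups.

Every hybrid ORF lands in exactly one of four outcome categories:

* ``ASSIGNED`` — it has a 1:1 ortholog in at least one parent and a unique
  parent wins on percent identity (strictly highest);
* ``AMBIGUOUS_EQUAL_IDENTITY`` — two or more parents tie for the maximum
  identity (typically near-identical genes such as tRNAs), so the parental
  origin cannot be decided;
* ``SUBTHRESHOLD_IDENTITY`` — no ortholog survived, but at least one
  parent's best hit failed *only* the >identity_min filter;
* ``NO_PREDICTION`` — no saved hit in any parent, or best hits that were
  never reciprocal.

Aneuploid hybrids carry extra copies of parental genes; a strict 1:1 BBH
criterion can anchor only one hybrid copy per parental gene.  The optional
:func:`propagate_via_paralogs` step extends assignments to the remaining
copies through the hybrid's own paralog pairs (a hybrid ORF that is a
near-identical self-BBH twin of an assigned ORF inherits its parental
gene), which is what makes per-parental-gene copy numbers > 1 observable.
"""

from __future__ import annotations

from collections import Counter, defaultdict, deque
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .homology import BbhPair, HomologGroup, merge_into_groups

__all__ = [
    "ASSIGNED",
    "AMBIGUOUS_EQUAL_IDENTITY",
    "SUBTHRESHOLD_IDENTITY",
    "NO_PREDICTION",
    "CATEGORIES",
    "AlleleAssignment",
    "CategorySummary",
    "CopyNumberRecord",
    "assign_parental_alleles",
    "propagate_via_paralogs",
    "classify_summary",
    "copy_numbers",
    "hybrid_homolog_groups",
    "shared_function_report",
]

ASSIGNED = "ASSIGNED"
AMBIGUOUS_EQUAL_IDENTITY = "AMBIGUOUS_EQUAL_IDENTITY"
SUBTHRESHOLD_IDENTITY = "SUBTHRESHOLD_IDENTITY"
NO_PREDICTION = "NO_PREDICTION"
CATEGORIES = (
    ASSIGNED,
    AMBIGUOUS_EQUAL_IDENTITY,
    SUBTHRESHOLD_IDENTITY,
    NO_PREDICTION,
)


@dataclass(frozen=True)
class AlleleAssignment:
    hybrid_id: str
    category: str
    parent_label: Optional[str] = None
    parental_gene_id: Optional[str] = None
    pident: Optional[float] = None
    via: str = "ortholog"  # "ortholog" or "paralog" (propagated)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        has_parent = self.parent_label is not None and self.parental_gene_id is not None
        if (self.category == ASSIGNED) != has_parent:
            raise ValueError(
                "parent fields must be set exactly when category is ASSIGNED"
            )


@dataclass
class CategorySummary:
    """Per-run category counts (the per-strain output contract).

    The four categories partition the hybrid ORF set, so the per-parent
    assigned counts plus the ambiguous, sub-threshold and no-prediction
    counts must sum to the total number of ORFs.
    """

    assigned: Dict[str, int]
    ambiguous: int
    subthreshold: int
    no_prediction: int
    total: int
    distinct_paralogs: int = 0
    n_paralog_groups: int = 0
    n_paralog_pairs: int = 0

    def validate(self) -> None:
        parts = sum(self.assigned.values()) + self.ambiguous + self.subthreshold + self.no_prediction
        if parts != self.total:
            raise ValueError(
                f"category counts sum to {parts}, expected total {self.total}"
            )

    def partition_sum(self) -> int:
        return (
            sum(self.assigned.values())
            + self.ambiguous
            + self.subthreshold
            + self.no_prediction
        )


@dataclass(frozen=True)
class CopyNumberRecord:
    parental_gene_id: str
    parent_label: str
    copy_number: int
    hybrid_ids: Tuple[str, ...]


def assign_parental_alleles(
    ortholog_sets: Mapping[str, Sequence[BbhPair]],
    subthreshold_ids: Mapping[str, Set[str]],
    all_hybrid_ids: Iterable[str],
    identity_min: float = 80.0,
    tie_decimals: int = 2,
) -> List[AlleleAssignment]:
    """Decide each hybrid ORF's parental allele across 2-4 parents.

    ``ortholog_sets`` maps each parent label to its hybrid-parent BBH pairs
    (hybrid id on side a).  When a hybrid ORF has a 1:1 ortholog in more
    than one parent, the parent sharing the strictly highest percent
    identity wins; identities equal after rounding to ``tie_decimals``
    decimals (the precision backends report) are ties and the ORF is
    declared ambiguous.
    """
    all_ids = set(all_hybrid_ids)
    candidates: Dict[str, List[Tuple[str, str, float]]] = defaultdict(list)
    for parent, pairs in ortholog_sets.items():
        for p in pairs:
            if p.id_a not in all_ids:
                raise ValueError(
                    f"ortholog hybrid id {p.id_a!r} absent from hybrid ORF set"
                )
            if p.pident <= identity_min:
                raise ValueError(
                    f"ortholog pair ({p.id_a},{p.id_b}) at pident {p.pident} "
                    f"violates identity_min {identity_min}"
                )
            candidates[p.id_a].append((parent, p.id_b, p.pident))
    sub_union: Dict[str, Set[str]] = defaultdict(set)
    for parent, ids in subthreshold_ids.items():
        for hid in ids:
            sub_union[hid].add(parent)

    out: List[AlleleAssignment] = []
    for hid in sorted(all_ids):
        cands = candidates.get(hid)
        if cands:
            best_rounded = max(round(c[2], tie_decimals) for c in cands)
            top = [c for c in cands if round(c[2], tie_decimals) == best_rounded]
            if len(top) == 1:
                parent, gene, pident = top[0]
                out.append(
                    AlleleAssignment(
                        hybrid_id=hid,
                        category=ASSIGNED,
                        parent_label=parent,
                        parental_gene_id=gene,
                        pident=pident,
                    )
                )
            else:
                out.append(
                    AlleleAssignment(hybrid_id=hid, category=AMBIGUOUS_EQUAL_IDENTITY)
                )
        elif hid in sub_union:
            out.append(
                AlleleAssignment(hybrid_id=hid, category=SUBTHRESHOLD_IDENTITY)
            )
        else:
            out.append(AlleleAssignment(hybrid_id=hid, category=NO_PREDICTION))
    return out


def propagate_via_paralogs(
    assignments: Sequence[AlleleAssignment],
    hybrid_self_pairs: Sequence[BbhPair],
) -> List[AlleleAssignment]:
    """Extend assignments to unassigned hybrid ORFs through paralog pairs.

    An unassigned (no-prediction or sub-threshold) ORF connected to the
    paralog graph inherits the parental gene of the *nearest* assigned ORF
    in its connected component (breadth-first distance over self-BBH edges;
    ties broken by id for determinism).  Ambiguous ORFs are left alone —
    their origin is undecidable, not missing.  Propagated assignments carry
    ``via='paralog'``.
    """
    graph = nx.Graph()
    for p in hybrid_self_pairs:
        graph.add_edge(p.id_a, p.id_b)
    by_id = {a.hybrid_id: a for a in assignments}
    assigned_ids = {a.hybrid_id for a in assignments if a.category == ASSIGNED}

    out: List[AlleleAssignment] = []
    for a in assignments:
        if a.category in (ASSIGNED, AMBIGUOUS_EQUAL_IDENTITY):
            out.append(a)
            continue
        if a.hybrid_id not in graph:
            out.append(a)
            continue
        # nearest assigned neighbour by BFS, tie-broken by id
        source: Optional[AlleleAssignment] = None
        seen = {a.hybrid_id}
        frontier = [a.hybrid_id]
        while frontier and source is None:
            nxt: List[str] = []
            hits: List[str] = []
            for node in frontier:
                for nb in graph.neighbors(node):
                    if nb in seen:
                        continue
                    seen.add(nb)
                    if nb in assigned_ids:
                        hits.append(nb)
                    nxt.append(nb)
            if hits:
                source = by_id[min(hits)]
            frontier = sorted(nxt)
        if source is None:
            out.append(a)
        else:
            out.append(
                AlleleAssignment(
                    hybrid_id=a.hybrid_id,
                    category=ASSIGNED,
                    parent_label=source.parent_label,
                    parental_gene_id=source.parental_gene_id,
                    pident=source.pident,
                    via="paralog",
                )
            )
    return out


def classify_summary(
    assignments: Sequence[AlleleAssignment],
    paralog_groups_in_hybrid: Sequence[HomologGroup],
    parent_labels: Optional[Sequence[str]] = None,
) -> CategorySummary:
    """Tally assignments into the per-strain category summary.

    ``distinct_paralogs`` counts hybrid ORFs that belong to at least one
    hybrid homolog group; the number of groups and of underlying pairs are
    reported alongside as alternative paralog tallies.
    """
    ids = [a.hybrid_id for a in assignments]
    dup = [hid for hid, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"hybrid ORFs classified more than once: {sorted(dup)[:5]}")
    assigned: Dict[str, int] = {p: 0 for p in (parent_labels or [])}
    ambiguous = subthreshold = none = 0
    for a in assignments:
        if a.category == ASSIGNED:
            assigned[a.parent_label] = assigned.get(a.parent_label, 0) + 1
        elif a.category == AMBIGUOUS_EQUAL_IDENTITY:
            ambiguous += 1
        elif a.category == SUBTHRESHOLD_IDENTITY:
            subthreshold += 1
        else:
            none += 1
    members: Set[str] = set()
    n_pairs = 0
    for g in paralog_groups_in_hybrid:
        members |= set(g.member_ids)
        n_pairs += len(g.evidence)
    summary = CategorySummary(
        assigned=assigned,
        ambiguous=ambiguous,
        subthreshold=subthreshold,
        no_prediction=none,
        total=len(assignments),
        distinct_paralogs=len(members),
        n_paralog_groups=len(paralog_groups_in_hybrid),
        n_paralog_pairs=n_pairs,
    )
    summary.validate()
    return summary


def copy_numbers(
    assignments: Sequence[AlleleAssignment],
) -> List[CopyNumberRecord]:
    """Count hybrid ORFs assigned to each parental gene.

    One record per parental gene that received at least one assignment;
    copy numbers over all records sum to the number of ASSIGNED ORFs.
    """
    by_gene: Dict[Tuple[str, str], List[str]] = defaultdict(list)
    for a in assignments:
        if a.category == ASSIGNED:
            by_gene[(a.parent_label, a.parental_gene_id)].append(a.hybrid_id)
    return [
        CopyNumberRecord(
            parental_gene_id=gene,
            parent_label=parent,
            copy_number=len(hids),
            hybrid_ids=tuple(sorted(hids)),
        )
        for (parent, gene), hids in sorted(by_gene.items())
    ]


def hybrid_homolog_groups(
    hybrid_self_pairs: Sequence[BbhPair],
    parent_self_pairs: Mapping[str, Sequence[BbhPair]],
    cross_parent_pairs: Sequence[BbhPair],
    assignments: Sequence[AlleleAssignment],
    layers: Sequence[str] = ("self", "parent-paralog", "cross-ortholog"),
    hybrid_label: str = "hybrid",
) -> List[HomologGroup]:
    """Group hybrid ORFs that are homologs of one another.

    Three configurable evidence layers contribute edges between hybrid ORFs:

    * ``self`` — the hybrid's own self-BBH paralog pairs (duplications that
      happened in, or were inherited into, the hybrid);
    * ``parent-paralog`` — two hybrid ORFs whose assigned parental genes
      are a paralog pair within one parent;
    * ``cross-ortholog`` — two hybrid ORFs whose assigned parental genes
      are a 1:1 ortholog pair between two parents (the two parental alleles
      of one ancestral gene).

    Returns the connected components (size >= 2) over hybrid ORFs.
    """
    graph = nx.Graph()
    evidence: List[BbhPair] = []
    if "self" in layers:
        for p in hybrid_self_pairs:
            graph.add_edge(p.id_a, p.id_b)
            evidence.append(p)
    assigned_to: Dict[Tuple[str, str], List[str]] = defaultdict(list)
    for a in assignments:
        if a.category == ASSIGNED:
            assigned_to[(a.parent_label, a.parental_gene_id)].append(a.hybrid_id)
    if "parent-paralog" in layers:
        for parent, pairs in parent_self_pairs.items():
            for p in pairs:
                left = assigned_to.get((parent, p.id_a), [])
                right = assigned_to.get((parent, p.id_b), [])
                for x in left:
                    for y in right:
                        graph.add_edge(x, y)
    if "cross-ortholog" in layers:
        for p in cross_parent_pairs:
            left = assigned_to.get((p.genome_a, p.id_a), [])
            right = assigned_to.get((p.genome_b, p.id_b), [])
            for x in left:
                for y in right:
                    graph.add_edge(x, y)
    groups: List[HomologGroup] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = frozenset(comp)
        groups.append(
            HomologGroup(
                member_ids=members,
                genome=hybrid_label,
                evidence=tuple(
                    p
                    for p in evidence
                    if p.id_a in members and p.id_b in members
                ),
            )
        )
    groups.sort(key=lambda g: min(g.member_ids))
    return groups


def shared_function_report(
    assignments: Sequence[AlleleAssignment],
    cross_parent_pairs: Sequence[BbhPair],
    parent_labels: Sequence[str],
) -> Dict[str, int]:
    """Count parental genes retained from one or both parents (two parents).

    A cross-parent ortholog pair is *both-retained* when each of its two
    parental genes received at least one hybrid assignment — the hybrid
    kept both parental alleles of the same ancestral function.  Remaining
    assigned genes are counted per parent (allele retained from only that
    parent).
    """
    if len(parent_labels) != 2:
        raise ValueError("shared-function report requires exactly 2 parents")
    pa, pb = parent_labels
    assigned_genes: Dict[str, Set[str]] = {pa: set(), pb: set()}
    for a in assignments:
        if a.category == ASSIGNED and a.parent_label in assigned_genes:
            assigned_genes[a.parent_label].add(a.parental_gene_id)
    both = 0
    in_pairs: Dict[str, Set[str]] = {pa: set(), pb: set()}
    for p in cross_parent_pairs:
        gene_by_label = {p.genome_a: p.id_a, p.genome_b: p.id_b}
        if set(gene_by_label) != {pa, pb}:
            raise ValueError(
                f"cross-parent pair genomes {sorted(gene_by_label)} do not "
                f"match parents {sorted((pa, pb))}"
            )
        ga, gb = gene_by_label[pa], gene_by_label[pb]
        if ga in assigned_genes[pa] and gb in assigned_genes[pb]:
            both += 1
            in_pairs[pa].add(ga)
            in_pairs[pb].add(gb)
    return {
        f"{pa}_only": len(assigned_genes[pa] - in_pairs[pa]),
        f"{pb}_only": len(assigned_genes[pb] - in_pairs[pb]),
        "both_retained": both,
    }
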