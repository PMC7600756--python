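"""Synthetic parent/hybrid ORF sets with full ground truth.

No real hybrid genome has both parental alleles mapped, so pipeline
accuracy is measured on simulated data instead.  The generator emulates
the standard allopolyploid history: an ancestor gene set; two (or more)
parents that each diverged from it by independent per-site substitution
and accumulated small-scale duplications; and an aneuploid hybrid that
samples a configurable number of allele copies per parent (the ploidy),
loses some copies, diverges slightly after hybridization and may duplicate
genes again.  Every surviving hybrid ORF's true source parent and source
gene are recorded, which turns the whole pipeline into a measurable
parameter-recovery experiment.

Substitutions are i.i.d. per site and uniform over the three alternative
bases (Jukes–Cantor-like); there is no indel model, so true percent
identities are analytically predictable.  Duplicates are full-length gene
copies, the small-scale-duplication case the assignment stage has to cope
with.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .seqio import OrfRecord, OrfSet

__all__ = [
    "SimConfig",
    "ParentTruth",
    "TruthRecord",
    "SimTruth",
    "SimDataset",
    "RecoveryMetrics",
    "simulate_ancestor",
    "diverge_parent",
    "make_hybrid",
    "simulate_dataset",
    "score_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

ORIGIN_ORTHOLOG = "inherited-ortholog"
ORIGIN_PARALOG = "inherited-paralog"
ORIGIN_POSTHYB_DUP = "posthyb-duplicate"


@dataclass
class SimConfig:
    """Study conditions for the recovery experiment.

    Defaults describe a yeast-like scenario: 500 ancestor genes of mean
    length 1000 nt (sd 300, minimum 150) at 40% GC; parents diverged by 10%
    per-site substitution each (so ~81% identity between parents and ~90%
    to the ancestor); a triploid-like hybrid carrying one copy of parent A
    and two of parent B, with 10% per-copy loss and 0.5% post-hybridization
    divergence.  Duplication rates default to zero; the duplication
    machinery is exercised by enabling them explicitly.
    """

    n_genes: int = 500
    len_mean: float = 1000.0
    len_sd: float = 300.0
    len_min: int = 150
    gc: float = 0.40
    div_parent: float = 0.10
    dup_rate_parent: float = 0.0
    parent_labels: Tuple[str, ...] = ("parentA", "parentB")
    ploidy: Mapping[str, int] = field(
        default_factory=lambda: {"parentA": 1, "parentB": 2}
    )
    loss_rate: float = 0.1
    div_posthyb: float = 0.005
    dup_rate_hybrid: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("gc", "div_parent", "dup_rate_parent", "loss_rate",
                     "div_posthyb", "dup_rate_hybrid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.ploidy) != set(self.parent_labels):
            raise ValueError("ploidy must be keyed by parent_labels")
        if any(c < 0 for c in self.ploidy.values()):
            raise ValueError("ploidy copy counts must be >= 0")
        if self.div_posthyb >= self.div_parent > 0:
            warnings.warn(
                "div_posthyb >= div_parent: hybrid copies may be as far from "
                "their source parent as from the other parent, making "
                "parental origin unidentifiable",
                stacklevel=2,
            )


@dataclass
class ParentTruth:
    """Provenance of one simulated parent's genes."""

    label: str
    ancestor_of: Dict[str, str]  # parent gene id -> ancestor gene id
    duplications: List[Tuple[str, str]]  # (template gene id, duplicate id)


@dataclass(frozen=True)
class TruthRecord:
    hybrid_id: str
    parent_label: str
    source_gene: str
    origin: str
    decidable: bool


@dataclass
class SimTruth:
    """Ground truth for one simulated hybrid."""

    records: Dict[str, TruthRecord]
    lost: List[Tuple[str, str, int]]  # (parent label, gene id, copy index)
    parent_truths: Dict[str, ParentTruth] = field(default_factory=dict)
    cross_parent_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def true_copy_numbers(self) -> Dict[Tuple[str, str], int]:
        """Surviving hybrid copies per (parent label, parental gene)."""
        counts: Counter = Counter()
        for rec in self.records.values():
            counts[(rec.parent_label, rec.source_gene)] += 1
        return dict(counts)

    def n_decidable(self) -> int:
        return sum(1 for r in self.records.values() if r.decidable)


@dataclass
class SimDataset:
    ancestor: OrfSet
    parents: Dict[str, OrfSet]
    hybrid: OrfSet
    truth: SimTruth
    config: SimConfig


@dataclass
class RecoveryMetrics:
    precision: Optional[float]
    recall: float
    per_parent_precision: Dict[str, Optional[float]]
    per_parent_recall: Dict[str, float]
    n_assigned: int
    n_decidable: int
    copy_number_exact_fraction: float
    copy_number_mean_abs_error: float
    group_purity: Optional[float] = None


def _seq_to_array(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _array_to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution, uniform over the three alternative bases."""
    if rate <= 0.0:
        return seq
    arr = _seq_to_array(seq)
    mask = rng.random(arr.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        arr = arr.copy()
        offsets = rng.integers(1, 4, size=n_mut).astype(np.uint8)
        arr[mask] = (arr[mask] + offsets) % 4
    return _array_to_seq(arr)


def simulate_ancestor(config: SimConfig) -> OrfSet:
    """Draw the ancestor gene set: i.i.d. bases at the configured GC."""
    rng = np.random.default_rng([0, config.seed])
    lengths = np.maximum(
        np.rint(rng.normal(config.len_mean, config.len_sd, config.n_genes)),
        config.len_min,
    ).astype(int)
    p = np.array(
        [
            (1 - config.gc) / 2,  # A
            config.gc / 2,        # C
            config.gc / 2,        # G
            (1 - config.gc) / 2,  # T
        ]
    )
    records = []
    for i, length in enumerate(lengths):
        arr = rng.choice(4, size=length, p=p).astype(np.uint8)
        records.append(OrfRecord(id=f"anc{i:05d}", seq=_array_to_seq(arr)))
    return OrfSet("ancestor", records)


def diverge_parent(
    ancestor: OrfSet,
    label: str,
    div_parent: float,
    dup_rate_parent: float,
    seed: int | Sequence[int],
) -> Tuple[OrfSet, ParentTruth]:
    """Evolve one parent from the ancestor: substitutions plus duplications.

    Each gene is independently substituted per site at ``div_parent``;
    duplicated genes (probability ``dup_rate_parent`` per gene) are
    appended with a ``_d1`` suffix and receive an extra substitution pass
    at the same rate, so paralog pairs are mutually more diverged than
    either copy is from the ancestor.
    """
    rng = np.random.default_rng(seed if isinstance(seed, (list, tuple)) else [1, seed])
    records: List[OrfRecord] = []
    ancestor_of: Dict[str, str] = {}
    duplications: List[Tuple[str, str]] = []
    for i, anc in enumerate(ancestor):
        gene_id = f"{label}_{i:05d}"
        seq = _mutate(anc.seq, div_parent, rng)
        records.append(OrfRecord(id=gene_id, seq=seq))
        ancestor_of[gene_id] = anc.id
        if rng.random() < dup_rate_parent:
            dup_id = f"{gene_id}_d1"
            dup_seq = _mutate(seq, div_parent, rng)
            records.append(OrfRecord(id=dup_id, seq=dup_seq))
            ancestor_of[dup_id] = anc.id
            duplications.append((gene_id, dup_id))
    return OrfSet(label, records), ParentTruth(label, ancestor_of, duplications)


def make_hybrid(
    parents: Sequence[OrfSet],
    ploidy: Mapping[str, int],
    loss_rate: float,
    div_posthyb: float,
    dup_rate_hybrid: float,
    seed: int | Sequence[int],
    parent_truths: Optional[Mapping[str, ParentTruth]] = None,
) -> Tuple[OrfSet, SimTruth]:
    """Assemble the aneuploid hybrid and its ground-truth origin table.

    For each parent gene and each of that parent's ploidy copies, the copy
    is included unless lost (probability ``loss_rate``), then substituted
    at ``div_posthyb``; surviving copies may be duplicated again in the
    hybrid (probability ``dup_rate_hybrid``).  Hybrid ids are fresh.

    A truth record is marked *decidable* when the source gene's sequence
    is not carried identically by any other parent — otherwise even a
    perfect method can only declare the origin ambiguous.
    """
    rng = np.random.default_rng(seed if isinstance(seed, (list, tuple)) else [2, seed])
    other_seqs: Dict[str, Set[str]] = {
        p.genome_label: {rec.seq for rec in p} for p in parents
    }
    records: List[OrfRecord] = []
    truth_records: Dict[str, TruthRecord] = {}
    lost: List[Tuple[str, str, int]] = []
    counter = 0

    def fresh_id() -> str:
        nonlocal counter
        counter += 1
        return f"hyb{counter:05d}"

    for parent in parents:
        label = parent.genome_label
        n_copies = ploidy.get(label, 1)
        dup_templates = set()
        if parent_truths and label in parent_truths:
            dup_templates = {d for pair in parent_truths[label].duplications for d in pair}
        foreign = set().union(
            *(s for lab, s in other_seqs.items() if lab != label)
        ) if len(parents) > 1 else set()
        for rec in parent:
            decidable = rec.seq not in foreign
            origin = ORIGIN_PARALOG if rec.id in dup_templates else ORIGIN_ORTHOLOG
            for copy_idx in range(n_copies):
                if rng.random() < loss_rate:
                    lost.append((label, rec.id, copy_idx))
                    continue
                hid = fresh_id()
                seq = _mutate(rec.seq, div_posthyb, rng)
                records.append(OrfRecord(id=hid, seq=seq))
                truth_records[hid] = TruthRecord(
                    hybrid_id=hid,
                    parent_label=label,
                    source_gene=rec.id,
                    origin=origin,
                    decidable=decidable,
                )
                if rng.random() < dup_rate_hybrid:
                    dup_hid = fresh_id()
                    dup_seq = _mutate(seq, div_posthyb, rng)
                    records.append(OrfRecord(id=dup_hid, seq=dup_seq))
                    truth_records[dup_hid] = TruthRecord(
                        hybrid_id=dup_hid,
                        parent_label=label,
                        source_gene=rec.id,
                        origin=ORIGIN_POSTHYB_DUP,
                        decidable=decidable,
                    )

    cross_pairs: List[Tuple[str, str]] = []
    if parent_truths and len(parents) == 2:
        la, lb = parents[0].genome_label, parents[1].genome_label
        if la in parent_truths and lb in parent_truths:
            by_anc_b: Dict[str, str] = {}
            for gid, anc in parent_truths[lb].ancestor_of.items():
                # orthologs pair the primary copies, not duplicates
                if not gid.endswith("_d1"):
                    by_anc_b[anc] = gid
            for gid, anc in parent_truths[la].ancestor_of.items():
                if gid.endswith("_d1"):
                    continue
                if anc in by_anc_b:
                    cross_pairs.append((gid, by_anc_b[anc]))

    if not records:
        warnings.warn("every hybrid copy was lost; hybrid ORF set is empty",
                      stacklevel=2)
    hybrid = OrfSet("hybrid", records)
    truth = SimTruth(
        records=truth_records,
        lost=lost,
        parent_truths=dict(parent_truths) if parent_truths else {},
        cross_parent_pairs=cross_pairs,
    )
    return hybrid, truth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: ancestor → parents → hybrid, with truth."""
    ancestor = simulate_ancestor(config)
    parents: Dict[str, OrfSet] = {}
    parent_truths: Dict[str, ParentTruth] = {}
    for i, label in enumerate(config.parent_labels):
        orfs, ptruth = diverge_parent(
            ancestor,
            label,
            config.div_parent,
            config.dup_rate_parent,
            seed=[1, config.seed, i],
        )
        parents[label] = orfs
        parent_truths[label] = ptruth
    hybrid, truth = make_hybrid(
        [parents[label] for label in config.parent_labels],
        config.ploidy,
        config.loss_rate,
        config.div_posthyb,
        config.dup_rate_hybrid,
        seed=[2, config.seed],
        parent_truths=parent_truths,
    )
    return SimDataset(ancestor, parents, hybrid, truth, config)


def score_recovery(
    assignments,
    truth: SimTruth,
    groups=None,
) -> RecoveryMetrics:
    """Score pipeline output against simulator ground truth.

    Precision: correct-parent assignments / all ASSIGNED.  Recall:
    correct-parent assignments / decidable truth ORFs.  Copy-number error
    compares predicted copies per parental gene against surviving true
    copies, over parental genes with at least one surviving copy.  Group
    purity (when hybrid homolog groups are supplied) is the mean, over
    groups, of the fraction of members sharing the group's majority source
    parent.
    """
    from .assign import ASSIGNED, copy_numbers  # local import avoids a cycle

    by_id = {a.hybrid_id: a for a in assignments}
    unknown = set(by_id) - set(truth.records)
    if unknown:
        raise ValueError(
            f"assignments reference unknown hybrid ids: {sorted(unknown)[:5]}"
        )

    labels = sorted({r.parent_label for r in truth.records.values()})
    correct: Counter = Counter()
    assigned: Counter = Counter()
    decidable: Counter = Counter()
    for hid, rec in truth.records.items():
        if rec.decidable:
            decidable[rec.parent_label] += 1
        a = by_id.get(hid)
        if a is not None and a.category == ASSIGNED:
            assigned[a.parent_label] += 1
            if a.parent_label == rec.parent_label:
                correct[rec.parent_label] += 1

    n_assigned = sum(assigned.values())
    n_correct = sum(correct.values())
    n_decidable = sum(decidable.values())
    precision = n_correct / n_assigned if n_assigned else None
    recall = n_correct / n_decidable if n_decidable else 0.0
    per_parent_precision = {
        lab: (correct[lab] / assigned[lab] if assigned[lab] else None)
        for lab in labels
    }
    per_parent_recall = {
        lab: (correct[lab] / decidable[lab] if decidable[lab] else 0.0)
        for lab in labels
    }

    true_cn = truth.true_copy_numbers()
    pred_cn = {
        (r.parent_label, r.parental_gene_id): r.copy_number
        for r in copy_numbers([a for a in assignments])
    }
    exact = 0
    abs_err = 0.0
    for key, true_count in true_cn.items():
        pred = pred_cn.get(key, 0)
        if pred == true_count:
            exact += 1
        abs_err += abs(pred - true_count)
    n_genes = len(true_cn)
    exact_frac = exact / n_genes if n_genes else 1.0
    mean_abs = abs_err / n_genes if n_genes else 0.0

    purity = None
    if groups is not None:
        vals = []
        for g in groups:
            origins = [
                truth.records[m].parent_label
                for m in g.member_ids
                if m in truth.records
            ]
            if origins:
                vals.append(Counter(origins).most_common(1)[0][1] / len(origins))
        purity = sum(vals) / len(vals) if vals else None

    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        per_parent_precision=per_parent_precision,
        per_parent_recall=per_parent_recall,
        n_assigned=n_assigned,
        n_decidable=n_decidable,
        copy_number_exact_fraction=exact_frac,
        copy_number_mean_abs_error=mean_abs,
        group_purity=purity,
    )
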