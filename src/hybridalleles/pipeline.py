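"""End-to-end orchestration: alignment → orthology → assignment → reports.

:func:`analyze` runs the whole method on in-memory ORF sets and returns a
:class:`PipelineResult`; :func:`run_pipeline` is the file-level wrapper that
reads FASTA inputs, writes every TSV/FASTA product into an output directory
and returns a manifest (path, size, sha256) of everything written.  Given
identical inputs and configuration the outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import align, assign, homology, seqio

logger = logging.getLogger("hybridalleles")

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_pipeline"]


@dataclass
class PipelineConfig:
    hybrid_fasta: str
    parent_fastas: Dict[str, str]  # label -> path, insertion-ordered
    outdir: str
    evalue_keep: float = 0.05
    identity_min: float = 80.0
    backend: str = "builtin"
    group_edge_layers: Tuple[str, ...] = (
        "self",
        "parent-paralog",
        "cross-ortholog",
    )
    propagate_paralogs: bool = True
    alpha: float = 0.01
    seed: int = 0
    threads: int = 1
    hybrid_label: str = "hybrid"

    def __post_init__(self) -> None:
        if not 2 <= len(self.parent_fastas) <= 4:
            raise ValueError(
                f"between 2 and 4 parental genomes are supported, "
                f"got {len(self.parent_fastas)}"
            )
        if not 0.0 < self.identity_min < 100.0:
            raise ValueError("identity_min must be in (0, 100)")
        if self.evalue_keep <= 0:
            raise ValueError("evalue_keep must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    hybrid: seqio.OrfSet
    parents: Dict[str, seqio.OrfSet]
    n_jobs: int
    ortholog_results: Dict[str, homology.OrthologResult]
    self_paralogs: Dict[str, List[homology.BbhPair]]
    cross_parent: Optional[homology.OrthologResult]
    assignments: List[assign.AlleleAssignment]
    hybrid_paralog_groups: List[homology.HomologGroup]
    homolog_groups: List[homology.HomologGroup]
    summary: assign.CategorySummary
    copy_records: List[assign.CopyNumberRecord]
    venn_counts: Optional[Dict[str, int]]


def _timed(stage: str, start: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall=%.2fs %s", stage, time.perf_counter() - start, extra)


def analyze(
    hybrid: seqio.OrfSet,
    parents: Mapping[str, seqio.OrfSet],
    params: Optional[align.AlignParams] = None,
    backend: str = "builtin",
    identity_min: float = 80.0,
    group_edge_layers: Sequence[str] = ("self", "parent-paralog", "cross-ortholog"),
    propagate_paralogs: bool = True,
    run_cross_parent: Optional[bool] = None,
) -> PipelineResult:
    """Run the full method on in-memory ORF sets.

    Stages, in order: job planning (3P+1 core alignment jobs), alignment,
    per-query best hits, 1:1 orthologs per parent and self-paralogs per
    genome, parental allele assignment (optionally propagated to extra
    copies through hybrid paralog pairs), homolog grouping, category
    summary, copy numbers and, with exactly two parents, the shared-
    function (cross-parent ortholog retention) counts.
    """
    if params is None:
        params = align.AlignParams()
    parent_labels = list(parents)
    jobs = align.plan_jobs(hybrid.genome_label, parent_labels)
    logger.info(
        "planned %d alignment jobs for %d parents", len(jobs), len(parent_labels)
    )
    sets: Dict[str, seqio.OrfSet] = {hybrid.genome_label: hybrid, **parents}

    tables: Dict[Tuple[str, str], align.HitTable] = {}
    for job in jobs:
        t0 = time.perf_counter()
        table = align.run_backend(
            job, sets[job.query_genome], sets[job.subject_genome], params, backend
        )
        tables[(job.query_genome, job.subject_genome)] = table
        _timed(f"align:{job.query_genome}->{job.subject_genome}", t0, hits=len(table))

    hyb = hybrid.genome_label
    t0 = time.perf_counter()
    ortholog_results = {
        p: homology.find_orthologs(
            tables[(hyb, p)], tables[(p, hyb)], identity_min, params.evalue_keep
        )
        for p in parent_labels
    }
    self_paralogs = {
        g: homology.find_self_paralogs(tables[(g, g)]) for g in sets
    }
    _timed(
        "homology",
        t0,
        **{f"orthologs_{p}": len(r.pairs) for p, r in ortholog_results.items()},
    )

    if run_cross_parent is None:
        run_cross_parent = len(parent_labels) == 2
    cross_res: Optional[homology.OrthologResult] = None
    if run_cross_parent and len(parent_labels) == 2:
        pa, pb = parent_labels
        t0 = time.perf_counter()
        fwd = align.run_backend(
            align.JobSpec(pa, pb, align.PURPOSE_FORWARD), parents[pa], parents[pb],
            params, backend,
        )
        rev = align.run_backend(
            align.JobSpec(pb, pa, align.PURPOSE_REVERSE), parents[pb], parents[pa],
            params, backend,
        )
        cross_res = homology.cross_parent_orthologs(
            fwd, rev, identity_min, params.evalue_keep
        )
        _timed("cross-parent-orthologs", t0, pairs=len(cross_res.pairs))

    t0 = time.perf_counter()
    assignments = assign.assign_parental_alleles(
        {p: r.pairs for p, r in ortholog_results.items()},
        {p: r.subthreshold_query_ids for p, r in ortholog_results.items()},
        hybrid.ids(),
        identity_min,
    )
    if propagate_paralogs:
        assignments = assign.propagate_via_paralogs(
            assignments, self_paralogs[hyb]
        )
    _timed(
        "assignment",
        t0,
        assigned=sum(1 for a in assignments if a.category == assign.ASSIGNED),
    )

    hybrid_paralog_groups = homology.merge_into_groups(
        self_paralogs[hyb], genome=hyb
    )
    groups = assign.hybrid_homolog_groups(
        self_paralogs[hyb],
        {p: self_paralogs[p] for p in parent_labels},
        cross_res.pairs if cross_res else [],
        assignments,
        layers=group_edge_layers,
        hybrid_label=hyb,
    )
    summary = assign.classify_summary(
        assignments, hybrid_paralog_groups, parent_labels
    )
    copy_records = assign.copy_numbers(assignments)
    venn = None
    if cross_res is not None and len(parent_labels) == 2:
        venn = assign.shared_function_report(
            assignments, cross_res.pairs, parent_labels
        )
    return PipelineResult(
        hybrid=hybrid,
        parents=dict(parents),
        n_jobs=len(jobs),
        ortholog_results=ortholog_results,
        self_paralogs=self_paralogs,
        cross_parent=cross_res,
        assignments=assignments,
        hybrid_paralog_groups=hybrid_paralog_groups,
        homolog_groups=groups,
        summary=summary,
        copy_records=copy_records,
        venn_counts=venn,
    )


# ---------------------------------------------------------------------------
# file-level products
# ---------------------------------------------------------------------------


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def _summary_rows(result: PipelineResult) -> List[Tuple[str, int]]:
    s = result.summary
    rows = [("total_genes", s.total)]
    for parent, count in s.assigned.items():
        rows.append((f"assigned_{parent}", count))
    rows += [
        ("ambiguous_equal_identity", s.ambiguous),
        ("subthreshold_identity", s.subthreshold),
        ("no_prediction", s.no_prediction),
        ("distinct_paralogs", s.distinct_paralogs),
        ("paralog_groups", s.n_paralog_groups),
        ("paralog_pairs", s.n_paralog_pairs),
    ]
    return rows


def write_products(result: PipelineResult, outdir: str | Path) -> Dict[str, dict]:
    """Write every TSV/FASTA product; return {name: {path, bytes, sha256}}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    hyb = result.hybrid.genome_label
    try:
        for parent, res in result.ortholog_results.items():
            path = outdir / f"orthologs_{parent}.tsv"
            _write_tsv(
                path,
                ["hybrid_id", "parent_id", "pident", "evalue"],
                [(p.id_a, p.id_b, p.pident, p.evalue) for p in res.pairs],
            )
            written.append(path)
        for genome, pairs in result.self_paralogs.items():
            path = outdir / f"paralogs_{genome}.tsv"
            _write_tsv(
                path,
                ["id_a", "id_b", "pident", "evalue"],
                [(p.id_a, p.id_b, p.pident, p.evalue) for p in pairs],
            )
            written.append(path)
        path = outdir / "assignments.tsv"
        _write_tsv(
            path,
            ["hybrid_id", "category", "parent", "parental_gene", "pident", "via"],
            [
                (a.hybrid_id, a.category, a.parent_label, a.parental_gene_id,
                 a.pident, a.via)
                for a in result.assignments
            ],
        )
        written.append(path)
        path = outdir / "homolog_groups.tsv"
        by_id = {a.hybrid_id: a for a in result.assignments}
        rows = []
        for gi, g in enumerate(result.homolog_groups, 1):
            members = sorted(g.member_ids)
            annos = []
            for m in members:
                a = by_id.get(m)
                if a is not None and a.category == assign.ASSIGNED:
                    annos.append(f"{m}:{a.parent_label}:{a.parental_gene_id}")
            rows.append((f"group{gi:05d}", len(members), ",".join(members),
                         ",".join(annos)))
        _write_tsv(path, ["group_id", "n_members", "members", "parental_alleles"], rows)
        written.append(path)
        path = outdir / "copy_number.tsv"
        _write_tsv(
            path,
            ["parental_gene", "parent", "copy_number", "hybrid_ids"],
            [
                (r.parental_gene_id, r.parent_label, r.copy_number,
                 ",".join(r.hybrid_ids))
                for r in result.copy_records
            ],
        )
        written.append(path)
        path = outdir / "summary.tsv"
        _write_tsv(path, ["category", hyb], _summary_rows(result))
        written.append(path)
        if result.venn_counts is not None:
            path = outdir / "venn_counts.tsv"
            _write_tsv(
                path,
                ["region", "count"],
                sorted(result.venn_counts.items()),
            )
            written.append(path)
        path = outdir / "id_mapping.tsv"
        _write_tsv(
            path,
            ["hybrid_id", "parental_id", "parent_label"],
            [
                (a.hybrid_id, a.parental_gene_id, a.parent_label)
                for a in result.assignments
                if a.category == assign.ASSIGNED
            ],
        )
        written.append(path)
        mapping = seqio.IdMapping(
            pairs={
                a.hybrid_id: a.parental_gene_id
                for a in result.assignments
                if a.category == assign.ASSIGNED
            }
        )
        path = outdir / f"{hyb}_annotated.fasta"
        seqio.write_fasta(seqio.rewrite_fasta_ids(result.hybrid, mapping), path)
        written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    manifest: Dict[str, dict] = {}
    for path in written:
        data = path.read_bytes()
        manifest[path.name] = {
            "path": str(path),
            "bytes": len(data),
            "sha256": hashlib.sha256(data).hexdigest(),
        }
    return manifest


def run_pipeline(config: PipelineConfig) -> Dict[str, dict]:
    """Read FASTA inputs, run :func:`analyze`, write products and manifest."""
    t0 = time.perf_counter()
    hybrid = seqio.read_orf_fasta(config.hybrid_fasta, config.hybrid_label)
    parents = {
        label: seqio.read_orf_fasta(path, label)
        for label, path in config.parent_fastas.items()
    }
    _timed("read-inputs", t0, hybrid=len(hybrid),
           **{label: len(p) for label, p in parents.items()})
    params = align.AlignParams(evalue_keep=config.evalue_keep)
    result = analyze(
        hybrid,
        parents,
        params=params,
        backend=config.backend,
        identity_min=config.identity_min,
        group_edge_layers=config.group_edge_layers,
        propagate_paralogs=config.propagate_paralogs,
    )
    manifest = write_products(result, config.outdir)
    manifest_path = Path(config.outdir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %d products to %s", len(manifest), config.outdir)
    return manifest
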