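"""All-vs-all nucleotide alignment: job planning, backends, hit tables.

The orthology pipeline needs, for a hybrid H and parents P1..Pk, the hit
tables of H against each parent in both directions plus every genome
against itself — 3P+1 jobs for P parents.  Two interchangeable backends
produce those tables:

* ``external-blastn`` shells out to NCBI ``makeblastdb``/``blastn`` and
  parses the tabular output;
* ``builtin`` is a self-contained k-mer-seeded aligner (exact candidate
  pre-filter on shared k-mers, then full alignment of each candidate pair
  with edlib) with blastn-style scoring and a Karlin–Altschul e-value.
  Its e-values are approximate; downstream stages depend only on hit
  ordering and on the e-value save threshold, which both backends honour.

Only the single best-scoring HSP per (query, subject) pair is kept: the
best-hit and reciprocity logic downstream is strictly pairwise.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib

from .seqio import OrfSet

__all__ = [
    "AlignmentHit",
    "HitTable",
    "JobSpec",
    "AlignParams",
    "plan_jobs",
    "run_backend",
    "evalue_from_score",
    "parse_tabular_hits",
]

PURPOSE_FORWARD = "ortholog-forward"
PURPOSE_REVERSE = "ortholog-reverse"
PURPOSE_SELF = "self-paralog"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    """One pairwise local-alignment result (the best HSP of a pair)."""

    query_id: str
    subject_id: str
    evalue: float
    pident: float
    pgaps: Optional[float]
    aln_len: int
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of range: {self.pident}")
        if self.pgaps is not None and not (0.0 <= self.pgaps <= 100.0):
            raise ValueError(f"pgaps out of range: {self.pgaps}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


@dataclass
class HitTable:
    """All saved hits for one (query genome, subject genome) job."""

    query_genome: str
    subject_genome: str
    hits: List[AlignmentHit] = field(default_factory=list)

    def validate_ids(self, query: OrfSet, subject: OrfSet) -> None:
        for h in self.hits:
            if h.query_id not in query:
                raise ValueError(f"unknown query id {h.query_id!r}")
            if h.subject_id not in subject:
                raise ValueError(f"unknown subject id {h.subject_id!r}")

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class JobSpec:
    query_genome: str
    subject_genome: str
    purpose: str

    def __post_init__(self) -> None:
        is_self = self.query_genome == self.subject_genome
        if is_self != (self.purpose == PURPOSE_SELF):
            raise ValueError(
                "purpose must be 'self-paralog' exactly when query and "
                "subject genomes coincide"
            )


@dataclass
class AlignParams:
    """Alignment scoring and filtering parameters.

    Defaults follow blastn conventions: match +2, mismatch −3, gap open 5,
    gap extend 2, and hits are saved only at e-value ≤ 0.05 (a deliberately
    stringent threshold compared to BLAST's default of 10).  ``karlin_lambda``
    and ``karlin_k`` are the ungapped Karlin–Altschul constants used by the
    builtin backend to convert raw scores to e-values.
    """

    evalue_keep: float = 0.05
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    both_strands: bool = True
    k: int = 11
    min_seed_hits: int = 2
    min_seed_frac: float = 0.01
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41

    def __post_init__(self) -> None:
        if self.evalue_keep <= 0:
            raise ValueError("evalue_keep must be > 0")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("require match > 0 and mismatch < 0")
        if self.k < 4:
            raise ValueError("seed length k must be >= 4")


def plan_jobs(hybrid_label: str, parent_labels: Sequence[str]) -> List[JobSpec]:
    """Plan the 3P+1 alignment jobs for a hybrid and its P parents.

    For each parent: hybrid→parent and parent→hybrid; then each of the P+1
    genomes against itself.  Two parents therefore yield seven jobs.  Order
    is deterministic (parents in the given order, forward before reverse,
    self jobs last starting with the hybrid).
    """
    parents = list(parent_labels)
    if not 2 <= len(parents) <= 4:
        raise ValueError(
            f"between 2 and 4 parental genomes are supported, got {len(parents)}"
        )
    labels = [hybrid_label] + parents
    if len(set(labels)) != len(labels):
        raise ValueError("genome labels must be distinct")
    jobs: List[JobSpec] = []
    for parent in parents:
        jobs.append(JobSpec(hybrid_label, parent, PURPOSE_FORWARD))
        jobs.append(JobSpec(parent, hybrid_label, PURPOSE_REVERSE))
    for label in labels:
        jobs.append(JobSpec(label, label, PURPOSE_SELF))
    return jobs


def evalue_from_score(
    raw_score: float,
    m: int,
    n: int,
    lambda_: float,
    K: float,
) -> float:
    """Karlin–Altschul expectation: E = K·m·n·exp(−λ·S).

    ``m`` is the query length and ``n`` the effective (total) subject
    search-space length.  Monotonically decreasing in the raw score.
    """
    if m < 1 or n < 1:
        raise ValueError("query and subject lengths must be >= 1")
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda and K must be > 0")
    exponent = -lambda_ * raw_score
    if exponent > 700.0:  # avoid float overflow; such 'hits' are junk anyway
        return math.inf
    return K * m * n * math.exp(exponent)


# ---------------------------------------------------------------------------
# builtin backend
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _alignment_stats(
    cigar: str,
    query: str,
    subject: str,
) -> Tuple[int, int, int, int, int]:
    """Count (matches, mismatches, gap_cols, gap_opens, aln_len) of a cigar.

    ``N`` is never counted as an identity: aligned columns involving an N in
    either sequence are reclassified as mismatches.
    """
    matches = mismatches = gap_cols = gap_opens = 0
    has_n = "N" in query or "N" in subject
    qi = si = 0
    runs = _CIGAR_RE.findall(cigar)
    if not has_n:
        for num, op in runs:
            length = int(num)
            if op == "=":
                matches += length
            elif op == "I" or op == "D":
                gap_cols += length
                gap_opens += 1
            else:  # X or M
                mismatches += length
    else:
        for num, op in runs:
            length = int(num)
            if op == "=":
                for j in range(length):
                    if query[qi + j] == "N" or subject[si + j] == "N":
                        mismatches += 1
                    else:
                        matches += 1
                qi += length
                si += length
            elif op == "I":  # insertion relative to subject: consumes query
                gap_cols += length
                gap_opens += 1
                qi += length
            elif op == "D":
                gap_cols += length
                gap_opens += 1
                si += length
            else:  # X or M
                mismatches += length
                qi += length
                si += length
    aln_len = matches + mismatches + gap_cols
    return matches, mismatches, gap_cols, gap_opens, aln_len


def _score_alignment(
    query: str, subject: str, params: AlignParams
) -> Optional[Tuple[float, float, float, int]]:
    """Globally align two sequences; return (score, pident, pgaps, aln_len)."""
    res = edlib.align(query, subject, task="path", mode="NW")
    cigar = res.get("cigar")
    if not cigar:
        return None
    matches, mismatches, gap_cols, gap_opens, aln_len = _alignment_stats(
        cigar, query, subject
    )
    if aln_len < 1:
        return None
    score = (
        params.match * matches
        + params.mismatch * mismatches
        - (params.gap_open * gap_opens + params.gap_extend * gap_cols)
    )
    pident = 100.0 * matches / aln_len
    pgaps = 100.0 * gap_cols / aln_len
    return float(score), pident, pgaps, aln_len


def _kmers(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _builtin_align(
    query: OrfSet, subject: OrfSet, params: AlignParams
) -> List[AlignmentHit]:
    k = params.k
    index: Dict[str, List[str]] = defaultdict(list)
    for rec in subject:
        for kmer in _kmers(rec.seq, k):
            index[kmer].append(rec.id)
    n_space = subject.total_bases()
    is_self = query is subject or (
        query.genome_label == subject.genome_label
    )

    hits: List[AlignmentHit] = []
    for qrec in query:
        qseq = qrec.seq
        counts: Dict[str, int] = defaultdict(int)
        for kmer in _kmers(qseq, k):
            for sid in index.get(kmer, ()):
                counts[sid] += 1
        rc_counts: Dict[str, int] = defaultdict(int)
        if params.both_strands:
            for kmer in _kmers(reverse_complement(qseq), k):
                for sid in index.get(kmer, ()):
                    rc_counts[sid] += 1
        # Chance k-mer sharing between long unrelated sequences grows with
        # length (~L^2/4^k expected shared seeds), so the seed requirement
        # scales with the shorter sequence: homologs down to ~70% identity
        # share an order of magnitude more seeds than chance pairs do.
        def _enough(sid: str, c: int) -> bool:
            need = max(
                params.min_seed_hits,
                int(params.min_seed_frac * min(qrec.length, subject[sid].length)),
            )
            return c >= need

        candidates = {
            sid for sid, c in counts.items() if _enough(sid, c)
        } | {
            sid for sid, c in rc_counts.items() if _enough(sid, c)
        }
        if is_self:
            candidates.add(qrec.id)  # identity self-hit always evaluated
        for sid in sorted(candidates):
            sseq = subject[sid].seq
            best = None
            # align the better-seeded orientation first; fall back to the
            # other only when it also has seeds
            orientations = []
            fwd_c, rc_c = counts.get(sid, 0), rc_counts.get(sid, 0)
            if sid == qrec.id or fwd_c >= rc_c:
                orientations.append(qseq)
                if params.both_strands and rc_c and _enough(sid, rc_c):
                    orientations.append(reverse_complement(qseq))
            else:
                orientations.append(reverse_complement(qseq))
                if fwd_c and _enough(sid, fwd_c):
                    orientations.append(qseq)
            for oriented in orientations:
                res = _score_alignment(oriented, sseq, params)
                if res is None:
                    continue
                if best is None or res[0] > best[0]:
                    best = res
            if best is None:
                continue
            score, pident, pgaps, aln_len = best
            evalue = evalue_from_score(
                score, qrec.length, n_space, params.karlin_lambda, params.karlin_k
            )
            if evalue > params.evalue_keep:
                continue
            hits.append(
                AlignmentHit(
                    query_id=qrec.id,
                    subject_id=sid,
                    evalue=evalue,
                    pident=round(pident, 2),
                    pgaps=round(pgaps, 2),
                    aln_len=aln_len,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# external blastn backend
# ---------------------------------------------------------------------------

_BLAST_OUTFMT = (
    "6 qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore gaps"
)


def _external_blastn(
    query: OrfSet, subject: OrfSet, params: AlignParams
) -> List[AlignmentHit]:
    from .seqio import write_fasta

    makeblastdb = shutil.which("makeblastdb")
    blastn = shutil.which("blastn")
    if makeblastdb is None or blastn is None:
        raise RuntimeError(
            "external blastn backend requested but makeblastdb/blastn were "
            "not found on PATH; use backend='builtin' instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        qpath = tmp_path / "query.fasta"
        spath = tmp_path / "subject.fasta"
        write_fasta(query, qpath)
        write_fasta(subject, spath)
        subprocess.run(
            [makeblastdb, "-in", str(spath), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        proc = subprocess.run(
            [
                blastn,
                "-task",
                "blastn",
                "-query",
                str(qpath),
                "-db",
                str(spath),
                "-evalue",
                str(params.evalue_keep),
                "-reward",
                str(params.match),
                "-penalty",
                str(params.mismatch),
                "-gapopen",
                str(params.gap_open),
                "-gapextend",
                str(params.gap_extend),
                "-strand",
                "both" if params.both_strands else "plus",
                "-dust",
                "no",
                "-outfmt",
                _BLAST_OUTFMT,
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    hits: Dict[Tuple[str, str], AlignmentHit] = {}
    for line in proc.stdout.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        qid, sid = f[0], f[1]
        pident = float(f[2])
        aln_len = int(f[3])
        evalue = float(f[10])
        score = float(f[11])
        gaps = int(f[12])
        hit = AlignmentHit(
            query_id=qid,
            subject_id=sid,
            evalue=evalue,
            pident=pident,
            pgaps=round(100.0 * gaps / aln_len, 2),
            aln_len=aln_len,
            score=score,
        )
        key = (qid, sid)
        prev = hits.get(key)
        if prev is None or (hit.score, -hit.evalue) > (prev.score, -prev.evalue):
            hits[key] = hit
    out = [hits[k] for k in sorted(hits)]
    return out


def run_backend(
    job: JobSpec,
    query: OrfSet,
    subject: OrfSet,
    params: Optional[AlignParams] = None,
    backend: str = "builtin",
) -> HitTable:
    """Execute one alignment job and return its hit table.

    Every hit satisfies ``evalue <= params.evalue_keep``; at most one hit
    (the best-scoring HSP) is kept per (query, subject) pair; hit order is
    deterministic (lexicographic by ids).
    """
    if params is None:
        params = AlignParams()
    if len(query) == 0:
        raise ValueError("empty query set")
    if query.genome_label != job.query_genome or subject.genome_label != job.subject_genome:
        raise ValueError(
            f"job is {job.query_genome}->{job.subject_genome} but sets are "
            f"{query.genome_label}->{subject.genome_label}"
        )
    if backend == "builtin":
        hits = _builtin_align(query, subject, params)
    elif backend in ("external-blastn", "blastn", "external"):
        hits = _external_blastn(query, subject, params)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return HitTable(job.query_genome, job.subject_genome, hits)


def parse_tabular_hits(
    path: str | Path, query_genome: str, subject_genome: str
) -> HitTable:
    """Parse precomputed BLAST tabular output (outfmt-6 style) into a table.

    The 12 standard columns are required; a 13th ``gaps`` column, when
    present, provides the gap percentage (``gaps/length*100``).  With only
    12 columns the gap percentage is unavailable (``pgaps=None``) — column
    6 counts gap *openings*, not gap columns, and is not a substitute.
    Comment lines beginning with ``#`` are ignored.
    """
    hits: List[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) not in (12, 13):
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 or 13 columns, "
                    f"found {len(f)}"
                )
            aln_len = int(f[3])
            pgaps = None
            if len(f) == 13:
                pgaps = round(100.0 * int(f[12]) / aln_len, 2)
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    evalue=float(f[10]),
                    pident=float(f[2]),
                    pgaps=pgaps,
                    aln_len=aln_len,
                    score=float(f[11]),
                )
            )
    return HitTable(query_genome, subject_genome, hits)
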