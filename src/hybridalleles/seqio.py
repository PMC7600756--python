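"""Reading, writing and relabelling ORF sequence sets.

The unit of input throughout the pipeline is an :class:`OrfSet`: the complete
collection of open-reading-frame nucleotide sequences of one genome (one
hybrid and two to four parents), read from a multi-record FASTA file.  This
module also rewrites identifiers — FASTA headers and GFF3 ``ID``/``Parent``
attributes — once parental alleles have been predicted, so that a hybrid's
placeholder gene IDs can be annotated with the parental gene names they were
inherited from.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

from Bio import SeqIO

__all__ = [
    "OrfRecord",
    "OrfSet",
    "IdMapping",
    "read_orf_fasta",
    "write_fasta",
    "rewrite_fasta_ids",
    "rewrite_gff3_ids",
]

# IUPAC nucleotide codes, including ambiguity codes and gaps are rejected.
_VALID_RESIDUES = frozenset("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class OrfRecord:
    """A single ORF: a unique identifier plus its nucleotide sequence."""

    id: str
    seq: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ORF record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"ORF {self.id!r} has an empty sequence")


class OrfSet:
    """An ordered, id-unique collection of :class:`OrfRecord` for one genome."""

    def __init__(self, genome_label: str, records: Iterable[OrfRecord]):
        if not genome_label:
            raise ValueError("genome_label must be non-empty")
        self.genome_label = genome_label
        self.records: List[OrfRecord] = list(records)
        self._index: Dict[str, OrfRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(
                    f"duplicate id {rec.id!r} in genome {genome_label!r}"
                )
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OrfRecord]:
        return iter(self.records)

    def __contains__(self, orf_id: str) -> bool:
        return orf_id in self._index

    def __getitem__(self, orf_id: str) -> OrfRecord:
        return self._index[orf_id]

    def ids(self) -> List[str]:
        return [rec.id for rec in self.records]

    def total_bases(self) -> int:
        return sum(rec.length for rec in self.records)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OrfSet({self.genome_label!r}, n={len(self)})"


@dataclass
class IdMapping:
    """Mapping from hybrid ORF ids to predicted parental gene ids.

    ``policy`` controls what happens to ids absent from the mapping:
    ``"keep"`` leaves them untouched, ``"tag"`` appends an ``unassigned``
    note to the record description.
    """

    pairs: Dict[str, str] = field(default_factory=dict)
    policy: str = "keep"
    parent_labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.policy not in ("keep", "tag"):
            raise ValueError(f"unknown policy {self.policy!r}")
        for hybrid_id, parental_id in self.pairs.items():
            if not parental_id:
                raise ValueError(f"empty replacement id for {hybrid_id!r}")

    @classmethod
    def from_tsv(cls, path: str | Path, policy: str = "keep") -> "IdMapping":
        """Read a ``hybrid_id <TAB> parental_id <TAB> parent_label`` table."""
        pairs: Dict[str, str] = {}
        labels: Dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns")
            hybrid_id, parental_id = fields[0], fields[1]
            if hybrid_id in pairs:
                raise ValueError(f"{path}: duplicate hybrid id {hybrid_id!r}")
            pairs[hybrid_id] = parental_id
            if len(fields) >= 3:
                labels[hybrid_id] = fields[2]
        return cls(pairs=pairs, policy=policy, parent_labels=labels)


def read_orf_fasta(path: str | Path, genome_label: str) -> OrfSet:
    """Read a nucleotide multi-FASTA file into an :class:`OrfSet`.

    The id of each record is the first whitespace-delimited token of the
    header (matching the query-id convention of BLAST tabular output, so hit
    tables join back cleanly); the remainder of the header is preserved as
    the description.  Sequences are uppercased.  Duplicate ids, empty files
    and residues outside the IUPAC nucleotide alphabet are hard errors.
    """
    path = Path(path)
    records: List[OrfRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        seq = str(seqrec.seq).upper()
        for pos, base in enumerate(seq, 1):
            if base not in _VALID_RESIDUES:
                raise ValueError(
                    f"{path}: record {seqrec.id!r}: invalid residue "
                    f"{base!r} at position {pos}"
                )
        desc = seqrec.description
        if desc.startswith(seqrec.id):
            desc = desc[len(seqrec.id):].strip()
        records.append(OrfRecord(id=seqrec.id, seq=seq, description=desc))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    try:
        return OrfSet(genome_label, records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_fasta(orfs: OrfSet, path: str | Path, width: int = 60) -> None:
    """Write an :class:`OrfSet` back to FASTA, preserving id order."""
    with open(path, "w") as fh:
        for rec in orfs:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def rewrite_fasta_ids(orfs: OrfSet, mapping: IdMapping) -> OrfSet:
    """Relabel hybrid ORFs with their predicted parental gene ids.

    Each record whose id is a mapping key is renamed to the parental gene
    id; the original hybrid id is kept in the description so the renaming is
    reversible.  When several hybrid ORFs map to the same parental gene
    (inherited or post-hybridization copies), subsequent records are
    disambiguated with a ``_copy2``, ``_copy3`` ... suffix in input order.
    Record order and sequences are unchanged.
    """
    seen: Dict[str, int] = {}
    out: List[OrfRecord] = []
    for rec in orfs:
        if rec.id in mapping.pairs:
            parental = mapping.pairs[rec.id]
            seen[parental] = seen.get(parental, 0) + 1
            new_id = parental if seen[parental] == 1 else f"{parental}_copy{seen[parental]}"
            desc = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.append(OrfRecord(id=new_id, seq=rec.seq, description=desc))
        elif mapping.policy == "tag":
            desc = (rec.description + " unassigned").strip()
            out.append(OrfRecord(id=rec.id, seq=rec.seq, description=desc))
        else:
            out.append(rec)
    return OrfSet(orfs.genome_label, out)


_ATTR_RE = re.compile(r"^([^=]+)=(.*)$")


def _rewrite_attributes(attrs: str, mapping: IdMapping, strict: bool) -> tuple[str, bool]:
    """Rewrite one GFF3 column-9 string; returns (new_attrs, touched)."""
    parts = attrs.rstrip("\n").split(";")
    touched = False
    target: Optional[str] = None
    name_idx: Optional[int] = None
    out_parts: List[str] = []
    for idx, part in enumerate(parts):
        m = _ATTR_RE.match(part)
        if m is None:
            out_parts.append(part)
            continue
        key, value = m.group(1), m.group(2)
        if key in ("ID", "Parent"):
            values = value.split(",")
            mapped = [mapping.pairs.get(v) for v in values]
            if any(mapped):
                touched = True
                if target is None:
                    target = next(v for v in mapped if v)
                if strict:
                    new_values = [mv if mv else v for v, mv in zip(values, mapped)]
                    part = f"{key}={','.join(new_values)}"
        elif key == "Name":
            name_idx = idx
        out_parts.append(part)
    if touched and not strict and target is not None:
        if name_idx is not None:
            out_parts[name_idx] = f"Name={target}"
        else:
            out_parts.append(f"Name={target}")
    return ";".join(out_parts), touched


def rewrite_gff3_ids(
    gff3_in: str | Path,
    mapping: IdMapping,
    gff3_out: str | Path,
    strict: bool = False,
) -> int:
    """Annotate a GFF3 file with predicted parental gene ids.

    For every feature whose ``ID`` or ``Parent`` attribute is a mapping key,
    a ``Name`` attribute carrying the parental gene id is set (added, or
    overwritten if present).  ``ID`` is preserved by default so that
    ``Parent`` references stay valid; with ``strict=True`` the ``ID`` and
    ``Parent`` values themselves are replaced.  Columns 1-8 of every line
    are emitted byte-identical to the input.  Returns the number of feature
    lines touched.
    """
    count = 0
    out_lines: List[str] = []
    with open(gff3_in) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                out_lines.append(stripped)
                continue
            cols = stripped.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{gff3_in}: line {lineno}: expected 9 tab-separated "
                    f"columns, found {len(cols)}"
                )
            new_attrs, touched = _rewrite_attributes(cols[8], mapping, strict)
            if touched:
                count += 1
                cols = cols[:8] + [new_attrs]
            out_lines.append("\t".join(cols))
    Path(gff3_out).write_text("\n".join(out_lines) + "\n")
    return count
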