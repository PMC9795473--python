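"""Reading and writing the formats the evaluator touches: FASTA, FASTQ, PAF.

FASTA/FASTQ go through Biopython's :mod:`Bio.SeqIO`; PAF is parsed here
(tab-separated, 0-based half-open coordinates, optional ``cg:Z``/``NM:i``/
``tp:A`` tags).  All internal coordinates are 0-based half-open, PAF native.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "CigarOp",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_paf",
    "write_paf",
    "parse_cigar",
    "cigar_to_string",
    "cigar_query_len",
    "cigar_target_len",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: CIGAR operations that consume query bases.
_Q_OPS = frozenset("=XIM")
#: CIGAR operations that consume target (reference) bases.
_T_OPS = frozenset("=XDM")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence: reference replicon, contig, or read."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: ``op`` in {=, X, I, D, M}, run length >= 1."""

    op: str
    run: int

    def __post_init__(self) -> None:
        if self.op not in "=XIDM":
            raise ValueError(f"unknown CIGAR op {self.op!r}")
        if self.run < 1:
            raise ValueError(f"CIGAR run must be >= 1, got {self.run}")


@dataclass
class AlignmentRecord:
    """One contig-vs-reference alignment (PAF semantics).

    Coordinates are 0-based half-open on the *forward* strands of both
    sequences.  For ``strand == '-'`` the CIGAR describes the alignment of
    the reverse-complemented query against the forward target, as in PAF.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    aln_cols: int
    mapq: int = 60
    cigar: Optional[list[CigarOp]] = None
    nm: Optional[int] = None
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"query interval [{self.query_start},{self.query_end}) out of "
                f"bounds for length {self.query_len} ({self.query_id})")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"target interval [{self.target_start},{self.target_end}) out "
                f"of bounds for length {self.target_len} ({self.target_id})")
        if self.n_match > self.aln_cols:
            raise ValueError("n_match cannot exceed alignment columns")
        if self.cigar is not None:
            qlen = cigar_query_len(self.cigar)
            tlen = cigar_target_len(self.cigar)
            if qlen != self.query_end - self.query_start:
                raise ValueError(
                    f"CIGAR consumes {qlen} query bases but coordinates span "
                    f"{self.query_end - self.query_start} ({self.query_id})")
            if tlen != self.target_end - self.target_start:
                raise ValueError(
                    f"CIGAR consumes {tlen} target bases but coordinates span "
                    f"{self.target_end - self.target_start} ({self.query_id})")


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse an extended CIGAR string into typed operations.

    Adjacent operations of the same kind are merged.  Only the operations
    {=, X, I, D, M} are accepted; a zero run length is an error.
    """
    if not text:
        return []
    pos = 0
    ops: list[CigarOp] = []
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR at offset {pos}: {text!r}")
        run, op = int(m.group(1)), m.group(2)
        if run == 0:
            raise ValueError(f"zero-length CIGAR run at offset {pos}: {text!r}")
        if ops and ops[-1].op == op:
            ops[-1] = CigarOp(op, ops[-1].run + run)
        else:
            ops.append(CigarOp(op, run))
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed CIGAR at offset {pos}: {text!r}")
    return ops


def cigar_to_string(ops: Iterable[CigarOp]) -> str:
    return "".join(f"{o.run}{o.op}" for o in ops)


def cigar_query_len(ops: Iterable[CigarOp]) -> int:
    """Query bases consumed: sum of runs of {=, X, I, M}."""
    return sum(o.run for o in ops if o.op in _Q_OPS)


def cigar_target_len(ops: Iterable[CigarOp]) -> int:
    """Target bases consumed: sum of runs of {=, X, D, M}."""
    return sum(o.run for o in ops if o.op in _T_OPS)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated and case-folded to upper.
    Duplicate ids and empty sequences under a header are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence under header {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; qualities are not retained (the evaluator never uses them)."""
    return [SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[SequenceRecord], path: str | Path,
                quality_char: str = "I") -> None:
    """Write FASTQ with a constant placeholder quality (simulated reads)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality_char * r.length}\n")


def _parse_paf_line(line: str, lineno: int) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"malformed PAF line {lineno}: expected >= 12 fields, "
                         f"got {len(fields)}")
    try:
        query_id = fields[0]
        query_len = int(fields[1])
        query_start = int(fields[2])
        query_end = int(fields[3])
        strand = fields[4]
        target_id = fields[5]
        target_len = int(fields[6])
        target_start = int(fields[7])
        target_end = int(fields[8])
        n_match = int(fields[9])
        aln_cols = int(fields[10])
        mapq = int(fields[11])
    except ValueError as exc:
        raise ValueError(f"malformed PAF line {lineno}: {exc}") from exc

    cigar: Optional[list[CigarOp]] = None
    nm: Optional[int] = None
    is_primary = True
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cigar = parse_cigar(tag[5:])
        elif tag.startswith("NM:i:"):
            nm = int(tag[5:])
        elif tag.startswith("tp:A:"):
            is_primary = tag[5:] != "S"
    try:
        return AlignmentRecord(
            query_id=query_id, query_len=query_len, query_start=query_start,
            query_end=query_end, strand=strand, target_id=target_id,
            target_len=target_len, target_start=target_start,
            target_end=target_end, n_match=n_match, aln_cols=aln_cols,
            mapq=mapq, cigar=cigar, nm=nm, is_primary=is_primary)
    except ValueError as exc:
        raise ValueError(f"invalid PAF record at line {lineno}: {exc}") from exc


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Read a PAF file (e.g. minimap2 output) into alignment records."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                records.append(_parse_paf_line(line, lineno))
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fields = [r.query_id, r.query_len, r.query_start, r.query_end,
                      r.strand, r.target_id, r.target_len, r.target_start,
                      r.target_end, r.n_match, r.aln_cols, r.mapq]
            tags = []
            if r.nm is not None:
                tags.append(f"NM:i:{r.nm}")
            tags.append("tp:A:P" if r.is_primary else "tp:A:S")
            if r.cigar is not None:
                tags.append(f"cg:Z:{cigar_to_string(r.cigar)}")
            fh.write("\t".join(str(f) for f in fields + tags) + "\n")
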