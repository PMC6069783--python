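"""Readers and writers for the external formats the pipeline touches.

FASTQ (phred+33), multi-FASTA references, SAM import/export of ungapped
placements, UCSC bedgraph, and TSV tables. Coordinates are 0-based
half-open internally; SAM conversion handles the 1-based offset. U
residues are mapped to T on ingest (DNA-space comparison); N never
matches any base downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

PLUS = "+"
MINUS = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class SmallRNARead:
    """One sequenced small RNA: id, nucleotide string, phred+33 qualities.

    Reads are never collapsed by sequence; every FASTQ record is an
    independent unit because downstream statistics count reads, not
    unique sequences.
    """

    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} "
                f"!= quality length {len(self.qual)}"
            )
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"read {self.read_id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """An ordered collection of named reference sequences of one category."""

    category: str
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise FormatError(
                f"duplicate sequence name {name!r} in {self.category} reference"
            )
        seq = _normalize_seq(seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"reference {name!r}: illegal characters {sorted(bad)}"
            )
        self.sequences[name] = seq


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One ungapped placement of a read on a reference sequence.

    ``start`` is the 0-based position of the leftmost aligned base on
    the reference plus strand, regardless of read orientation.
    """

    ref_name: str
    start: int
    strand: str
    read_id: str
    mismatches: int
    read_len: int

    @property
    def end(self) -> int:
        """0-based half-open end on the reference."""
        return self.start + self.read_len

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' end."""
        return self.start if self.strand == PLUS else self.start + self.read_len - 1


def read_fastq(path: str | Path) -> list[SmallRNARead]:
    """Parse a 4-line-record FASTQ file into validated reads.

    U residues are converted to T and sequences uppercased. Malformed
    records raise :class:`FormatError` naming the offending line. An
    empty file yields an empty list.
    """
    reads: list[SmallRNARead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"{path}: truncated FASTQ record near line {len(lines)}"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not header.startswith("@"):
            raise FormatError(f"{path}:{lineno}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
        read_id = header[1:].split()[0] if header[1:].split() else ""
        if not read_id:
            raise FormatError(f"{path}:{lineno}: empty read id")
        seq = _normalize_seq(seq)
        try:
            reads.append(SmallRNARead(read_id, seq, qual))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_fasta(path: str | Path, category: str) -> ReferenceSet:
    """Parse a multi-FASTA file into a :class:`ReferenceSet`.

    Headers are tokenized at the first whitespace; duplicate names and
    illegal residues are rejected.
    """
    refs = ReferenceSet(category=category)
    for record in SeqIO.parse(str(path), "fasta"):
        refs.add(record.id, str(record.seq))
    return refs


def write_fasta(refs: ReferenceSet | Mapping[str, str], path: str | Path) -> None:
    seqs = refs.sequences if isinstance(refs, ReferenceSet) else refs
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _count_mismatches(read_seq: str, ref_seq: str) -> int:
    return sum(1 for a, b in zip(read_seq, ref_seq) if a != b or a == "N" or b == "N")


def import_alignments(
    path: str | Path, refs: ReferenceSet
) -> list[AlignmentHit]:
    """Import mapped records of a SAM file as :class:`AlignmentHit` objects.

    SAM 1-based POS is converted to a 0-based start, FLAG 16 becomes a
    minus-strand hit, and unmapped records are dropped. The mismatch
    count is taken from the NM tag when present and recomputed against
    ``refs`` otherwise. Records with indels or clipping are skipped with
    a warning (ungapped alignment model).
    """
    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        header_sq = {
            sq["SN"]: sq["LN"] for sq in sam.header.to_dict().get("SQ", [])
        }
        for name, length in header_sq.items():
            if name not in refs.sequences:
                raise FormatError(
                    f"{path}: SAM reference {name!r} absent from "
                    f"{refs.category} reference set"
                )
            if length != len(refs.sequences[name]):
                raise FormatError(
                    f"{path}: SAM reference {name!r} length {length} != "
                    f"{len(refs.sequences[name])}"
                )
        for rec in sam:
            if rec.is_unmapped:
                continue
            cigar = rec.cigartuples or []
            if any(op != 0 for op, _ in cigar):  # 0 = M
                logger.warning(
                    "skipping %s: CIGAR %s has indels/clipping (ungapped model)",
                    rec.query_name,
                    rec.cigarstring,
                )
                continue
            strand = MINUS if rec.is_reverse else PLUS
            start = rec.reference_start
            seq = rec.query_sequence or ""
            read_len = len(seq) if seq else rec.query_length
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                window = refs.sequences[rec.reference_name][start : start + read_len]
                nm = _count_mismatches(seq, window)
            hits.append(
                AlignmentHit(
                    ref_name=rec.reference_name,
                    start=start,
                    strand=strand,
                    read_id=rec.query_name,
                    mismatches=nm,
                    read_len=read_len,
                )
            )
    return hits


def export_alignments(
    hits: Iterable[AlignmentHit],
    reads_by_id: Mapping[str, SmallRNARead],
    refs: ReferenceSet,
    path: str | Path,
) -> None:
    """Write placements as a position-sorted SAM file with NM tags.

    Minus-strand records store the reverse complement of the read, as
    SAM requires. Sorting is by (reference, position).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in refs.lengths.items()
        ],
    }
    ref_order = {name: i for i, name in enumerate(refs.names)}
    sorted_hits = sorted(hits, key=lambda h: (ref_order[h.ref_name], h.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in sorted_hits:
            read = reads_by_id[h.read_id]
            a = pysam.AlignedSegment(out.header)
            a.query_name = h.read_id
            a.flag = 16 if h.strand == MINUS else 0
            a.reference_id = ref_order[h.ref_name]
            a.reference_start = h.start
            a.mapping_quality = 255
            a.cigartuples = [(0, h.read_len)]
            a.query_sequence = revcomp(read.seq) if h.strand == MINUS else read.seq
            a.query_qualities = pysam.qualitystring_to_array(
                read.qual[::-1] if h.strand == MINUS else read.qual
            )
            a.set_tag("NM", h.mismatches)
            out.write(a)


def write_bedgraph(track, path: str | Path) -> None:
    """Write a coverage track as UCSC bedgraph (0-based half-open).

    Zero-valued runs are omitted; adjacent equal-valued bins merge into
    one interval. ``track`` is a :class:`smallrna.coverage.CoverageTrack`.
    """
    with open(path, "w") as fh:
        for ref_start, ref_end, value in track.intervals():
            fh.write(f"{track.ref_name}\t{ref_start}\t{ref_end}\t{value:g}\n")


def _render_cell(value) -> str:
    """Render a table cell with full (round-trip) precision for floats."""
    if value is None:
        return "NA"
    if isinstance(value, float):
        value = float(value)  # numpy scalars -> plain float
        if value != value:  # NaN
            return "NA"
        return repr(value)
    return str(value)


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write rows as a TSV with a header; floats keep full precision."""
    if columns is None:
        columns = list(rows[0]) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_render_cell(row.get(c)) for c in columns) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_table` back as strings."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    columns = lines[0].split("\t")
    return [dict(zip(columns, line.split("\t"))) for line in lines[1:]]
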