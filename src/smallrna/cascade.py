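"""Length selection, sequential category assignment, subgroup extraction.

Genome-mapping reads are tested against category references in a fixed
order (default rRNA, miRNA, tRNA, snRNA, transcript, TE); each read is
assigned to the first category it maps to, remaining reads fall into
"other". The pie chart of a small RNA library is the per-category share
of genome-mappers under this exclusive assignment. Four subgroups are
then extracted for downstream quantification:

* bonafide — genome-mappers minus miRNA/rRNA/tRNA/snRNA-assigned reads
  (structural-RNA decontamination);
* miRNA — the miRNA-assigned reads;
* siRNA — bonafide reads in the siRNA length window (default 21 nt);
* piRNA — bonafide reads in the piRNA length window (default 23-29 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import aligner
from .io_formats import ReferenceSet, SmallRNARead

STRUCTURAL = ("miRNA", "rRNA", "tRNA", "snRNA")
DEFAULT_ORDER = ("rRNA", "miRNA", "tRNA", "snRNA", "transcript", "TE")
OTHER = "other"
CATEGORIES = DEFAULT_ORDER + (OTHER,)


@dataclass
class PipelineParams:
    """User-tunable analysis windows and mismatch bounds (all in nt)."""

    min_len: int = 18
    max_len: int = 29
    sirna_len_min: int = 21
    sirna_len_max: int = 21
    pirna_len_min: int = 23
    pirna_len_max: int = 29
    genome_mm: int = 0
    te_mm: int = 3
    seed_len: int = 10
    category_order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.pirna_len_min > self.pirna_len_max:
            raise ValueError("pirna_len_min > pirna_len_max")
        unknown = set(self.category_order) - set(DEFAULT_ORDER)
        if unknown:
            raise ValueError(f"unknown categories in order: {sorted(unknown)}")


@dataclass
class CategoryAssignment:
    """Exclusive category of every genome-mapping read."""

    category_of: dict[str, str]
    counts: dict[str, int]
    total_genome_mappers: int
    total_genome_unique: int

    def reads_in(self, category: str) -> set[str]:
        return {r for r, c in self.category_of.items() if c == category}


@dataclass
class Subgroups:
    """The four analysis subgroups as read-id sets."""

    bonafide: set[str] = field(default_factory=set)
    mirna: set[str] = field(default_factory=set)
    sirna: set[str] = field(default_factory=set)
    pirna: set[str] = field(default_factory=set)

    def sizes(self) -> dict[str, int]:
        return {
            "bonafide": len(self.bonafide),
            "miRNA": len(self.mirna),
            "siRNA": len(self.sirna),
            "piRNA": len(self.pirna),
        }


def filter_by_length(
    reads: Iterable[SmallRNARead], min_len: int, max_len: int
) -> list[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if min_len <= len(r) <= max_len]


def categorize(
    reads: Sequence[SmallRNARead],
    category_refs: Mapping[str, ReferenceSet],
    params: PipelineParams,
    uniqueness: Mapping[str, str] | None = None,
) -> CategoryAssignment:
    """Assign each genome-mapping read to the first category it maps to.

    ``reads`` must already be restricted to genome-mappers. Category
    mapping aligns the read sequence against each category's multi-FASTA
    reference (sequence identity, not genomic-interval overlap) at the
    TE mismatch bound. Categories without a reference file are skipped;
    reads matching no category are "other".
    """
    unknown = set(params.category_order) - set(DEFAULT_ORDER)
    if unknown:
        raise ValueError(f"unknown categories in order: {sorted(unknown)}")
    indexes = {}
    for cat in params.category_order:
        refs = category_refs.get(cat)
        if refs is not None and len(refs) > 0:
            indexes[cat] = aligner.build_index(refs, params.seed_len)
    category_of: dict[str, str] = {}
    remaining = list(reads)
    for cat in params.category_order:
        if cat not in indexes:
            continue
        still_unmapped = []
        for read in remaining:
            if aligner.align(read, indexes[cat], params.te_mm):
                category_of[read.read_id] = cat
            else:
                still_unmapped.append(read)
        remaining = still_unmapped
    for read in remaining:
        category_of[read.read_id] = OTHER
    counts = {cat: 0 for cat in CATEGORIES}
    for cat in category_of.values():
        counts[cat] += 1
    n_unique = (
        sum(1 for r in reads if uniqueness.get(r.read_id) == aligner.UNIQUE)
        if uniqueness
        else 0
    )
    return CategoryAssignment(
        category_of=category_of,
        counts=counts,
        total_genome_mappers=len(reads),
        total_genome_unique=n_unique,
    )


def extract_subgroups(
    assignment: CategoryAssignment,
    reads_by_id: Mapping[str, SmallRNARead],
    params: PipelineParams,
) -> Subgroups:
    """Extract bonafide / miRNA / siRNA / piRNA subgroups.

    Transcript-, TE- and other-assigned reads are all bonafide; the
    length windows then carve siRNA and piRNA out of bonafide.
    """
    sub = Subgroups()
    for read_id, cat in assignment.category_of.items():
        if cat == "miRNA":
            sub.mirna.add(read_id)
        if cat in STRUCTURAL:
            continue
        sub.bonafide.add(read_id)
        n = len(reads_by_id[read_id])
        if params.sirna_len_min <= n <= params.sirna_len_max:
            sub.sirna.add(read_id)
        if params.pirna_len_min <= n <= params.pirna_len_max:
            sub.pirna.add(read_id)
    return sub


def pie_fractions(assignment: CategoryAssignment) -> dict[str, float]:
    """Per-category percentage of genome-mapping reads."""
    total = assignment.total_genome_mappers
    if total == 0:
        raise ValueError("no genome-mapping reads; pie undefined")
    return {cat: 100.0 * n / total for cat, n in assignment.counts.items()}
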