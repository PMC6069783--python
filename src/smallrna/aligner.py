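"""Exhaustive ungapped k-mismatch placement of short reads.

Replaces an external short-read aligner at desk scale with a matcher
whose hit set is provably complete: every ungapped placement with at
most ``max_mm`` substitutions on either strand is returned. Guarantee
by pigeonhole seeding — the read is partitioned into ``max_mm + 1``
non-overlapping chunks; if a placement has <= max_mm mismatches, at
least one chunk matches the reference exactly, so exact lookup of each
chunk followed by full verification cannot miss a hit.

Chunks at least as long as the index k-mer are located through the
hash index; shorter chunks (short reads at high mismatch bounds) fall
back to exact substring scanning, preserving the guarantee.

N in either read or reference always counts as a mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    MINUS,
    PLUS,
    AlignmentHit,
    ReferenceSet,
    SmallRNARead,
    revcomp,
)

logger = logging.getLogger(__name__)

UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"


@dataclass
class AlignmentIndex:
    """Hash index over fixed-length k-mers of a reference set (plus strand).

    Minus-strand hits are found by searching the reverse complement of
    the read against the plus strand, so only one strand is indexed.
    """

    refs: ReferenceSet
    seed_len: int
    kmer_map: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    @property
    def indexed_names(self) -> list[str]:
        return [n for n, s in self.refs.sequences.items() if len(s) >= self.seed_len]


def build_index(refs: ReferenceSet, seed_len: int = 10) -> AlignmentIndex:
    """Index every plus-strand k-mer position of every reference.

    References shorter than ``seed_len`` are excluded with a warning.
    """
    if seed_len < 8:
        raise ValueError(f"seed_len must be >= 8, got {seed_len}")
    if len(refs) == 0:
        raise ValueError(f"empty {refs.category!r} reference set")
    for name, seq in refs.sequences.items():
        if len(seq) == 0:
            raise ValueError(f"reference {name!r} is empty")
    index = AlignmentIndex(refs=refs, seed_len=seed_len)
    for name, seq in refs.sequences.items():
        if len(seq) < seed_len:
            logger.warning(
                "reference %r (%d nt) shorter than seed_len %d; excluded from index",
                name, len(seq), seed_len,
            )
            continue
        for pos in range(len(seq) - seed_len + 1):
            kmer = seq[pos : pos + seed_len]
            if "N" in kmer:
                continue
            index.kmer_map.setdefault(kmer, []).append((name, pos))
    return index


def _mismatches_bounded(a: str, b: str, bound: int) -> int:
    """Hamming distance counting N as mismatch; early exit past ``bound``."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > bound:
                return mm
    return mm


def _chunk_starts(read_len: int, n_chunks: int) -> list[tuple[int, int]]:
    """Partition [0, read_len) into n_chunks non-overlapping intervals."""
    base = read_len // n_chunks
    rem = read_len % n_chunks
    starts = []
    pos = 0
    for i in range(n_chunks):
        size = base + (1 if i < rem else 0)
        starts.append((pos, pos + size))
        pos += size
    return starts


def _candidate_starts(
    query: str, index: AlignmentIndex, max_mm: int
) -> set[tuple[str, int]]:
    """Candidate (ref, start) placements of ``query`` via pigeonhole seeds."""
    candidates: set[tuple[str, int]] = set()
    k = index.seed_len
    for c_start, c_end in _chunk_starts(len(query), max_mm + 1):
        chunk = query[c_start:c_end]
        if "N" in chunk:
            continue  # a chunk with N can never match exactly
        if len(chunk) >= k:
            seed = chunk[:k]
            for ref_name, pos in index.kmer_map.get(seed, ()):
                candidates.add((ref_name, pos - c_start))
        else:
            for ref_name, seq in index.refs.sequences.items():
                pos = seq.find(chunk)
                while pos != -1:
                    candidates.add((ref_name, pos - c_start))
                    pos = seq.find(chunk, pos + 1)
    return candidates


def align(
    read: SmallRNARead, index: AlignmentIndex, max_mm: int = 0
) -> list[AlignmentHit]:
    """Every ungapped placement of ``read`` with <= max_mm substitutions.

    Hits are returned sorted by (ref_name, start, strand) so downstream
    seeded sampling is reproducible across platforms.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    L = len(read.seq)
    if L < index.seed_len:
        logger.warning(
            "read %r (%d nt) shorter than seed_len %d; not aligned",
            read.read_id, L, index.seed_len,
        )
        return []
    hits: list[AlignmentHit] = []
    seen: set[tuple[str, int, str]] = set()
    for strand, query in ((PLUS, read.seq), (MINUS, revcomp(read.seq))):
        for ref_name, start in _candidate_starts(query, index, max_mm):
            if start < 0:
                continue
            ref_seq = index.refs.sequences[ref_name]
            if start + L > len(ref_seq):
                continue
            key = (ref_name, start, strand)
            if key in seen:
                continue
            seen.add(key)
            mm = _mismatches_bounded(query, ref_seq[start : start + L], max_mm)
            if mm <= max_mm:
                hits.append(
                    AlignmentHit(
                        ref_name=ref_name,
                        start=start,
                        strand=strand,
                        read_id=read.read_id,
                        mismatches=mm,
                        read_len=L,
                    )
                )
    hits.sort()
    return hits


def align_all(
    reads: Iterable[SmallRNARead], index: AlignmentIndex, max_mm: int = 0
) -> dict[str, list[AlignmentHit]]:
    """Align every read; returns hits keyed by read id (unmapped reads map to [])."""
    return {r.read_id: align(r, index, max_mm) for r in reads}


def classify_uniqueness(hits_per_read: Mapping[str, Sequence[AlignmentHit]]) -> dict[str, str]:
    """Flag each read unique / multi / unmapped by its genomic placement count."""
    flags = {}
    for read_id, hits in hits_per_read.items():
        if len(hits) == 0:
            flags[read_id] = UNMAPPED
        elif len(hits) == 1:
            flags[read_id] = UNIQUE
        else:
            flags[read_id] = MULTI
    return flags


@dataclass(frozen=True)
class PlacementPolicy:
    """How multi-mapping reads are reported.

    ``random_one`` mirrors single-placement aligner reporting: one
    placement drawn uniformly among the minimum-mismatch hits with a
    seeded generator. ``all`` keeps every placement (exhaustive
    profiling mode).
    """

    mode: str = "random_one"
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("random_one", "all"):
            raise ValueError(f"unknown placement mode {self.mode!r}")


def place_reads(
    hits_per_read: Mapping[str, Sequence[AlignmentHit]],
    policy: PlacementPolicy,
) -> list[AlignmentHit]:
    """Select reported placements per read under the given policy.

    In ``random_one`` mode ties are broken by sorting candidate hits by
    (ref_name, start, strand) before seeded uniform sampling, so runs
    are deterministic given (seed, input order).
    """
    rng = np.random.default_rng(policy.rng_seed)
    placed: list[AlignmentHit] = []
    for read_id in hits_per_read:
        hits = hits_per_read[read_id]
        if not hits:
            continue
        if policy.mode == "all":
            placed.extend(hits)
            continue
        best_mm = min(h.mismatches for h in hits)
        best = sorted(h for h in hits if h.mismatches == best_mm)
        placed.append(best[int(rng.integers(len(best)))])
    return placed
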