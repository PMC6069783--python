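"""Per-feature counting, normalization, nucleotide bias, length distribution.

Counting operates on reported placements of a subgroup against a
reference set (TEs, transcripts or miRNAs). Two normalizations are
provided: RPKM (reads per kilobase of feature per million genome
mappers) and reads-per-million of a subgroup (piRNA, miRNA, bonafide).
The 1U/10A bias — uridine at read position 1, adenine at position 10,
the hallmark of ping-pong piRNA processing — is computed per feature
and strand on the read in its own 5'->3' orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import MINUS, PLUS, AlignmentHit, ReferenceSet, SmallRNARead
from .aligner import UNIQUE


@dataclass
class FeatureCounts:
    """Raw per-feature tallies for one (subgroup x reference set) pair."""

    feature_len: dict[str, int]
    count_all: dict[str, int]
    count_unique: dict[str, int]
    sense_reads: dict[str, list[str]]      # read ids placed on plus strand
    antisense_reads: dict[str, list[str]]  # read ids placed on minus strand

    @property
    def features(self) -> list[str]:
        return list(self.feature_len)

    @property
    def total_all(self) -> int:
        return sum(self.count_all.values())


def count_features(
    placements: Iterable[AlignmentHit],
    uniqueness: Mapping[str, str],
    refs: ReferenceSet,
) -> FeatureCounts:
    """Tally placements per feature.

    Every placement increments its feature once (so in all-placements
    mode a multi-mapping read contributes to each feature it hits;
    under random_one it contributes exactly once). ``count_unique`` is
    restricted to genome-unique reads.
    """
    lengths = refs.lengths
    fc = FeatureCounts(
        feature_len=dict(lengths),
        count_all={n: 0 for n in lengths},
        count_unique={n: 0 for n in lengths},
        sense_reads={n: [] for n in lengths},
        antisense_reads={n: [] for n in lengths},
    )
    for hit in placements:
        if hit.ref_name not in lengths:
            raise KeyError(
                f"placement on {hit.ref_name!r} absent from "
                f"{refs.category} reference set"
            )
        fc.count_all[hit.ref_name] += 1
        if uniqueness.get(hit.read_id) == UNIQUE:
            fc.count_unique[hit.ref_name] += 1
        if hit.strand == PLUS:
            fc.sense_reads[hit.ref_name].append(hit.read_id)
        else:
            fc.antisense_reads[hit.ref_name].append(hit.read_id)
    return fc


def rpkm(count: int, feature_len: int, total_mappers: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_len <= 0:
        raise ValueError("feature_len must be > 0")
    if total_mappers <= 0:
        raise ValueError("total_mappers must be > 0")
    return count / ((feature_len / 1000.0) * (total_mappers / 1e6))


def per_million(count: int, subgroup_total: int) -> float | None:
    """Reads per million of a subgroup; None (NA) when the subgroup is empty."""
    if subgroup_total <= 0:
        return None
    return 1e6 * count / subgroup_total


def nucleotide_bias(
    read_ids: Sequence[str], reads_by_id: Mapping[str, SmallRNARead]
) -> tuple[float | None, float | None]:
    """(pct_1U, pct_10A) over one strand class of placed reads.

    Position 1/10 is counted on the read 5'->3'; reads shorter than
    10 nt are excluded from the 10A denominator. Empty classes give
    None (rendered NA).
    """
    if not read_ids:
        return None, None
    n1u = sum(1 for rid in read_ids if reads_by_id[rid].seq[0] == "T")
    long_enough = [rid for rid in read_ids if len(reads_by_id[rid]) >= 10]
    pct_1u = 100.0 * n1u / len(read_ids)
    if not long_enough:
        return pct_1u, None
    n10a = sum(1 for rid in long_enough if reads_by_id[rid].seq[9] == "A")
    return pct_1u, 100.0 * n10a / len(long_enough)


def build_count_table(
    fc: FeatureCounts,
    reads_by_id: Mapping[str, SmallRNARead],
    total_mappers: int,
    total_unique: int,
    subgroup_totals: Mapping[str, int],
) -> list[dict[str, object]]:
    """Assemble the per-feature table with counts, RPKM, per-million and bias.

    RPKM uses the total genome-mapper count for the all-mapper column
    and the genome-unique total for the unique column; the per-million
    columns normalize by the piRNA / miRNA / bonafide subgroup sizes.
    """
    rows = []
    for name in fc.features:
        sense = fc.sense_reads[name]
        anti = fc.antisense_reads[name]
        pct_1u_s, pct_10a_s = nucleotide_bias(sense, reads_by_id)
        pct_1u_a, pct_10a_a = nucleotide_bias(anti, reads_by_id)
        row: dict[str, object] = {
            "feature": name,
            "length": fc.feature_len[name],
            "count_all": fc.count_all[name],
            "count_unique": fc.count_unique[name],
            "rpkm_all": rpkm(fc.count_all[name], fc.feature_len[name], total_mappers)
            if total_mappers > 0 else None,
            "rpkm_unique": rpkm(fc.count_unique[name], fc.feature_len[name], total_unique)
            if total_unique > 0 else None,
        }
        for sub in ("piRNA", "miRNA", "bonafide"):
            row[f"per_million_{sub}"] = per_million(
                fc.count_all[name], subgroup_totals.get(sub, 0)
            )
        row.update(
            pct_1U_sense=pct_1u_s,
            pct_10A_sense=pct_10a_s,
            pct_1U_antisense=pct_1u_a,
            pct_10A_antisense=pct_10a_a,
        )
        rows.append(row)
    return rows


@dataclass
class MismatchStrata:
    """TE placements split by mismatch count: exact (0), all (0..k), imperfect (1..k)."""

    exact: list[AlignmentHit] = field(default_factory=list)
    all: list[AlignmentHit] = field(default_factory=list)
    imperfect: list[AlignmentHit] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[AlignmentHit]]:
        return {"exact": self.exact, "all": self.all, "imperfect": self.imperfect}


def stratify_te(placements: Iterable[AlignmentHit], k_max: int) -> MismatchStrata:
    """Partition placements into the three mismatch strata.

    Additivity holds by construction: exact + imperfect = all, per feature.
    """
    strata = MismatchStrata()
    for hit in placements:
        if hit.mismatches > k_max:
            raise ValueError(
                f"placement of {hit.read_id!r} has {hit.mismatches} mismatches "
                f"> k_max {k_max}"
            )
        strata.all.append(hit)
        if hit.mismatches == 0:
            strata.exact.append(hit)
        else:
            strata.imperfect.append(hit)
    return strata


def length_distribution(
    placements_per_read: Mapping[str, Sequence[AlignmentHit]] | None = None,
    reads: Sequence[SmallRNARead] | None = None,
    mapped_ids: set[str] | None = None,
) -> dict[int, int]:
    """Histogram of genome-mapping read lengths.

    Accepts either per-read genome hits (reads with >= 1 hit counted) or
    an explicit (reads, mapped_ids) pair.
    """
    hist: dict[int, int] = {}
    if placements_per_read is not None:
        for hits in placements_per_read.values():
            if hits:
                n = hits[0].read_len
                hist[n] = hist.get(n, 0) + 1
    elif reads is not None:
        for r in reads:
            if mapped_ids is None or r.read_id in mapped_ids:
                hist[len(r)] = hist.get(len(r), 0) + 1
    return dict(sorted(hist.items()))
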