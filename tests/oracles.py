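"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: alignment
by dense sliding-window Hamming scan (numpy), overlap spectra by
explicit enumeration of all opposite-strand read pairs.
"""

from __future__ import annotations

import numpy as np

from smallrna.io_formats import MINUS, PLUS, AlignmentHit, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def hamming_scan(
    read_id: str, read_seq: str, refs: dict[str, str], max_mm: int
) -> list[AlignmentHit]:
    """Every ungapped placement with <= max_mm mismatches, by dense scan.

    N (code 4) mismatches everything, including another N.
    """
    hits = []
    L = len(read_seq)
    for strand, query in ((PLUS, read_seq), (MINUS, revcomp(read_seq))):
        q = _encode(query)
        q_is_n = q == 4
        for ref_name, ref_seq in refs.items():
            if len(ref_seq) < L:
                continue
            r = _encode(ref_seq)
            windows = np.lib.stride_tricks.sliding_window_view(r, L)
            mm = ((windows != q) | q_is_n | (windows == 4)).sum(axis=1)
            for start in np.nonzero(mm <= max_mm)[0]:
                hits.append(
                    AlignmentHit(
                        ref_name=ref_name,
                        start=int(start),
                        strand=strand,
                        read_id=read_id,
                        mismatches=int(mm[start]),
                        read_len=L,
                    )
                )
    return sorted(hits)


def pair_enumeration_spectrum(
    plus_fives: list[int], minus_fives: list[int], S: int
) -> list[int]:
    """N_s for s=1..S by enumerating all ordered plus x minus 5'-end pairs."""
    counts = [0] * S
    for p in plus_fives:
        for q in minus_fives:
            s = q - p + 1
            if 1 <= s <= S:
                counts[s - 1] += 1
    return counts


def pair_scan_partners(
    plus_fives: dict[str, int], minus_fives: dict[str, int]
) -> tuple[set[str], set[str]]:
    """Read ids (per strand) having a 10-nt 5'-overlap partner, by pair scan."""
    sense_with = {
        rid
        for rid, p in plus_fives.items()
        if any(q - p + 1 == 10 for q in minus_fives.values())
    }
    anti_with = {
        rid
        for rid, q in minus_fives.items()
        if any(q - p + 1 == 10 for p in plus_fives.values())
    }
    return sense_with, anti_with
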