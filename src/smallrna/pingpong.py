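"""The piRNA ping-pong signature.

Secondary piRNA biogenesis (the ping-pong cycle) produces sense and
antisense piRNAs whose 5' ends overlap by exactly 10 nt. Given the
placements of the piRNA subgroup on one transposable element, the
5'-overlap spectrum counts, for every overlap size s = 1..S, the
ordered pairs of opposite-strand reads whose 5' ends span s overlapping
nucleotides:

    N_s = sum_p plus_profile[p] * minus_profile[p + s - 1]

where the profiles hold 5'-end depths per position (a plus-strand
read's 5' end is its start; a minus-strand read's is start + len - 1).
S defaults to the minimum piRNA read length (23), so a 10-nt overlap
sits well inside the evaluated spectrum.

The signature is scored by treating N_10 as an observation from the
spectrum: z = (N_10 - mu) / sigma with mu the spectrum mean and sigma
its population standard deviation (divisor S, all S counts including
N_10), and p the one-sided upper-tail normal probability 1 - Phi(z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import MINUS, PLUS, AlignmentHit

PINGPONG_OVERLAP = 10  # nt, the ping-pong duplex 5'-overlap


@dataclass(frozen=True)
class OverlapSpectrum:
    """Counts N_s of opposite-strand 5'-overlap pairs for s = 1..S."""

    counts: tuple[float, ...]

    @property
    def S(self) -> int:
        return len(self.counts)

    @property
    def overlap_sum(self) -> float:
        return float(sum(self.counts))

    @property
    def ten_sum(self) -> float:
        return float(self.counts[PINGPONG_OVERLAP - 1])


@dataclass(frozen=True)
class PingPongStats:
    """Summary statistics of one overlap spectrum.

    ``z`` and ``p`` are None when sigma = 0 (degenerate spectrum).
    """

    overlap_sum: float
    ten_sum: float
    mean: float
    sigma: float
    z: float | None
    p: float | None


def five_prime_profiles(
    placements: Iterable[AlignmentHit], feature_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position 5'-end depth on each strand of one feature."""
    plus = np.zeros(feature_len, dtype=float)
    minus = np.zeros(feature_len, dtype=float)
    for hit in placements:
        pos = hit.five_prime
        if 0 <= pos < feature_len:
            (plus if hit.strand == PLUS else minus)[pos] += 1
    return plus, minus


def overlap_spectrum(
    plus_profile: np.ndarray, minus_profile: np.ndarray, S: int
) -> OverlapSpectrum:
    """Spectrum of ordered opposite-strand 5'-overlap pair counts.

    A plus 5' end at p and a minus 5' end at q = p + s - 1 form an
    s-nt overlap (both 5' ends inside the duplex); only q >= p
    contributes. Pairs are counted with read multiplicity.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    plus = np.asarray(plus_profile, dtype=float)
    minus = np.asarray(minus_profile, dtype=float)
    if plus.shape != minus.shape:
        raise ValueError("strand profiles must cover the same feature length")
    L = plus.size
    counts = []
    for s in range(1, S + 1):
        shift = s - 1
        if shift >= L:
            counts.append(0.0)
        else:
            counts.append(float(np.dot(plus[: L - shift], minus[shift:])))
    return OverlapSpectrum(counts=tuple(counts))


def zscore(ten_sum: float, mean: float, sigma: float) -> float | None:
    """z of the 10-nt overlap count within the spectrum; None if sigma = 0."""
    if sigma == 0:
        return None
    return (ten_sum - mean) / sigma


def pvalue(z: float | None) -> float | None:
    """One-sided upper-tail standard normal probability 1 - Phi(z)."""
    if z is None:
        return None
    return float(norm.sf(z))


def pingpong_stats(spectrum: OverlapSpectrum) -> PingPongStats:
    """Score a spectrum: mean, population sigma, z of N_10, upper-tail p.

    sigma is the population standard deviation (divisor S) over all S
    counts including N_10 itself.
    """
    x = np.asarray(spectrum.counts, dtype=float)
    mean = float(x.sum()) / spectrum.S
    sigma = float(np.sqrt(((x - mean) ** 2).sum() / spectrum.S))
    z = zscore(spectrum.ten_sum, mean, sigma)
    return PingPongStats(
        overlap_sum=spectrum.overlap_sum,
        ten_sum=spectrum.ten_sum,
        mean=mean,
        sigma=sigma,
        z=z,
        p=pvalue(z),
    )


def overlap_histogram(spectrum: OverlapSpectrum) -> list[float | None]:
    """Percentage of overlap pairs at each size s; NA when the spectrum is empty."""
    total = spectrum.overlap_sum
    if total == 0:
        return [None] * spectrum.S
    return [100.0 * n / total for n in spectrum.counts]


@dataclass
class PartnerLists:
    """Read ids with/without a 10-nt 5'-overlap partner, per strand."""

    sense_with: list[str]
    sense_without: list[str]
    antisense_with: list[str]
    antisense_without: list[str]


def partner_lists(
    placements: Sequence[AlignmentHit], feature_len: int
) -> PartnerLists:
    """Split each strand's reads by presence of a ping-pong partner.

    A plus-strand read with 5' end at p has a partner iff some minus
    5' end sits at p + 9; symmetrically for minus reads at q and
    plus 5' ends at q - 9. Positions outside the feature count as
    empty.
    """
    plus_prof, minus_prof = five_prime_profiles(placements, feature_len)
    off = PINGPONG_OVERLAP - 1
    lists = PartnerLists([], [], [], [])
    for hit in placements:
        pos = hit.five_prime
        if hit.strand == PLUS:
            partnered = pos + off < feature_len and minus_prof[pos + off] > 0
            (lists.sense_with if partnered else lists.sense_without).append(hit.read_id)
        else:
            partnered = pos - off >= 0 and plus_prof[pos - off] > 0
            (lists.antisense_with if partnered else lists.antisense_without).append(hit.read_id)
    return lists


def pingpong_table(
    placements_by_feature: Mapping[str, Sequence[AlignmentHit]],
    feature_lengths: Mapping[str, int],
    S: int,
) -> list[dict[str, object]]:
    """Per-feature ping-pong statistics rows (all-zero spectra give NA stats)."""
    rows = []
    for name in feature_lengths:
        plus, minus = five_prime_profiles(
            placements_by_feature.get(name, ()), feature_lengths[name]
        )
        stats = pingpong_stats(overlap_spectrum(plus, minus, S))
        rows.append(
            {
                "ID": name,
                "overlap sum": stats.overlap_sum,
                "ten overlap sum": stats.ten_sum,
                "mean": stats.mean,
                "standard deviation": stats.sigma,
                "z-score": stats.z,
                "p-value": stats.p,
            }
        )
    return rows
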