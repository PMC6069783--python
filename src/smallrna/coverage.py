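"""Strand-specific coverage tracks and figure rendering.

Tracks accumulate either full read footprints (depth mode) or 5' ends
(five_prime mode) into fixed-width bins along a reference. Raw values
can be normalized per million mappers, or additionally by bin width in
kilobases (rpkm_binned) — the unit used for chromosome-scale profiles,
where per-base RPKM would be ill-defined.

Figures (genome profiles, TE density profiles, pie chart, length
histogram, overlap histogram) are rendered with matplotlib; every
figure's numeric series is also written as a TSV sidecar, which is the
testable surface — pixels are not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_formats import MINUS, PLUS, AlignmentHit, write_table

logger = logging.getLogger(__name__)

PLUS_COLOR = "tab:blue"   # plus strand drawn upward in blue
MINUS_COLOR = "tab:red"   # minus strand drawn downward in red


@dataclass
class CoverageTrack:
    """Binned strand-specific coverage along one reference sequence."""

    ref_name: str
    ref_len: int
    strand: str
    mode: str            # depth | five_prime
    bin_size: int
    normalization: str   # raw | per_million | rpkm_binned
    values: np.ndarray

    def intervals(self) -> Iterator[tuple[int, int, float]]:
        """Merged nonzero runs as (start, end, value), 0-based half-open."""
        i = 0
        n = self.values.size
        while i < n:
            v = self.values[i]
            j = i + 1
            while j < n and self.values[j] == v:
                j += 1
            if v != 0:
                start = i * self.bin_size
                end = min(j * self.bin_size, self.ref_len)
                yield start, end, float(v)
            i = j


def coverage_track(
    placements: Iterable[AlignmentHit],
    ref_name: str,
    ref_len: int,
    strand: str,
    mode: str = "depth",
    bin_size: int = 1,
    normalization: str = "raw",
    total_mappers: int | None = None,
) -> CoverageTrack:
    """Accumulate placements of one strand into a binned track.

    depth mode adds each read's full footprint; five_prime mode adds
    one count at the 5' end. per_million divides by mappers/1e6;
    rpkm_binned further divides by bin_size/1000.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = math.ceil(ref_len / bin_size)
    per_base = np.zeros(ref_len, dtype=float)
    for hit in placements:
        if hit.ref_name != ref_name or hit.strand != strand:
            continue
        if mode == "depth":
            per_base[hit.start : min(hit.end, ref_len)] += 1
        elif mode == "five_prime":
            pos = hit.five_prime
            if 0 <= pos < ref_len:
                per_base[pos] += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if bin_size == 1:
        values = per_base
    else:
        pad = n_bins * bin_size - ref_len
        values = np.pad(per_base, (0, pad)).reshape(n_bins, bin_size).sum(axis=1)
    if normalization != "raw":
        if not total_mappers or total_mappers <= 0:
            raise ValueError("normalization requires a positive total_mappers")
        values = values / (total_mappers / 1e6)
        if normalization == "rpkm_binned":
            values = values / (bin_size / 1000.0)
        elif normalization != "per_million":
            raise ValueError(f"unknown normalization {normalization!r}")
    return CoverageTrack(
        ref_name=ref_name,
        ref_len=ref_len,
        strand=strand,
        mode=mode,
        bin_size=bin_size,
        normalization=normalization,
        values=values,
    )


def _write_sidecar(path: Path, columns: Mapping[str, Sequence]) -> None:
    names = list(columns)
    rows = [
        {name: columns[name][i] for name in names}
        for i in range(len(columns[names[0]]))
    ]
    write_table(rows, path, columns=names)


def plot_strand_profile(
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    out_png: Path,
    title: str,
    ylabel: str,
) -> None:
    """Two-strand profile: plus upward in blue, minus downward in red."""
    x = np.arange(plus_track.values.size) * plus_track.bin_size
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(x, plus_track.values, color=PLUS_COLOR, step="post", label="plus")
    ax.fill_between(x, -minus_track.values, color=MINUS_COLOR, step="post", label="minus")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel(f"position on {plus_track.ref_name} (nt)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    _write_sidecar(
        out_png.with_suffix(".tsv"),
        {
            "bin_start": [int(v) for v in x],
            "plus": list(plus_track.values),
            "minus": list(minus_track.values),
        },
    )


def plot_pie(fractions: Mapping[str, float], out_png: Path) -> None:
    """Category pie of genome-mapping reads, with a TSV sidecar."""
    labels = [k for k, v in fractions.items() if v > 0]
    sizes = [fractions[k] for k in labels]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if sizes:
        ax.pie(sizes, labels=labels, autopct="%1.0f%%")
    ax.set_title("genome-mapping reads by category")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    _write_sidecar(
        out_png.with_suffix(".tsv"),
        {"category": list(fractions), "percent": [fractions[k] for k in fractions]},
    )


def plot_length_histogram(hist: Mapping[int, int], out_png: Path) -> None:
    """Mapped-read length distribution, with a TSV sidecar."""
    lengths = sorted(hist)
    counts = [hist[n] for n in lengths]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(lengths, counts, color="grey")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("mapped reads")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    _write_sidecar(out_png.with_suffix(".tsv"), {"length": lengths, "count": counts})


def plot_overlap_histogram(
    percentages: Sequence[float | None], out_png: Path
) -> None:
    """Percentage of 5'-overlap pairs per overlap size, with a TSV sidecar."""
    sizes = list(range(1, len(percentages) + 1))
    vals = [0.0 if p is None else p for p in percentages]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(sizes, vals, color="tab:purple")
    ax.set_xlabel("5'-overlap size (nt)")
    ax.set_ylabel("% of overlap pairs")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    _write_sidecar(
        out_png.with_suffix(".tsv"),
        {"overlap": sizes, "percent": list(percentages)},
    )
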