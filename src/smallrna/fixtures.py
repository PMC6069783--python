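"""Deterministic synthetic small RNA-seq data with a ground-truth manifest.

The generator emulates a single-end small RNA library over a small
genome: category sequences (TEs, transcripts, miRNAs, rRNAs, tRNAs,
snRNAs) are random sequences embedded verbatim in random background
contigs, so every category read is simultaneously a perfect genome
mapper. Reads are drawn per category with a planted composition, a
bimodal length structure (22-nt miRNAs, 21-nt siRNAs, 23-29-nt
piRNAs), planted ping-pong pairs (a plus-strand read with its 5' end
at p paired with a minus-strand read whose 5' end is at p + 9), and
1U/10A nucleotide bias.

Bias is planted by rejection-sampling read start positions conditional
on the desired base (with probability ``bias_1U`` the sense read must
start with T, otherwise it must not; 10A analogously on antisense
reads), so reads stay perfect genome matches. For a planted ping-pong
pair the sense 1U and antisense 10A conditions are the same genomic
base, so pairs take a single bias draw — mirroring the biological
coupling of the two signatures.

Every generated read is verified against all other category references
(at the categorization mismatch bound) and rejected on a collision, so
the planted classification is unambiguous and the manifest is an exact
oracle for the cascade. Noise reads are verified unmappable to the
genome. Identical parameters yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import aligner
from .cascade import PipelineParams
from .io_formats import (
    MINUS,
    PLUS,
    ReferenceSet,
    SmallRNARead,
    revcomp,
    write_fasta,
    write_fastq,
)

BASES = np.array(list("ACGT"))

DEFAULT_COMPOSITION = {
    "TE": 0.40,
    "miRNA": 0.24,
    "rRNA": 0.08,
    "tRNA": 0.05,
    "snRNA": 0.02,
    "transcript": 0.06,
    "other": 0.10,
}  # remainder (0.05) = unmappable noise reads

CATEGORY_FILES = {
    "TE": "te.fa",
    "transcript": "transcripts.fa",
    "miRNA": "mirna.fa",
    "rRNA": "rrna.fa",
    "tRNA": "trna.fa",
    "snRNA": "snrna.fa",
}


@dataclass
class FixtureParams:
    """Knobs of the synthetic library and its reference landscape."""

    seed: int = 0
    n_reads: int = 2000
    n_contigs: int = 3
    spacer_len: int = 300
    n_te: int = 4
    te_len: tuple[int, int] = (600, 1000)
    n_transcript: int = 4
    transcript_len: tuple[int, int] = (400, 800)
    n_mirna: int = 5
    mirna_len: int = 22
    n_rrna: int = 2
    rrna_len: tuple[int, int] = (120, 180)
    n_trna: int = 3
    trna_len: tuple[int, int] = (70, 90)
    n_snrna: int = 2
    snrna_len: tuple[int, int] = (100, 150)
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    pingpong_fraction: float = 0.5
    te_sirna_fraction: float = 0.25
    bias_1U: float = 0.8
    bias_10A: float = 0.8
    min_len: int = 18
    max_len: int = 29
    pirna_len_min: int = 23
    pirna_len_max: int = 29
    sirna_len: int = 21
    te_mm: int = 3
    genome_mm: int = 0
    duplicate_te: bool = False  # embed the first TE twice -> multi-mappers

    def __post_init__(self):
        total = sum(self.composition.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"composition sums to {total} > 1")
        if not all(0.0 <= v <= 1.0 for v in self.composition.values()):
            raise ValueError("composition fractions must be in [0, 1]")


@dataclass
class ReadRecord:
    """Ground truth for one emitted read."""

    read_id: str
    category: str          # TE/transcript/miRNA/rRNA/tRNA/snRNA/other/noise
    feature: str | None    # source feature name (None for other/noise)
    strand: str | None     # orientation relative to the source feature
    length: int
    feature_start: int | None  # leftmost position on the feature (local)
    pair_id: int | None    # planted ping-pong pair id, if any
    base1: str
    base10: str | None


@dataclass
class TruthManifest:
    """Everything downstream stages should recover from the fixture."""

    params: FixtureParams
    records: list[ReadRecord]

    def reads_of(self, category: str) -> list[ReadRecord]:
        return [r for r in self.records if r.category == category]

    def expected_category_counts(self) -> dict[str, int]:
        """Exclusive cascade category counts over genome-mapping reads."""
        counts: dict[str, int] = {}
        for r in self.records:
            if r.category == "noise":
                continue
            counts[r.category] = counts.get(r.category, 0) + 1
        return counts

    @property
    def n_genome_mappers(self) -> int:
        return sum(1 for r in self.records if r.category != "noise")

    def expected_subgroup_sizes(self) -> dict[str, int]:
        p = self.params
        sizes = {"bonafide": 0, "miRNA": 0, "siRNA": 0, "piRNA": 0}
        for r in self.records:
            if r.category == "noise":
                continue
            if r.category == "miRNA":
                sizes["miRNA"] += 1
            if r.category in ("miRNA", "rRNA", "tRNA", "snRNA"):
                continue
            sizes["bonafide"] += 1
            if r.length == p.sirna_len:
                sizes["siRNA"] += 1
            if p.pirna_len_min <= r.length <= p.pirna_len_max:
                sizes["piRNA"] += 1
        return sizes

    def te_pirna_placements(self) -> dict[str, list[tuple[str, int, int]]]:
        """Per-TE (strand, local start, length) of piRNA-window TE reads."""
        p = self.params
        out: dict[str, list[tuple[str, int, int]]] = {}
        for r in self.records:
            if r.category != "TE":
                continue
            if not (p.pirna_len_min <= r.length <= p.pirna_len_max):
                continue
            out.setdefault(r.feature, []).append(
                (r.strand, r.feature_start, r.length)
            )
        return out

    def planted_pair_counts(self) -> dict[str, int]:
        """Number of planted ping-pong pairs per TE."""
        pairs: dict[str, set[int]] = {}
        for r in self.records:
            if r.pair_id is not None:
                pairs.setdefault(r.feature, set()).add(r.pair_id)
        return {te: len(ids) for te, ids in pairs.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": asdict(self.params),
                "records": [asdict(r) for r in self.records],
            },
            indent=1,
        )


@dataclass
class Fixture:
    """In-memory synthetic dataset: references, reads, truth."""

    genome: ReferenceSet
    category_refs: dict[str, ReferenceSet]
    feature_location: dict[str, tuple[str, int]]  # feature -> (contig, offset)
    reads: list[SmallRNARead]
    manifest: TruthManifest


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def simulate_references(params: FixtureParams) -> tuple[
    ReferenceSet, dict[str, ReferenceSet], dict[str, tuple[str, int]]
]:
    """Generate category references and a genome embedding them verbatim."""
    rng = np.random.default_rng(params.seed)
    specs = [
        ("TE", params.n_te, params.te_len),
        ("transcript", params.n_transcript, params.transcript_len),
        ("miRNA", params.n_mirna, (params.mirna_len, params.mirna_len)),
        ("rRNA", params.n_rrna, params.rrna_len),
        ("tRNA", params.n_trna, params.trna_len),
        ("snRNA", params.n_snrna, params.snrna_len),
    ]
    category_refs: dict[str, ReferenceSet] = {}
    features: list[tuple[str, str]] = []  # (name, seq) in embedding order
    for cat, n, (lo, hi) in specs:
        refs = ReferenceSet(category=cat)
        for i in range(n):
            name = f"{cat}_{i + 1}"
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            refs.add(name, seq)
            features.append((name, seq))
        category_refs[cat] = refs
    if params.duplicate_te and params.n_te > 0:
        name, seq = features[0]
        features.append((name + "__copy", seq))

    contigs = [[f"chr{i + 1}", []] for i in range(params.n_contigs)]
    feature_location: dict[str, tuple[str, int]] = {}
    offsets = [0] * params.n_contigs
    for i, (name, seq) in enumerate(features):
        c = i % params.n_contigs
        spacer = _random_seq(rng, params.spacer_len)
        contigs[c][1].append(spacer)
        offsets[c] += params.spacer_len
        contigs[c][1].append(seq)
        feature_location[name] = (contigs[c][0], offsets[c])
        offsets[c] += len(seq)
    genome = ReferenceSet(category="genome")
    for c, (cname, parts) in enumerate(contigs):
        parts.append(_random_seq(rng, params.spacer_len))
        genome.add(cname, "".join(parts))
    return genome, category_refs, feature_location


def _sample_start(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    want_base: str | None,
    base_at,
    invert: bool,
    tries: int = 200,
) -> int:
    """Uniform start in [lo, hi] conditioned on a base; fall back unconstrained."""
    if hi < lo:
        raise ValueError("infeasible start window")
    if want_base is None:
        return int(rng.integers(lo, hi + 1))
    for _ in range(tries):
        s = int(rng.integers(lo, hi + 1))
        hit = base_at(s) == want_base
        if hit != invert:
            return s
    return int(rng.integers(lo, hi + 1))


def _allocate(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n reads to fractions (exact totals)."""
    raw = {k: n * v for k, v in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_reads(
    params: FixtureParams,
    genome: ReferenceSet,
    category_refs: Mapping[str, ReferenceSet],
) -> tuple[list[SmallRNARead], TruthManifest]:
    """Draw the planted read population and its ground-truth manifest."""
    rng = np.random.default_rng(params.seed + 1)
    genome_index = aligner.build_index(genome, seed_len=10)
    cat_indexes = {
        cat: aligner.build_index(refs, seed_len=10)
        for cat, refs in category_refs.items()
        if len(refs) > 0
    }

    comp = dict(params.composition)
    noise_frac = max(0.0, 1.0 - sum(comp.values()))
    comp["noise"] = noise_frac
    counts = _allocate(params.n_reads, comp)

    reads: list[SmallRNARead] = []
    records: list[ReadRecord] = []
    serial = 0

    def emit(seq: str, category: str, feature: str | None, strand: str | None,
             start: int | None, pair_id: int | None) -> None:
        nonlocal serial
        serial += 1
        rid = f"r{serial:06d}"
        reads.append(SmallRNARead(rid, seq, "I" * len(seq)))
        records.append(
            ReadRecord(
                read_id=rid,
                category=category,
                feature=feature,
                strand=strand,
                length=len(seq),
                feature_start=start,
                pair_id=pair_id,
                base1=seq[0],
                base10=seq[9] if len(seq) >= 10 else None,
            )
        )

    def unambiguous(seq: str, own_cat: str | None, own_feature: str | None = None) -> bool:
        """True iff the read matches only its own feature, in its own category."""
        probe = SmallRNARead("probe", seq, "I" * len(seq))
        for cat, idx in cat_indexes.items():
            hits = aligner.align(probe, idx, params.te_mm)
            if cat == own_cat:
                if any(h.ref_name != own_feature for h in hits):
                    return False
            elif hits:
                return False
        return True

    def draw_window(cat: str, n_wanted: int, sense_only: bool):
        """Fragment reads from a category's features, bias-free."""
        refs = category_refs[cat]
        names = refs.names
        made = 0
        while made < n_wanted:
            name = names[int(rng.integers(len(names)))]
            seq = refs.sequences[name]
            length = int(rng.integers(params.min_len, params.max_len + 1))
            length = min(length, len(seq))
            start = int(rng.integers(0, len(seq) - length + 1))
            strand = PLUS if sense_only or rng.random() < 0.5 else MINUS
            window = seq[start : start + length]
            read_seq = window if strand == PLUS else revcomp(window)
            if not unambiguous(read_seq, cat, name):
                continue
            emit(read_seq, cat, name, strand, start, None)
            made += 1

    # --- miRNA: each read is a full-length 22-nt miRNA, sense ---
    mirna_names = category_refs["miRNA"].names
    made = 0
    while made < counts.get("miRNA", 0):
        name = mirna_names[int(rng.integers(len(mirna_names)))]
        seq = category_refs["miRNA"].sequences[name]
        if not unambiguous(seq, "miRNA", name):
            continue
        emit(seq, "miRNA", name, PLUS, 0, None)
        made += 1

    # --- structural RNAs and transcripts: plain fragments ---
    draw_window("rRNA", counts.get("rRNA", 0), sense_only=False)
    draw_window("tRNA", counts.get("tRNA", 0), sense_only=False)
    draw_window("snRNA", counts.get("snRNA", 0), sense_only=False)
    draw_window("transcript", counts.get("transcript", 0), sense_only=True)

    # --- TE reads: siRNA-length + piRNA-length with planted ping-pong ---
    n_te_reads = counts.get("TE", 0)
    n_sirna = int(round(params.te_sirna_fraction * n_te_reads))
    n_pirna = n_te_reads - n_sirna
    n_pairs = int(params.pingpong_fraction * n_pirna / 2)
    n_single_pi = n_pirna - 2 * n_pairs
    te_refs = category_refs["TE"]
    te_names = te_refs.names
    pair_serial = 0

    def biased_te_start(seq: str, lo: int, hi: int, bias: float, base: str) -> int:
        biased = rng.random() < bias
        return _sample_start(
            rng, lo, hi, base, lambda s: seq[s], invert=not biased
        )

    made = 0
    while made < n_pairs:
        name = te_names[int(rng.integers(len(te_names)))]
        seq = te_refs.sequences[name]
        L1 = int(rng.integers(params.pirna_len_min, params.pirna_len_max + 1))
        L2 = int(rng.integers(params.pirna_len_min, params.pirna_len_max + 1))
        lo = max(0, L2 - 10)
        hi = min(len(seq) - L1, len(seq) - 10)
        if hi < lo:
            continue
        # sense 1U and antisense 10A both require seq[p] == 'T': one draw
        p = biased_te_start(seq, lo, hi, params.bias_1U, "T")
        plus_seq = seq[p : p + L1]
        q = p + 9  # 5' end of the minus partner: exactly 10-nt overlap
        minus_window = seq[q - L2 + 1 : q + 1]
        minus_seq = revcomp(minus_window)
        if not (unambiguous(plus_seq, "TE", name) and unambiguous(minus_seq, "TE", name)):
            continue
        pair_serial += 1
        emit(plus_seq, "TE", name, PLUS, p, pair_serial)
        emit(minus_seq, "TE", name, MINUS, q - L2 + 1, pair_serial)
        made += 1

    def te_single(n_wanted: int, length_of) -> None:
        made = 0
        while made < n_wanted:
            name = te_names[int(rng.integers(len(te_names)))]
            seq = te_refs.sequences[name]
            L = length_of()
            if len(seq) < L:
                continue
            strand = PLUS if rng.random() < 0.5 else MINUS
            if strand == PLUS:
                # 1U: read[0] == T  <=>  seq[start] == T
                s = biased_te_start(seq, 0, len(seq) - L, params.bias_1U, "T")
                read_seq = seq[s : s + L]
            else:
                # 10A: read[9] == A  <=>  seq[s + L - 10] == T
                biased = rng.random() < params.bias_10A
                s = _sample_start(
                    rng, 0, len(seq) - L, "T",
                    lambda s: seq[s + L - 10], invert=not biased,
                )
                read_seq = revcomp(seq[s : s + L])
            if not unambiguous(read_seq, "TE", name):
                continue
            emit(read_seq, "TE", name, strand, s, None)
            made += 1

    te_single(
        n_single_pi,
        lambda: int(rng.integers(params.pirna_len_min, params.pirna_len_max + 1)),
    )
    te_single(n_sirna, lambda: params.sirna_len)

    # --- other: genome background windows matching no category ---
    contig_names = genome.names
    made = 0
    while made < counts.get("other", 0):
        cname = contig_names[int(rng.integers(len(contig_names)))]
        seq = genome.sequences[cname]
        L = int(rng.integers(params.min_len, params.max_len + 1))
        s = int(rng.integers(0, len(seq) - L + 1))
        read_seq = seq[s : s + L]
        if "N" in read_seq or not unambiguous(read_seq, None):
            continue
        emit(read_seq, "other", None, None, None, None)
        made += 1

    # --- noise: verified unmappable to the genome ---
    made = 0
    while made < counts.get("noise", 0):
        L = int(rng.integers(params.min_len, params.max_len + 1))
        seq = _random_seq(rng, L)
        probe = SmallRNARead("probe", seq, "I" * L)
        if aligner.align(probe, genome_index, params.genome_mm):
            continue
        emit(seq, "noise", None, None, None, None)
        made += 1

    return reads, TruthManifest(params=params, records=records)


def simulate(params: FixtureParams) -> Fixture:
    """Generate the full fixture (references + reads + manifest)."""
    genome, category_refs, feature_location = simulate_references(params)
    reads, manifest = simulate_reads(params, genome, category_refs)
    return Fixture(
        genome=genome,
        category_refs=category_refs,
        feature_location=feature_location,
        reads=reads,
        manifest=manifest,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA references, FASTQ reads and the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fa", "reads": outdir / "reads.fastq",
             "manifest": outdir / "manifest.json"}
    write_fasta(fixture.genome, paths["genome"])
    for cat, fname in CATEGORY_FILES.items():
        paths[cat] = outdir / fname
        write_fasta(fixture.category_refs[cat], paths[cat])
    write_fastq(fixture.reads, paths["reads"])
    paths["manifest"].write_text(fixture.manifest.to_json())
    return paths
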