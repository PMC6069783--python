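"""End-to-end pipeline: length filter -> genome alignment -> category
cascade -> subgroups -> quantification -> ping-pong -> coverage/figures.

All randomness (multi-mapper placement) flows from the single policy
seed, so two runs with identical configuration produce identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import aligner, cascade, coverage, pingpong, quantify
from .aligner import PlacementPolicy
from .cascade import PipelineParams
from .io_formats import (
    MINUS,
    PLUS,
    ReferenceSet,
    SmallRNARead,
    export_alignments,
    read_fasta,
    read_fastq,
    write_bedgraph,
    write_fastq,
    write_table,
)

logger = logging.getLogger(__name__)

SUBGROUPS = ("bonafide", "miRNA", "siRNA", "piRNA")

PP_COLUMNS = ["ID", "overlap sum", "ten overlap sum", "mean",
              "standard deviation", "z-score", "p-value"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    fastq: list[Path]
    genome: Path
    te: Path
    transcripts: Path
    mirna: Path
    rrna: Path | None = None
    trna: Path | None = None
    snrna: Path | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    policy: PlacementPolicy = field(default_factory=PlacementPolicy)
    outdir: Path = Path("smallrna_out")
    chrom_bin: int = 1000
    render: bool = True

    def provenance(self) -> dict:
        d = {
            "fastq": [str(p) for p in self.fastq],
            "genome": str(self.genome),
            "te": str(self.te),
            "transcripts": str(self.transcripts),
            "mirna": str(self.mirna),
            "rrna": str(self.rrna) if self.rrna else None,
            "trna": str(self.trna) if self.trna else None,
            "snrna": str(self.snrna) if self.snrna else None,
            "params": dataclasses.asdict(self.params),
            "placement": dataclasses.asdict(self.policy),
            "chrom_bin": self.chrom_bin,
        }
        return d


@dataclass
class LibraryResult:
    """Numeric results of one library, plus the paths written for it."""

    name: str
    outdir: Path
    n_input: int
    n_filtered: int
    n_genome_mappers: int
    n_genome_unique: int
    length_dist: dict[int, int]
    pie: dict[str, float]
    assignment: cascade.CategoryAssignment
    subgroups: cascade.Subgroups
    pingpong_rows: list[dict[str, object]]
    files: list[Path] = field(default_factory=list)


@dataclass
class ReportBundle:
    """All per-library results of a run plus provenance."""

    config: RunConfig
    libraries: list[LibraryResult]

    def summary(self) -> dict:
        return {
            "provenance": self.config.provenance(),
            "libraries": {
                lib.name: {
                    "input_reads": lib.n_input,
                    "length_filtered": lib.n_filtered,
                    "genome_mappers": lib.n_genome_mappers,
                    "genome_unique": lib.n_genome_unique,
                    "pie_percent": lib.pie,
                    "subgroup_sizes": lib.subgroups.sizes(),
                }
                for lib in self.libraries
            },
        }


def load_references(config: RunConfig) -> tuple[ReferenceSet, dict[str, ReferenceSet]]:
    genome = read_fasta(config.genome, "genome")
    category_refs = {
        "TE": read_fasta(config.te, "TE"),
        "transcript": read_fasta(config.transcripts, "transcript"),
        "miRNA": read_fasta(config.mirna, "miRNA"),
    }
    for cat, path in (("rRNA", config.rrna), ("tRNA", config.trna),
                      ("snRNA", config.snrna)):
        if path is not None:
            category_refs[cat] = read_fasta(path, cat)
    return genome, category_refs


def _write_count_tables(
    outdir: Path,
    prefix: str,
    placements,
    uniqueness,
    refs: ReferenceSet,
    reads_by_id,
    totals,
    subgroup_totals,
    files: list[Path],
) -> None:
    fc = quantify.count_features(placements, uniqueness, refs)
    rows = quantify.build_count_table(
        fc, reads_by_id, totals["all"], totals["unique"], subgroup_totals
    )
    path = outdir / f"{prefix}_counts.tsv"
    write_table(rows, path)
    files.append(path)


def analyse_library(
    name: str,
    reads: list[SmallRNARead],
    genome: ReferenceSet,
    category_refs: dict[str, ReferenceSet],
    config: RunConfig,
) -> LibraryResult:
    """Run every stage on one library and write its output folder."""
    params = config.params
    policy = config.policy
    outdir = Path(config.outdir) / name
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    logger.info("[%s] length selection %d-%d nt", name, params.min_len, params.max_len)
    filtered = cascade.filter_by_length(reads, params.min_len, params.max_len)
    reads_by_id = {r.read_id: r for r in filtered}

    logger.info("[%s] genome alignment (max %d mm)", name, params.genome_mm)
    genome_index = aligner.build_index(genome, params.seed_len)
    genome_hits = aligner.align_all(filtered, genome_index, params.genome_mm)
    flags = aligner.classify_uniqueness(genome_hits)
    mappers = [r for r in filtered if flags[r.read_id] != aligner.UNMAPPED]
    n_unique = sum(1 for r in mappers if flags[r.read_id] == aligner.UNIQUE)
    genome_placed = aligner.place_reads(genome_hits, policy)

    logger.info("[%s] category cascade: %s", name, " -> ".join(params.category_order))
    assignment = cascade.categorize(mappers, category_refs, params, flags)
    subgroups = cascade.extract_subgroups(assignment, reads_by_id, params)
    pie = cascade.pie_fractions(assignment) if mappers else {}
    length_dist = quantify.length_distribution(
        {rid: h for rid, h in genome_hits.items() if h}
    )
    subgroup_totals = {
        "piRNA": len(subgroups.pirna),
        "miRNA": len(subgroups.mirna),
        "bonafide": len(subgroups.bonafide),
    }
    totals = {"all": len(mappers), "unique": n_unique}
    subgroup_ids = {
        "bonafide": subgroups.bonafide,
        "miRNA": subgroups.mirna,
        "siRNA": subgroups.sirna,
        "piRNA": subgroups.pirna,
    }

    te_refs = category_refs["TE"]
    tx_refs = category_refs["transcript"]
    te_index = aligner.build_index(te_refs, params.seed_len)
    tx_index = aligner.build_index(tx_refs, params.seed_len)

    pirna_te_placements: dict[str, list] = {}

    for sub in SUBGROUPS:
        ids = subgroup_ids[sub]
        sub_dir = outdir / sub
        sub_dir.mkdir(exist_ok=True)
        sub_reads = [reads_by_id[i] for i in sorted(ids)]
        sub_genome_placed = [h for h in genome_placed if h.read_id in ids]

        # genome folder: SAM, strand bedgraphs (all + unique), count table
        gdir = sub_dir / "genome"
        gdir.mkdir(exist_ok=True)
        sam_path = gdir / "all_mappers.sam"
        export_alignments(sub_genome_placed, reads_by_id, genome, sam_path)
        files.append(sam_path)
        uniq_placed = [
            h for h in sub_genome_placed if flags[h.read_id] == aligner.UNIQUE
        ]
        sam_path = gdir / "unique_mappers.sam"
        export_alignments(uniq_placed, reads_by_id, genome, sam_path)
        files.append(sam_path)
        for variant, placed in (("all", sub_genome_placed), ("unique", uniq_placed)):
            for strand, tag in ((PLUS, "plus"), (MINUS, "minus")):
                for cname, clen in genome.lengths.items():
                    track = coverage.coverage_track(
                        placed, cname, clen, strand, mode="depth", bin_size=1
                    )
                    path = gdir / f"{cname}_{variant}_{tag}.bedgraph"
                    write_bedgraph(track, path)
                    files.append(path)
        _write_count_tables(
            gdir, "genome", sub_genome_placed, flags, genome,
            reads_by_id, totals, subgroup_totals, files,
        )

        # TE and transcript folders: parallel (non-exclusive) mapping
        te_hits = aligner.align_all(sub_reads, te_index, params.te_mm)
        te_placed = aligner.place_reads(te_hits, policy)
        tdir = sub_dir / "TE"
        tdir.mkdir(exist_ok=True)
        strata = quantify.stratify_te(te_placed, params.te_mm)
        for stratum, placed in strata.as_dict().items():
            _write_count_tables(
                tdir, f"te_{stratum}", placed, flags, te_refs,
                reads_by_id, totals, subgroup_totals, files,
            )
        xdir = sub_dir / "transcripts"
        xdir.mkdir(exist_ok=True)
        tx_hits = aligner.align_all(sub_reads, tx_index, params.te_mm)
        tx_placed = aligner.place_reads(tx_hits, policy)
        _write_count_tables(
            xdir, "transcripts", tx_placed, flags, tx_refs,
            reads_by_id, totals, subgroup_totals, files,
        )

        if sub == "piRNA":
            for h in te_placed:
                pirna_te_placements.setdefault(h.ref_name, []).append(h)

        if config.render:
            for cname, clen in genome.lengths.items():
                for variant, placed in (("all", sub_genome_placed), ("unique", uniq_placed)):
                    tracks = [
                        coverage.coverage_track(
                            placed, cname, clen, strand, mode="depth",
                            bin_size=config.chrom_bin,
                            normalization="rpkm_binned",
                            total_mappers=totals[variant] or 1,
                        )
                        for strand in (PLUS, MINUS)
                    ]
                    png = gdir / f"{cname}_{variant}_profile.png"
                    coverage.plot_strand_profile(
                        tracks[0], tracks[1], png,
                        f"{sub} on {cname} ({variant} mappers)", "RPKM",
                    )
                    files.extend([png, png.with_suffix(".tsv")])

    # ping-pong signature on piRNA-subgroup TE placements
    ppdir = outdir / "pingpong"
    ppdir.mkdir(exist_ok=True)
    S = params.pirna_len_min
    pp_rows = pingpong.pingpong_table(
        pirna_te_placements, te_refs.lengths, S
    )
    pp_path = ppdir / "pingpong_stats.tsv"
    write_table(pp_rows, pp_path, columns=PP_COLUMNS)
    files.append(pp_path)
    for te_name, te_len in te_refs.lengths.items():
        placed = pirna_te_placements.get(te_name, [])
        plus_prof, minus_prof = pingpong.five_prime_profiles(placed, te_len)
        spectrum = pingpong.overlap_spectrum(plus_prof, minus_prof, S)
        hist = pingpong.overlap_histogram(spectrum)
        hist_path = ppdir / f"{te_name}_overlap_histogram.tsv"
        write_table(
            [{"overlap": s + 1, "count": spectrum.counts[s], "percent": hist[s]}
             for s in range(S)],
            hist_path,
        )
        files.append(hist_path)
        lists = pingpong.partner_lists(placed, te_len)
        for tag, ids in (
            ("sense_with_partner", lists.sense_with),
            ("sense_without_partner", lists.sense_without),
            ("antisense_with_partner", lists.antisense_with),
            ("antisense_without_partner", lists.antisense_without),
        ):
            path = ppdir / f"{te_name}_{tag}.fastq"
            write_fastq((reads_by_id[i] for i in ids), path)
            files.append(path)
        if config.render:
            png = ppdir / f"{te_name}_overlap_histogram.png"
            coverage.plot_overlap_histogram(hist, png)
            files.extend([png, png.with_suffix(".tsv")])
            te_tracks = [
                coverage.coverage_track(
                    placed, te_name, te_len, strand, mode="depth", bin_size=1
                )
                for strand in (PLUS, MINUS)
            ]
            png = ppdir / f"{te_name}_density.png"
            coverage.plot_strand_profile(
                te_tracks[0], te_tracks[1], png,
                f"piRNA density on {te_name}", "reads",
            )
            files.extend([png, png.with_suffix(".tsv")])

    if config.render and mappers:
        png = outdir / "pie.png"
        coverage.plot_pie(pie, png)
        files.extend([png, png.with_suffix(".tsv")])
        png = outdir / "length_distribution.png"
        coverage.plot_length_histogram(length_dist, png)
        files.extend([png, png.with_suffix(".tsv")])
    ld_path = outdir / "length_distribution.tsv"
    write_table(
        [{"length": k, "count": v} for k, v in length_dist.items()], ld_path
    )
    files.append(ld_path)

    return LibraryResult(
        name=name,
        outdir=outdir,
        n_input=len(reads),
        n_filtered=len(filtered),
        n_genome_mappers=len(mappers),
        n_genome_unique=n_unique,
        length_dist=length_dist,
        pie=pie,
        assignment=assignment,
        subgroups=subgroups,
        pingpong_rows=pp_rows,
        files=files,
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every library of the configuration with identical parameters."""
    genome, category_refs = load_references(config)
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    libraries = []
    for fastq_path in config.fastq:
        name = Path(fastq_path).stem
        logger.info("processing library %s", name)
        reads = read_fastq(fastq_path)
        libraries.append(
            analyse_library(name, reads, genome, category_refs, config)
        )
    bundle = ReportBundle(config=config, libraries=libraries)
    (Path(config.outdir) / "summary.json").write_text(
        json.dumps(bundle.summary(), indent=1)
    )
    return bundle
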