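# Methods

## Alignment model

Reads are placed on references by an exhaustive ungapped matcher:
every placement on either strand with at most `max_mm` substitutions
is reported. Completeness follows from pigeonhole seeding — the read
is partitioned into `max_mm + 1` non-overlapping chunks, so any
placement within the bound leaves at least one chunk matching the
reference exactly; exact chunk occurrences are found through a 10-mer
hash index (or, when chunks are shorter than 10 nt, by direct
substring scanning) and candidates are verified by full Hamming
comparison. `N` never matches any base, in read or reference. Indels
are outside the model: small RNA reads are short (18–32 nt) and the
pipeline's questions — category membership, 5′-end positions,
mismatch strata — are substitution-level. A SAM import path accepts
placements from any external aligner instead; records with indels or
clipping are skipped with a warning.

Multi-mapping reads (several genomic placements within the bound) are
reported, by default, at one placement drawn uniformly among their
minimum-mismatch hits with a seeded generator, candidate hits being
pre-sorted by (reference, start, strand) so runs are reproducible
across platforms. `all` mode keeps every placement and is used for
exhaustive TE density profiles. Default mismatch bounds: 0 to the
genome, 3 to TEs/transcripts and the other category references; both
are configurable. The genome bound chooses stringency of "genome
mapper"; the TE bound admits reads from diverged TE copies.

## Category cascade and subgroups

Only genome-mapping reads enter categorization. Each read's sequence
is aligned against the category references in a configurable order,
default rRNA → miRNA → tRNA → snRNA → transcript → TE, and the read is
assigned to the first category that accepts it; unmatched reads are
"other". The structural classes act as contamination filters: the
*bonafide* subgroup is the genome mappers minus rRNA/miRNA/tRNA/snRNA
matches, and the siRNA (21 nt) and piRNA (23–29 nt) subgroups are
length windows within bonafide. The relative order of transcript vs
TE matters only for reads matching both; it is a knob because
biological priority between the two is not canonical. Category
assignment is exclusive (it feeds the pie chart); subgroup
quantification against TEs and transcripts is, by contrast,
non-exclusive — each subgroup is mapped to both reference sets in
parallel.

## Normalization

RPKM = count / ((feature length / 1000) × (total mappers / 10⁶)), with
total genome mappers as the denominator for all-mapper tables and
total genome-unique mappers for unique tables. The per-million columns
divide by the piRNA / miRNA / bonafide subgroup sizes instead, and are
reported as NA when a subgroup is empty. 1U/10A percentages are
computed on the read in its own 5′→3′ orientation, per feature and
per strand class (sense = read on the feature's plus strand); reads
shorter than 10 nt (impossible under default length selection) are
excluded from the 10A denominator.

## Ping-pong statistic

For the piRNA subgroup's placements on one TE (mismatches 0..k), the
5′-end depth profiles per strand are multiplied to give the overlap
spectrum: N_s = Σ_p plus[p] · minus[p + s − 1] for s = 1..S, i.e. the
number of ordered opposite-strand read pairs whose 5′ ends span s
overlapping nucleotides (a plus 5′ end at p and a minus 5′ end at
q ≥ p overlap by q − p + 1). S is the minimum piRNA length (default
23). Pairs are counted with read multiplicity; no collapsing by
distinct sequence is applied. The signature score treats N₁₀ as an
observation within the spectrum: z = (N₁₀ − μ)/σ with μ = Σ N_s / S
and σ the **population** standard deviation (divisor S) over all S
counts including N₁₀; p = 1 − Φ(z), one-sided upper tail. The
population convention and the one-sided tail are pinned by the
σ-convention test in the acceptance suite (an integer spectrum with
the published row's moments reproduces the published σ only under the
population divisor). Degenerate spectra (σ = 0, e.g. no opposite-
strand pairs at all) yield NA rather than being dropped. Note that z
is bounded by construction (all mass at N₁₀ gives z = √(S−1) ≈ 4.69
for S = 23), so it is a detection statistic, not an effect size. A
read has a ping-pong *partner* iff an opposite-strand 5′ end sits
exactly 9 nt inward; partner/non-partner lists are emitted per strand.

## Coverage tracks and figures

Depth tracks accumulate full read footprints; five_prime tracks
accumulate 5′ ends. Chromosome profiles are normalized as RPKM with
the bin width as the kilobase term (default 1 kb bins, configurable)
because per-base RPKM is not a coherent unit; TE profiles are per-base
raw depth per strand. Bedgraph output is 0-based half-open, zero runs
omitted, equal-valued neighbours merged. Every figure writes its
numeric series to a TSV sidecar; the sidecars, not the pixels, are
what tests compare.

## Synthetic data generator

`smallrna simulate` emulates a germline-like small RNA library at desk
scale. Category sequences are uniform-random and embedded verbatim in
random background contigs, so category reads are simultaneously
perfect genome mappers. Defaults: 4 TEs (600–1000 nt), 4 transcripts
(400–800 nt), 5 miRNAs (22 nt), 2 rRNAs, 3 tRNAs, 2 snRNAs on 3
contigs; composition 40% TE, 24% miRNA, 8% rRNA, 6% transcript, 5%
tRNA, 2% snRNA, 10% unannotated genome ("other"), 5% unmappable
noise — a bimodal length structure (22-nt miRNA peak, 23–29-nt piRNA
bulk, 21-nt siRNAs as a quarter of TE reads) resembling a drosophila
ovary library. Half of the TE piRNA reads are planted as ping-pong
pairs (minus-strand partner's 5′ end exactly at p + 9, emitted as the
reverse complement of the genomic window), and 1U/10A bias defaults
to 0.8.

Two generator choices deserve note. First, bias is planted by
rejection-sampling the read's start position conditional on the
desired base (with probability `bias_1U` the sense read must start
with T, otherwise it must not), rather than rewriting bases — a
rewrite would break the zero-mismatch genome match. Consequently for a
planted pair the sense-1U and antisense-10A conditions are the same
genomic base and share one bias draw, mirroring the biological
coupling of the two signatures. Second, every read is verified (with
the aligner, at the category mismatch bound) to match only its own
source feature, and noise reads are verified unmappable; this makes
the manifest an exact oracle — category counts, subgroup sizes and
per-feature counts are recovered with zero error, and bias
percentages within binomial noise.

What the generator does *not* emulate: sequencing errors, real TE
family structure and divergence, expression-level skew, isomiRs, and
genome-scale repeat content. Passing the recovery tests therefore
demonstrates correctness of the bookkeeping and statistics on
unambiguous data, not robustness to real-library ambiguity (where
multi-mapping and cross-category similarity make the "true" category
ill-defined).

## Problem sizes and numerical choices

Tests run on libraries of a few hundred to ~2500 reads over ~20-kb
genomes, where the exhaustive aligner is exact and fast; the
brute-force oracles (sliding-window Hamming scan, all-pairs overlap
enumeration) are tractable at this scale and pin the implementation
exactly. Planted-signal acceptance uses 520 pairs on one TE (z ≈ 4.6);
null calibration uses 100 replicates of 100 uniform 5′ ends per
strand on a 1-kb feature. Table statistics are pure floating-point
arithmetic plus the normal CDF and reproduce published values to
~10⁻¹² relative. Ties in multi-mapper placement are broken by sorted
order before seeded sampling; TSV floats are written with shortest
round-trip precision (`repr`), so re-reading a table reproduces values
bit-for-bit.

## Known limitations

- No gapped or quality-aware alignment; the SAM import path is the
  escape hatch for external aligners.
- The hash-index aligner is O(genome × reads) in the worst case via
  its substring-scan fallback and is meant for desk-scale genomes
  (≤ a few Mb), not mammalian ones.
- Ping-pong analysis uses the reported (default: one random) placement
  of multi-mappers; with `all` placements, pair counts on recently
  duplicated TEs inflate correspondingly.
- The HTML report is a static index of files, not an interactive
  browser.
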