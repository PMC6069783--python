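import itertools

import numpy as np
import pytest

from smallrna.cascade import (
    DEFAULT_ORDER,
    CategoryAssignment,
    PipelineParams,
    Subgroups,
    categorize,
    extract_subgroups,
    filter_by_length,
    pie_fractions,
)
from smallrna.io_formats import ReferenceSet, SmallRNARead

BASES = "ACGT"


def _read(rid, seq):
    return SmallRNARead(rid, seq, "I" * len(seq))


def _rand(rng, n):
    return "".join(BASES[b] for b in rng.integers(0, 4, n))


class TestLengthFilter:
    def test_bounds_inclusive(self):
        reads = [_read(f"r{n}", "A" * n) for n in (17, 18, 29, 30)]
        kept = filter_by_length(reads, 18, 29)
        assert [len(r) for r in kept] == [18, 29]

    def test_wider_window_retains_32nt_read(self):
        reads = [_read("r", "A" * 32)]
        assert filter_by_length(reads, 18, 32) == reads

    def test_matches_direct_filter(self):
        rng = np.random.default_rng(0)
        reads = [
            _read(f"r{i}", "A" * int(rng.integers(15, 35))) for i in range(200)
        ]
        kept = filter_by_length(reads, 18, 29)
        assert [r.read_id for r in kept] == [
            r.read_id for r in reads if 18 <= len(r) <= 29
        ]

    def test_order_preserved(self):
        reads = [_read("b", "A" * 20), _read("a", "A" * 25)]
        assert [r.read_id for r in filter_by_length(reads, 18, 29)] == ["b", "a"]


@pytest.fixture()
def disjoint_refs():
    """One reference per category, pairwise unrelated random sequences."""
    rng = np.random.default_rng(11)
    refs = {}
    for cat, n in [("rRNA", 150), ("miRNA", 22), ("tRNA", 80),
                   ("snRNA", 120), ("transcript", 500), ("TE", 800)]:
        rs = ReferenceSet(cat)
        rs.add(f"{cat}_1", _rand(rng, n))
        refs[cat] = rs
    return refs


class TestCategorize:
    def test_first_matching_category_wins(self, disjoint_refs):
        """A read matching both miRNA and TE goes to miRNA (earlier in order)."""
        mirna_seq = disjoint_refs["miRNA"].sequences["miRNA_1"]
        # embed the miRNA inside the TE so the read matches both references
        te = disjoint_refs["TE"]
        te.sequences["TE_1"] = te.sequences["TE_1"][:100] + mirna_seq + te.sequences["TE_1"][122:]
        read = _read("r", mirna_seq)
        assignment = categorize([read], disjoint_refs, PipelineParams())
        assert assignment.category_of["r"] == "miRNA"

    def test_unmatched_read_is_other(self, disjoint_refs):
        rng = np.random.default_rng(99)
        read = _read("r", _rand(rng, 25))
        assignment = categorize([read], disjoint_refs, PipelineParams())
        assert assignment.category_of["r"] == "other"
        assert assignment.counts["other"] == 1

    def test_runs_without_structural_references(self, disjoint_refs):
        te_read = _read("r", disjoint_refs["TE"].sequences["TE_1"][10:35])
        refs = {k: disjoint_refs[k] for k in ("miRNA", "transcript", "TE")}
        assignment = categorize([te_read], refs, PipelineParams())
        assert assignment.category_of["r"] == "TE"
        assert assignment.counts["rRNA"] == 0

    def test_counts_conserve_mappers(self, small_fixture):
        mappers = [r for r in small_fixture.reads
                   if small_fixture.manifest.records[int(r.read_id[1:]) - 1].category != "noise"]
        assignment = categorize(
            mappers, small_fixture.category_refs, PipelineParams()
        )
        assert sum(assignment.counts.values()) == assignment.total_genome_mappers
        assert assignment.total_genome_mappers == len(mappers)

    def test_single_category_reads_order_invariant(self, disjoint_refs):
        """Reads matching exactly one category keep their class under any order."""
        reads = [
            _read("te", disjoint_refs["TE"].sequences["TE_1"][5:30]),
            _read("mi", disjoint_refs["miRNA"].sequences["miRNA_1"]),
            _read("tx", disjoint_refs["transcript"].sequences["transcript_1"][50:75]),
        ]
        expected = {"te": "TE", "mi": "miRNA", "tx": "transcript"}
        for order in itertools.islice(itertools.permutations(DEFAULT_ORDER), 0, 24, 5):
            params = PipelineParams(category_order=tuple(order))
            assignment = categorize(reads, disjoint_refs, params)
            assert assignment.category_of == expected


class TestSubgroups:
    def _assignment(self, cats):
        counts = {}
        for c in cats.values():
            counts[c] = counts.get(c, 0) + 1
        return CategoryAssignment(cats, counts, len(cats), 0)

    def test_21nt_te_read_in_bonafide_and_sirna(self):
        reads = {"r": _read("r", "A" * 21)}
        sub = extract_subgroups(
            self._assignment({"r": "TE"}), reads, PipelineParams()
        )
        assert "r" in sub.bonafide and "r" in sub.sirna and "r" not in sub.pirna

    def test_25nt_other_read_in_bonafide_and_pirna(self):
        reads = {"r": _read("r", "A" * 25)}
        sub = extract_subgroups(
            self._assignment({"r": "other"}), reads, PipelineParams()
        )
        assert "r" in sub.bonafide and "r" in sub.pirna and "r" not in sub.sirna

    def test_structural_reads_excluded_from_bonafide(self):
        reads = {c: _read(c, "A" * 25) for c in ("mi", "rr", "tr", "sn")}
        cats = {"mi": "miRNA", "rr": "rRNA", "tr": "tRNA", "sn": "snRNA"}
        sub = extract_subgroups(self._assignment(cats), reads, PipelineParams())
        assert sub.bonafide == set()
        assert sub.mirna == {"mi"}

    def test_sizes_match_generator_manifest(self, small_fixture):
        m = small_fixture.manifest
        reads_by_id = {r.read_id: r for r in small_fixture.reads}
        cats = {
            rec.read_id: rec.category
            for rec in m.records
            if rec.category != "noise"
        }
        sub = extract_subgroups(self._assignment(cats), reads_by_id, PipelineParams())
        assert sub.sizes() == m.expected_subgroup_sizes()

    def test_narrower_window_never_grows_subgroups(self, small_fixture):
        m = small_fixture.manifest
        reads_by_id = {r.read_id: r for r in small_fixture.reads}
        cats = {r.read_id: r.category for r in m.records if r.category != "noise"}
        assignment = self._assignment(cats)
        wide = extract_subgroups(
            assignment, reads_by_id, PipelineParams(pirna_len_min=23, pirna_len_max=29)
        )
        narrow = extract_subgroups(
            assignment, reads_by_id, PipelineParams(pirna_len_min=24, pirna_len_max=28)
        )
        assert narrow.pirna <= wide.pirna


class TestPieFractions:
    def _assignment(self, counts):
        return CategoryAssignment({}, counts, sum(counts.values()), 0)

    def test_single_category_is_100_percent(self):
        pie = pie_fractions(self._assignment({"TE": 10}))
        assert pie["TE"] == 100.0

    def test_published_style_proportions(self):
        pie = pie_fractions(
            self._assignment({"TE": 46, "miRNA": 24, "transcript": 6, "other": 24})
        )
        assert (pie["TE"], pie["miRNA"], pie["transcript"]) == (46.0, 24.0, 6.0)

    def test_fractions_match_direct_ratio(self):
        rng = np.random.default_rng(2)
        counts = {c: int(n) for c, n in zip("abcd", rng.integers(1, 100, 4))}
        pie = pie_fractions(self._assignment(counts))
        total = sum(counts.values())
        for c, n in counts.items():
            assert pie[c] == pytest.approx(100 * n / total)
        assert sum(pie.values()) == pytest.approx(100.0)

    def test_zero_mappers_is_error(self):
        with pytest.raises(ValueError):
            pie_fractions(self._assignment({}))


class TestParams:
    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            PipelineParams(min_len=30, max_len=20)
        with pytest.raises(ValueError):
            PipelineParams(category_order=("TE", "plasmid"))
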