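import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from oracles import pair_enumeration_spectrum, pair_scan_partners
from smallrna.io_formats import MINUS, PLUS, AlignmentHit
from smallrna.pingpong import (
    OverlapSpectrum,
    five_prime_profiles,
    overlap_histogram,
    overlap_spectrum,
    partner_lists,
    pingpong_stats,
    pingpong_table,
)


def _hit(rid, start, strand, length=25, feature="TE_1"):
    return AlignmentHit(feature, start, strand, rid, 0, length)


class TestFivePrimeProfiles:
    def test_plus_read_five_prime_is_start(self):
        plus, minus = five_prime_profiles([_hit("r", 0, PLUS, 25)], 100)
        assert plus[0] == 1 and plus.sum() == 1 and minus.sum() == 0

    def test_minus_read_five_prime_is_right_end(self):
        plus, minus = five_prime_profiles([_hit("r", 0, MINUS, 25)], 100)
        assert minus[24] == 1 and minus.sum() == 1 and plus.sum() == 0

    def test_profiles_match_direct_accumulation(self):
        rng = np.random.default_rng(3)
        hits = [
            _hit(f"r{i}", int(rng.integers(0, 150)),
                 PLUS if rng.random() < 0.5 else MINUS,
                 int(rng.integers(23, 30)))
            for i in range(200)
        ]
        plus, minus = five_prime_profiles(hits, 200)
        exp_plus = np.zeros(200)
        exp_minus = np.zeros(200)
        for h in hits:
            if h.strand == PLUS:
                exp_plus[h.start] += 1
            else:
                exp_minus[h.start + h.read_len - 1] += 1
        assert (plus == exp_plus).all() and (minus == exp_minus).all()


class TestOverlapSpectrum:
    def test_ten_nt_overlap_definition(self):
        plus = np.zeros(50); minus = np.zeros(50)
        plus[0] = 1; minus[9] = 1
        spec = overlap_spectrum(plus, minus, 23)
        assert spec.ten_sum == 1
        assert spec.overlap_sum == 1

    def test_minimal_one_nt_overlap(self):
        plus = np.zeros(50); minus = np.zeros(50)
        plus[0] = 1; minus[0] = 1
        spec = overlap_spectrum(plus, minus, 23)
        assert spec.counts[0] == 1 and spec.overlap_sum == 1

    def test_matches_pair_enumeration(self):
        """50 reads per strand: spectrum equals brute-force q - p + 1 counts."""
        rng = np.random.default_rng(8)
        p5 = [int(x) for x in rng.integers(0, 300, 50)]
        m5 = [int(x) for x in rng.integers(0, 300, 50)]
        plus = np.zeros(300); minus = np.zeros(300)
        for p in p5: plus[p] += 1
        for q in m5: minus[q] += 1
        spec = overlap_spectrum(plus, minus, 23)
        assert list(spec.counts) == pair_enumeration_spectrum(p5, m5, 23)

    def test_invalid_spectrum_size(self):
        with pytest.raises(ValueError):
            overlap_spectrum(np.zeros(5), np.zeros(5), 0)


class TestPingPongStats:
    def test_mean_from_table_style_sum(self):
        spec = OverlapSpectrum(counts=tuple([1267 / 23] * 23))
        assert pingpong_stats(spec).mean == pytest.approx(
            55.0869565217391, rel=1e-12
        )

    def test_no_tens_spectrum_with_known_sigma(self):
        # integer spectrum with sum 13, sum of squares 31, N_10 = 0
        counts = (1, 2, 2, 2, 3, 3, 0, 0, 0, 0) + (0,) * 13
        stats = pingpong_stats(OverlapSpectrum(counts=counts))
        assert stats.mean == pytest.approx(0.565217391304348, rel=1e-12)
        assert stats.sigma == pytest.approx(1.01407859040788, rel=1e-12)
        assert stats.z == pytest.approx(-0.557370401713154, rel=1e-12)
        assert stats.p == pytest.approx(0.711362808127372, rel=1e-9)

    def test_spiked_spectrum_closed_form(self):
        # all-ones spectrum with N_10 = 24: mean 2, sigma sqrt(22), z sqrt(22)
        counts = tuple(24 if s == 10 else 1 for s in range(1, 24))
        stats = pingpong_stats(OverlapSpectrum(counts=counts))
        assert stats.mean == pytest.approx(2.0)
        assert stats.sigma == pytest.approx(math.sqrt(22))
        assert stats.z == pytest.approx(math.sqrt(22))
        assert stats.p == pytest.approx(float(norm.sf(math.sqrt(22))))

    def test_degenerate_spectrum_gives_na(self):
        stats = pingpong_stats(OverlapSpectrum(counts=(0.0,) * 23))
        assert stats.z is None and stats.p is None

    @settings(deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=23, max_size=23),
        c=st.integers(1, 50),
    )
    def test_scale_invariance_of_z(self, counts, c):
        base = pingpong_stats(OverlapSpectrum(counts=tuple(map(float, counts))))
        scaled = pingpong_stats(
            OverlapSpectrum(counts=tuple(float(c * x) for x in counts))
        )
        if base.z is None:
            assert scaled.z is None
        else:
            assert scaled.z == pytest.approx(base.z, rel=1e-9)


class TestOverlapHistogram:
    def test_single_pair_is_100_percent(self):
        spec = OverlapSpectrum(counts=tuple(1.0 if s == 10 else 0.0 for s in range(1, 24)))
        hist = overlap_histogram(spec)
        assert hist[9] == 100.0

    def test_uniform_spectrum(self):
        hist = overlap_histogram(OverlapSpectrum(counts=(2.0,) * 23))
        assert all(h == pytest.approx(100 / 23) for h in hist)
        assert sum(hist) == pytest.approx(100.0)

    def test_empty_spectrum_is_na(self):
        assert overlap_histogram(OverlapSpectrum(counts=(0.0,) * 23)) == [None] * 23


class TestPartnerLists:
    def test_ten_nt_pair_both_partnered(self):
        # minus read with 5' at 9: start + len - 1 = 9 -> start 0, len 10
        hits = [_hit("p", 0, PLUS, 25), _hit("m", 0, MINUS, 10)]
        lists = partner_lists(hits, 100)
        assert lists.sense_with == ["p"]
        assert lists.antisense_with == ["m"]

    def test_lone_plus_read_without_partner(self):
        lists = partner_lists([_hit("p", 5, PLUS)], 100)
        assert lists.sense_without == ["p"]
        assert not lists.sense_with

    def test_with_without_partitions_each_strand(self):
        rng = np.random.default_rng(12)
        hits = [
            _hit(f"r{i}", int(rng.integers(0, 80)),
                 PLUS if rng.random() < 0.5 else MINUS, int(rng.integers(23, 30)))
            for i in range(120)
        ]
        lists = partner_lists(hits, 120)
        sense = {h.read_id for h in hits if h.strand == PLUS}
        anti = {h.read_id for h in hits if h.strand == MINUS}
        assert set(lists.sense_with) | set(lists.sense_without) == sense
        assert not set(lists.sense_with) & set(lists.sense_without)
        assert set(lists.antisense_with) | set(lists.antisense_without) == anti

    def test_matches_brute_force_pair_scan(self):
        rng = np.random.default_rng(13)
        hits = [
            _hit(f"r{i}", int(rng.integers(0, 150)),
                 PLUS if i % 2 else MINUS, int(rng.integers(23, 30)))
            for i in range(100)
        ]
        lists = partner_lists(hits, 200)
        plus5 = {h.read_id: h.five_prime for h in hits if h.strand == PLUS}
        minus5 = {h.read_id: h.five_prime for h in hits if h.strand == MINUS}
        sense_with, anti_with = pair_scan_partners(plus5, minus5)
        assert set(lists.sense_with) == sense_with
        assert set(lists.antisense_with) == anti_with


class TestPingPongTable:
    def test_empty_feature_reported_with_na(self):
        rows = pingpong_table({}, {"TE_1": 500}, 23)
        assert rows[0]["ID"] == "TE_1"
        assert rows[0]["z-score"] is None and rows[0]["p-value"] is None

    def test_planted_fixture_spectrum_matches_manifest_plus_incidentals(
        self, small_fixture
    ):
        """Computed spectrum = planted pairs + oracle-computed incidental pairs."""
        m = small_fixture.manifest
        te_lens = small_fixture.category_refs["TE"].lengths
        for te, placements in m.te_pirna_placements().items():
            plus5 = [s for strand, s, L in placements if strand == PLUS]
            minus5 = [s + L - 1 for strand, s, L in placements if strand == MINUS]
            expected = pair_enumeration_spectrum(plus5, minus5, 23)
            plus = np.zeros(te_lens[te]); minus = np.zeros(te_lens[te])
            for p in plus5: plus[p] += 1
            for q in minus5: minus[q] += 1
            spec = overlap_spectrum(plus, minus, 23)
            assert list(spec.counts) == expected
            # every planted pair contributes one 10-nt overlap
            assert spec.ten_sum >= m.planted_pair_counts().get(te, 0)
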