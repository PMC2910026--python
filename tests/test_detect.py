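"""Frequency-based tag prediction: k-mers, shifts, classification, recovery."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tagtrim.detect import (
    FrequencyProfile,
    KmerShift,
    PositionClass,
    TagDetectionError,
    adjust_shifts,
    align_shift,
    classify_positions,
    corrected_frequencies,
    detect_tag,
    extract_end_kmers,
    filter_and_rank_kmers,
    frequency_report,
    merge_kmers,
    predict_tag,
)
from tagtrim.records import End, SequenceRecord
from tagtrim.simulate import DEFAULT_TAG3, DEFAULT_TAG5, SimulationConfig, generate

from conftest import random_dna


def recs(*seqs: str) -> list[SequenceRecord]:
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]


class TestEndKmers:
    def test_uniform_prefixes_give_a_single_kmer(self):
        reads = recs(*["GTGGTACGT" for _ in range(10)])
        assert extract_end_kmers(reads, k=5) == {"GTGGT": 10}

    def test_counts_partition_the_reads(self):
        rng = random.Random(0)
        reads = recs(*[random_dna(rng, 30) for _ in range(200)])
        counts = extract_end_kmers(reads, k=5, end=End.THREE_PRIME)
        assert sum(counts.values()) == 200

    def test_short_reads_are_skipped_and_empty_input_rejected(self):
        with pytest.raises(TagDetectionError):
            extract_end_kmers(recs("ACG"), k=5)

    def test_indel_noise_produces_shifted_variants_of_the_top_kmer(self):
        cfg = SimulationConfig(
            n_reads=500, indel_rate=0.20, substitution_rate=0.0, concat_rate=0.0,
            duplicate_rate=0.0, n_rate=0.0, insert_min=100, insert_max=200,
            read_cap=400, seed=21,
        )
        reads, _ = generate(cfg)
        counts = extract_end_kmers(reads, k=5)
        top = max(counts, key=counts.get)
        assert top == DEFAULT_TAG5[:5]
        shifted = [k for k in counts if k != top and align_shift(top, k, 2) is not None]
        assert shifted  # at least one 1-2 position shift variant present


class TestRanking:
    def test_ten_percent_threshold(self):
        ranked = filter_and_rank_kmers({"AAAAA": 60, "AAAAT": 20, "CCCCC": 5}, 100)
        assert [ks.kmer for ks in ranked] == ["AAAAA", "AAAAT"]
        assert [ks.count for ks in ranked] == [60, 20]

    def test_all_unique_kmers_abort_detection(self):
        counts = {f"K{i}": 1 for i in range(1000)}
        with pytest.raises(TagDetectionError, match="no conserved end signal"):
            filter_and_rank_kmers(counts, 1000)

    def test_ties_break_lexicographically(self):
        ranked = filter_and_rank_kmers({"TTTTT": 50, "AAAAA": 50}, 100)
        assert [ks.kmer for ks in ranked] == ["AAAAA", "TTTTT"]


class TestAlignShift:
    def test_both_directions_tie(self):
        assert align_shift("ACACA", "CACAC") == (1, True)

    def test_identical_strings(self):
        assert align_shift("GTGGT", "GTGGT") == (0, False)

    def test_unalignable_within_two_shifts(self):
        assert align_shift("GTGTT", "TTTGG") is None

    def test_single_direction_shift(self):
        # candidate shifted left: its tail matches the anchor's head
        assert align_shift("CACCA", "ACACC") == (-1, False)


class TestMergeAndAdjust:
    def test_three_prime_agglomeration(self):
        # dominant terminal 5-mer plus one left- and one right-shifted variant
        ranked = [
            KmerShift("CACCA", 60),
            KmerShift("ACACC", 20),  # terminal deletion: shifted left
            KmerShift("ACCAA", 15),  # terminal insertion: shifted right
        ]
        consensus, shifts = merge_kmers(ranked, end=End.THREE_PRIME)
        assert len(consensus) == 7
        assert {k: v.shift for k, v in shifts.items()} == {
            "CACCA": 0, "ACACC": -1, "ACCAA": 1,
        }
        adjusted = adjust_shifts(shifts, End.THREE_PRIME)
        assert {k: v.shift for k, v in adjusted.items()} == {
            "CACCA": -1, "ACACC": -2, "ACCAA": 0,
        }

    def test_single_kmer_is_its_own_consensus(self):
        consensus, shifts = merge_kmers([KmerShift("GTGGT", 100)])
        assert consensus == "GTGGT"
        assert shifts["GTGGT"].shift == 0

    def test_unalignable_kmer_is_left_out(self):
        consensus, shifts = merge_kmers([KmerShift("GTGGT", 60), KmerShift("CCCCC", 20)])
        assert consensus == "GTGGT"
        assert "CCCCC" not in shifts

    def test_five_prime_adjustment_makes_shifts_nonnegative(self):
        shifts = {
            "AAAAA": KmerShift("AAAAA", 50, shift=0),
            "CAAAA": KmerShift("CAAAA", 20, shift=-2),
        }
        adjusted = adjust_shifts(shifts, End.FIVE_PRIME)
        assert {k: v.shift for k, v in adjusted.items()} == {"AAAAA": 2, "CAAAA": 0}

    def test_all_zero_shifts_stay_unchanged(self):
        shifts = {"AAAAA": KmerShift("AAAAA", 50, shift=0)}
        for end in End:
            assert adjust_shifts(shifts, end)["AAAAA"].shift == 0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5), min_size=1,
                    max_size=8, unique=True))
    def test_merge_terminates_with_bounded_consensus(self, kmers):
        ranked = [KmerShift(k, 100 - i) for i, k in enumerate(kmers)]
        consensus, shifts = merge_kmers(ranked)
        abs_shifts = sum(abs(v.shift) for v in shifts.values() if not v.both)
        assert len(consensus) <= 5 + abs_shifts


class TestProfiles:
    def test_no_assignments_equals_raw_frequencies(self):
        rng = random.Random(1)
        reads = recs(*[random_dna(rng, 80) for _ in range(100)])
        raw = corrected_frequencies(reads, {}, End.FIVE_PRIME)
        again = corrected_frequencies(reads, {}, End.FIVE_PRIME)
        assert np.array_equal(raw.counts, again.counts)

    def test_uniform_shift_translates_the_profile(self):
        rng = random.Random(2)
        reads = recs(*[random_dna(rng, 80) for _ in range(50)])
        raw = corrected_frequencies(reads, {}, End.FIVE_PRIME, depth=40)
        assign = {r.sequence[:5]: KmerShift(r.sequence[:5], 1, shift=1) for r in reads}
        shifted = corrected_frequencies(reads, assign, End.FIVE_PRIME, depth=40)
        assert np.array_equal(shifted.counts[1:40], raw.counts[0:39])
        assert shifted.counts[0].sum() == 0

    def test_n_bases_are_excluded_from_support(self):
        reads = recs("NACG", "AACG")
        prof = corrected_frequencies(reads, {}, End.FIVE_PRIME, depth=4)
        assert prof.support[0] == 1
        assert prof.support[1] == 2

    def test_shift_correction_sharpens_tag_positions(self):
        # 30% of reads miss their first base; re-registration must not blur
        # (and here must sharpen) the per-position majority frequencies
        rng = random.Random(3)
        tag = "GTGGTGTGTTGG"
        reads = []
        for i in range(400):
            body = tag + random_dna(rng, 60)
            reads.append(SequenceRecord(f"r{i}", body[1:] if i % 10 < 3 else body))
        raw = corrected_frequencies(reads, {}, End.FIVE_PRIME, depth=len(tag))
        counts = extract_end_kmers(reads, k=5)
        ranked = filter_and_rank_kmers(counts, len(reads))
        _, shifts = merge_kmers(ranked, end=End.FIVE_PRIME)
        adjusted = adjust_shifts(shifts, End.FIVE_PRIME)
        corr = corrected_frequencies(reads, adjusted, End.FIVE_PRIME, depth=len(tag))
        sharp_raw = raw.freqs.max(axis=1)[1 : len(tag)].mean()
        sharp_corr = corr.freqs.max(axis=1)[1 : len(tag)].mean()
        assert sharp_corr >= sharp_raw
        assert sharp_corr > 0.99


def profile_from_freqs(rows, n=1000):
    counts = np.asarray([[int(round(f * n)) for f in row] for row in rows])
    return FrequencyProfile(End.FIVE_PRIME, counts)


class TestClassification:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((1.0, 0.0, 0.0, 0.0), PositionClass.SPECIFIC),
            ((0.25, 0.25, 0.25, 0.25), PositionClass.BACKGROUND),
            ((0.45, 0.30, 0.15, 0.10), PositionClass.QUASI_RANDOM),
        ],
    )
    def test_range_median_rule(self, freqs, expected):
        prof = profile_from_freqs([freqs])
        assert classify_positions(prof) == [expected]

    def test_low_support_positions_are_background(self):
        prof = profile_from_freqs([(1.0, 0.0, 0.0, 0.0)], n=10)
        assert classify_positions(prof, min_support=50) == [PositionClass.BACKGROUND]

    def test_classification_is_scale_free(self):
        rows = [(0.45, 0.30, 0.15, 0.10), (0.9, 0.05, 0.03, 0.02), (0.25,) * 4]
        a = classify_positions(profile_from_freqs(rows, n=1000))
        b = classify_positions(profile_from_freqs(rows, n=7000))
        assert a == b


class TestPrediction:
    def test_tag_is_the_leading_non_background_run(self):
        rows = [(0.97, 0.01, 0.01, 0.01)] * 3 + [(0.45, 0.30, 0.15, 0.10)] * 2 + [(0.25,) * 4] * 3
        prof = profile_from_freqs(rows)
        classes = classify_positions(prof)
        tag = predict_tag(classes, prof, End.FIVE_PRIME)
        assert tag.sequence == "AAANN"

    def test_three_prime_prediction_is_reversed(self):
        rows = [(0.0, 0.97, 0.02, 0.01), (0.97, 0.01, 0.01, 0.01), (0.25,) * 4]
        prof = FrequencyProfile(End.THREE_PRIME, profile_from_freqs(rows).counts)
        classes = classify_positions(prof)
        tag = predict_tag(classes, prof, End.THREE_PRIME)
        assert tag.sequence == "AC"  # position 0 is the last read base

    def test_background_everywhere_means_no_tag(self):
        prof = profile_from_freqs([(0.25,) * 4] * 5)
        classes = classify_positions(prof)
        assert predict_tag(classes, prof, End.FIVE_PRIME) is None

    def test_exact_recovery_on_a_simulated_wta_dataset(self):
        cfg = SimulationConfig(
            n_reads=2000, indel_rate=0.05, substitution_rate=0.0, concat_rate=0.0,
            duplicate_rate=0.0, n_rate=0.0, insert_min=100, insert_max=300,
            read_cap=500, seed=2024,
        )
        reads, _ = generate(cfg)
        r5 = detect_tag(reads, End.FIVE_PRIME)
        r3 = detect_tag(reads, End.THREE_PRIME)
        assert r5.tag is not None and r5.tag.sequence == DEFAULT_TAG5
        assert r3.tag is not None and r3.tag.sequence == DEFAULT_TAG3

    def test_tag_free_data_reports_no_conserved_signal(self):
        rng = random.Random(4)
        reads = recs(*[random_dna(rng, 120) for _ in range(1000)])
        result = detect_tag(reads, End.FIVE_PRIME)
        assert result.tag is None
        assert "no conserved end signal" in result.note

    def test_frequency_report_lists_every_position(self):
        rng = random.Random(5)
        reads = recs(*[random_dna(rng, 120) for _ in range(100)])
        result = detect_tag(reads, End.FIVE_PRIME)
        lines = frequency_report(result).strip().splitlines()
        assert lines[0].startswith("position\tA\tC\tG\tT")
        assert len(lines) == 1 + result.corrected_profile.depth
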