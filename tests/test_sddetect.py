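"""Segmental-duplication detection: stages and end-to-end recovery."""

import numpy as np
import pytest

from pprdup.core import GenomicInterval
from pprdup.sddetect import (
    Fragment, SDParams, alignment_rows, detect_sds, fragment, pairwise_align,
    remove_repeats,
)
from pprdup.simulate import mutate_to_identity, random_dna, random_genome


class TestRemoveRepeats:
    def test_condensed_length_and_mapping(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 10_000)
        reps = [GenomicInterval("chr1", 2000, 3000), GenomicInterval("chr1", 5000, 6000)]
        condensed, maps = remove_repeats({"chr1": seq}, reps)
        assert len(condensed["chr1"]) == 8000
        # condensed position 2000 is the first base after the first repeat
        assert maps["chr1"].to_original(2000) == 3000

    def test_round_trip_on_non_repeat_positions(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 5000)
        reps = [GenomicInterval("chr1", 1000, 1500)]
        condensed, maps = remove_repeats({"chr1": seq}, reps)
        m = maps["chr1"]
        for pos in (0, 999, 1500, 4999):
            assert m.to_original(m.to_condensed(pos)) == pos
        with pytest.raises(ValueError):
            m.to_condensed(1200)  # inside the repeat

    def test_overlapping_repeats_merged(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 4000)
        reps = [GenomicInterval("chr1", 1000, 2000), GenomicInterval("chr1", 1500, 2500)]
        condensed, _ = remove_repeats({"chr1": seq}, reps)
        assert len(condensed["chr1"]) == 2500


class TestFragment:
    def test_fragment_sizes(self):
        seqs = {"chr1": "A" * 1_000_000}
        frags = fragment(seqs, 400_000)
        assert [len(f.sequence) for f in frags] == [400_000, 400_000, 200_000]
        assert [f.offset for f in frags] == [0, 400_000, 800_000]

    def test_short_sequence_single_fragment(self):
        frags = fragment({"chr1": "A" * 300_000}, 400_000)
        assert len(frags) == 1 and frags[0].offset == 0


class TestPairwiseAlign:
    def test_exact_copies_found_at_full_identity(self):
        rng = np.random.default_rng(3)
        copy = random_dna(rng, 1000)
        seq = random_dna(rng, 5000) + copy + random_dna(rng, 5000) + copy \
            + random_dna(rng, 3000)
        raws = pairwise_align([Fragment("chr1", 0, seq)])
        assert len(raws) == 1
        assert raws[0].identity == 100.0
        assert raws[0].aligned_length >= 1000

    def test_mutated_copy_identity_close_to_target(self):
        rng = np.random.default_rng(4)
        copy = random_dna(rng, 1500)
        mutated = mutate_to_identity(copy, 94.0, rng)
        seq = random_dna(rng, 4000) + copy + random_dna(rng, 4000) + mutated \
            + random_dna(rng, 2000)
        raws = pairwise_align([Fragment("chr1", 0, seq)])
        assert len(raws) == 1
        assert 93.0 <= raws[0].identity <= 95.0

    def test_null_sequence_has_no_long_alignment(self):
        # random sequence: no raw alignment of 1 kb or more
        misses = 0
        for seed in range(20):
            seqs = random_genome(100_000, 900 + seed)
            raws = pairwise_align([Fragment("chr1", 0, seqs["chr1"])])
            if not any(r.aligned_length >= 1000 for r in raws):
                misses += 1
        assert misses >= 19

    def test_reverse_orientation_copy_detected(self):
        rng = np.random.default_rng(5)
        copy = random_dna(rng, 1500)
        rc = copy[::-1].translate(str.maketrans("ACGT", "TGCA"))
        seq = random_dna(rng, 4000) + copy + random_dna(rng, 4000) + rc \
            + random_dna(rng, 2000)
        raws = pairwise_align([Fragment("chr1", 0, seq)])
        assert any(r.orientation == "reverse" and r.aligned_length >= 1400
                   for r in raws)


class TestDetect:
    def _planted_genome(self, seed, identity=95.0, length=2000, reverse=False):
        rng = np.random.default_rng(seed)
        copy = random_dna(rng, length)
        mutated = mutate_to_identity(copy, identity, rng)
        if reverse:
            mutated = mutated[::-1].translate(str.maketrans("ACGT", "TGCA"))
        chr1 = random_dna(rng, 60_000) + copy + random_dna(rng, 50_000)
        chr2 = random_dna(rng, 30_000) + mutated + random_dna(rng, 40_000)
        truth_a = GenomicInterval("chr1", 60_000, 60_000 + length)
        truth_b = GenomicInterval("chr2", 30_000, 30_000 + length)
        return {"chr1": chr1, "chr2": chr2}, truth_a, truth_b

    def test_planted_duplication_recovered(self):
        seqs, ta, tb = self._planted_genome(10)
        sds = detect_sds(seqs, [])
        assert len(sds) == 1
        sd = sds[0]
        assert abs(sd.identity - 95.0) <= 1.0
        for found, want in ((sd.copy_a, ta), (sd.copy_b, tb)):
            ov = found.overlap(want)
            assert ov >= 0.95 * len(want) and ov >= 0.95 * len(found)

    def test_symmetric_under_copy_order(self):
        seqs, _, _ = self._planted_genome(11)
        swapped = {"chr1": seqs["chr2"], "chr2": seqs["chr1"]}
        sds = detect_sds(seqs, [])
        sds_swapped = detect_sds(swapped, [])
        assert len(sds) == len(sds_swapped) == 1
        assert sds[0].aligned_length == pytest.approx(
            sds_swapped[0].aligned_length, abs=30
        )

    def test_short_duplication_rejected(self):
        # 900 bp at 99% stays below the 1-kb final cutoff
        rng = np.random.default_rng(12)
        copy = random_dna(rng, 900)
        mutated = mutate_to_identity(copy, 99.0, rng)
        seqs = {"chr1": random_dna(rng, 30_000) + copy + random_dna(rng, 30_000)
                + mutated + random_dna(rng, 10_000)}
        assert detect_sds(seqs, []) == []

    def test_repeat_interrupted_duplication_merged(self):
        # both copies interrupted by the same annotated 2-kb repeat
        rng = np.random.default_rng(13)
        left = random_dna(rng, 1200)
        right = random_dna(rng, 1200)
        repeat = random_dna(rng, 2000)
        unit_a = left + repeat + right
        unit_b = (mutate_to_identity(left, 96.0, rng) + repeat
                  + mutate_to_identity(right, 96.0, rng))
        chr1 = random_dna(rng, 20_000) + unit_a + random_dna(rng, 20_000) \
            + unit_b + random_dna(rng, 10_000)
        a0 = 20_000
        b0 = a0 + len(unit_a) + 20_000
        repeats = [
            GenomicInterval("chr1", a0 + 1200, a0 + 3200),
            GenomicInterval("chr1", b0 + 1200, b0 + 3200),
        ]
        sds = detect_sds({"chr1": chr1}, repeats)
        assert len(sds) == 1
        # the final SD spans the repeat on both copies
        assert len(sds[0].copy_a) >= 4000 and len(sds[0].copy_b) >= 4000

    def test_reported_identity_matches_independent_realignment(self):
        seqs, _, _ = self._planted_genome(14, identity=93.0, length=2500)
        sds = detect_sds(seqs, [])
        assert len(sds) == 1
        sd = sds[0]
        sub_a = seqs[sd.copy_a.chromosome][sd.copy_a.start : sd.copy_a.end]
        sub_b = seqs[sd.copy_b.chromosome][sd.copy_b.start : sd.copy_b.end]
        _, match_row, _ = alignment_rows(sub_a, sub_b)
        independent = 100.0 * match_row.count("|") / len(match_row)
        assert abs(independent - sd.identity) <= 0.5

    def test_reverse_duplication_reported_with_orientation(self):
        seqs, ta, tb = self._planted_genome(15, reverse=True)
        sds = detect_sds(seqs, [])
        assert len(sds) == 1
        assert sds[0].orientation == "reverse"
        ov = sds[0].copy_a.overlap(ta) + sds[0].copy_b.overlap(tb) \
            + sds[0].copy_a.overlap(tb) + sds[0].copy_b.overlap(ta)
        assert ov >= 0.9 * (len(ta) + len(tb))

    def test_deterministic(self):
        seqs, _, _ = self._planted_genome(16)
        first = detect_sds(seqs, [])
        second = detect_sds(seqs, [])
        assert [(s.copy_a, s.copy_b, s.identity) for s in first] == [
            (s.copy_a, s.copy_b, s.identity) for s in second
        ]


class TestInvariants:
    def test_final_thresholds_hold_on_fixture(self, sd_results):
        for lab in ("A", "B"):
            for sd in sd_results[lab].sds:
                assert sd.aligned_length > 1000
                assert sd.identity > 90.0
                ov = sd.copy_a.overlap(sd.copy_b)
                assert ov <= 0.1 * min(len(sd.copy_a), len(sd.copy_b))

    def test_segment_map_projection_roundtrip(self, sd_results):
        sd = sd_results["A"].sds[0]
        from pprdup.sddetect import _invert_map

        inv = _invert_map(sd.segment_map)
        mid = (sd.copy_a.start + sd.copy_a.end) // 2
        projected = sd.segment_map.project(mid)
        assert sd.copy_b.start <= projected < sd.copy_b.end
        # substitution-only fixture: the map is exactly invertible
        assert inv.project(projected) == mid
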