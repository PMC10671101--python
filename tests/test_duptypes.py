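"""Collinearity chaining and duplication-type classification."""

import itertools

import numpy as np
import pytest

from pprdup.duptypes import (
    classify_duplications, detect_collinear_blocks, dup_type_proportions,
    gene_labels, gene_orders,
)
from pprdup.homology import SimilarityHit


def _orders_from_anchors(anchors):
    orders = {}
    for i, (ra, rb) in enumerate(anchors):
        orders[f"x{i}"] = ("c1", ra)
        orders[f"y{i}"] = ("c2", rb)
    return orders


def _hits_from_anchors(anchors):
    return [SimilarityHit(f"x{i}", f"y{i}", 500.0, 80.0, 100)
            for i in range(len(anchors))]


def _brute_force_longest_chain(anchors, max_gap):
    """Exhaustive longest monotone chain with the rank-gap constraint."""
    n = len(anchors)
    best = 0
    order = sorted(range(n), key=lambda i: anchors[i])

    def extend(chain_last, remaining, length, inverted):
        nonlocal best
        best = max(best, length)
        for i in remaining:
            ra, rb = anchors[i]
            la, lb = anchors[chain_last]
            di = ra - la
            dj = (lb - rb) if inverted else (rb - lb)
            if 1 <= di <= max_gap and 1 <= dj <= max_gap:
                extend(i, [j for j in remaining if anchors[j][0] > ra], length + 1,
                       inverted)

    for inverted in (False, True):
        for i in order:
            extend(i, [j for j in order if anchors[j][0] > anchors[i][0]], 1,
                   inverted)
    return best


class TestChaining:
    def test_five_consecutive_anchors_one_block(self):
        anchors = [(10 + k, 210 + k) for k in range(5)]
        blocks = detect_collinear_blocks(
            _hits_from_anchors(anchors), _orders_from_anchors(anchors)
        )
        assert len(blocks) == 1 and len(blocks[0]) == 5

    def test_four_anchors_below_minimum(self):
        anchors = [(10 + k, 210 + k) for k in range(4)]
        assert detect_collinear_blocks(
            _hits_from_anchors(anchors), _orders_from_anchors(anchors)
        ) == []

    def test_large_gap_splits_chain(self):
        # 6 anchors with a 30-rank gap: two fragments of 3, neither >= 5
        anchors = [(k, 100 + k) for k in range(3)]
        anchors += [(33 + k, 133 + k) for k in range(3)]
        assert detect_collinear_blocks(
            _hits_from_anchors(anchors), _orders_from_anchors(anchors)
        ) == []

    def test_inverted_block_detected(self):
        anchors = [(10 + k, 300 - k) for k in range(6)]
        blocks = detect_collinear_blocks(
            _hits_from_anchors(anchors), _orders_from_anchors(anchors)
        )
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(5, 31))
            anchors = [tuple(map(int, rng.integers(0, 40, size=2))) for _ in range(n)]
            anchors = list({a for a in anchors})
            blocks = detect_collinear_blocks(
                _hits_from_anchors(anchors), _orders_from_anchors(anchors),
                min_anchors=1, max_rank_gap=25,
            )
            got = len(blocks[0]) if blocks else 0
            assert got == _brute_force_longest_chain(anchors, 25)


class TestClassification:
    def _single_chrom_orders(self, ranks):
        return {f"g{r}": ("c1", r) for r in ranks}

    def test_adjacent_ranks_are_tandem(self):
        orders = self._single_chrom_orders(range(20))
        hits = [SimilarityHit("g7", "g8", 300.0, 70.0, 100)]
        pairs = classify_duplications(hits, [], orders)
        assert pairs[0].dup_type == "tandem"

    def test_close_ranks_are_proximal(self):
        orders = self._single_chrom_orders(range(20))
        hits = [SimilarityHit("g7", "g14", 300.0, 70.0, 100)]
        pairs = classify_duplications(hits, [], orders)
        assert pairs[0].dup_type == "proximal"

    def test_beyond_gap_is_dispersed(self):
        orders = self._single_chrom_orders(range(30))
        hits = [SimilarityHit("g2", "g25", 300.0, 70.0, 100)]
        pairs = classify_duplications(hits, [], orders)
        assert pairs[0].dup_type == "dispersed"

    def test_types_mutually_exclusive_and_exhaustive(self, dataset, paralog_hit_sets):
        from pprdup import pipeline

        res = pipeline.run_duptypes(dataset.genome_a, paralog_hit_sets["A"])
        seen = set()
        for p in res.pairs:
            key = frozenset((p.gene_1, p.gene_2))
            assert key not in seen
            seen.add(key)
            assert p.dup_type in ("WGD", "tandem", "proximal", "dispersed")


class TestProportions:
    def test_dispersed_fraction_arithmetic(self):
        orders = {}
        hits = []
        # 88 dispersed pairs and 12 tandem pairs over disjoint gene sets
        for i in range(88):
            orders[f"d{i}a"] = ("c1", 2 * i)
            orders[f"d{i}b"] = ("c2", 2 * i)
            hits.append(SimilarityHit(f"d{i}a", f"d{i}b", 300.0, 70.0, 100))
        for i in range(6):
            orders[f"t{i}a"] = ("c3", 200 + 2 * i)
            orders[f"t{i}b"] = ("c3", 200 + 2 * i + 1)
            hits.append(SimilarityHit(f"t{i}a", f"t{i}b", 300.0, 70.0, 100))
        pairs = classify_duplications(hits, [], orders)
        props = dup_type_proportions(pairs, orders.keys())
        assert props["dispersed"] == pytest.approx(176 / 188)
        assert props.sum() == pytest.approx(1.0)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            dup_type_proportions([], [])


class TestTruthRecovery:
    def test_planted_labels_recovered(self, dataset, paralog_hit_sets):
        from pprdup import pipeline

        for lab in ("A", "B"):
            res = pipeline.run_duptypes(dataset.genome(lab), paralog_hit_sets[lab])
            label_map = {
                frozenset((p.gene_1, p.gene_2)): p.dup_type for p in res.pairs
            }
            for g1, g2, want in dataset.truth.dup_pairs[lab]:
                assert label_map.get(frozenset((g1, g2))) == want, (g1, g2, want)

    def test_gene_label_priority(self):
        from pprdup.duptypes import DuplicationPair

        pairs = [DuplicationPair("g", "h", "dispersed"),
                 DuplicationPair("g", "k", "tandem")]
        assert gene_labels(pairs)["g"] == "tandem"
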