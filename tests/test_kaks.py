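"""NG86 Ka/Ks estimation against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from pprdup.kaks import (
    KsRecord, classify_origin, codon_align, codon_differences, codon_sites,
    ks_ng86, ks_pair,
)
from pprdup.simulate import backtranslate, evolve_cds, random_protein

_TABLE = dict(standard_dna_table.forward_table)
for _s in standard_dna_table.stop_codons:
    _TABLE[_s] = "*"


def _oracle_sites(codon):
    """Independent per-codon site count by exhaustive enumeration."""
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _TABLE[alt] == _TABLE[codon]:
                s += 1 / 3
    return s, 3 - s


def _oracle_diffs(ca, cb):
    """Pathway enumeration with stop-avoiding minimal paths."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(pos):
        cur, sd, nd, ok = ca, 0, 0, True
        for step, p in enumerate(order):
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if _TABLE[nxt] == "*" and step < len(order) - 1:
                ok = False
                break
            sd += _TABLE[nxt] == _TABLE[cur]
            nd += _TABLE[nxt] != _TABLE[cur]
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        for order in itertools.permutations(pos):
            cur, sd, nd = ca, 0, 0
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                sd += _TABLE[nxt] == _TABLE[cur]
                nd += _TABLE[nxt] != _TABLE[cur]
                cur = nxt
            paths.append((sd, nd))
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def _oracle_ng86(cols):
    sa = sb = sd = nd = 0.0
    for ca, cb in cols:
        sa += _oracle_sites(ca)[0]
        sb += _oracle_sites(cb)[0]
        d = _oracle_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    s = (sa + sb) / 2
    n = 3 * len(cols) - s
    ps = sd / s if s else 0.0
    pn = nd / n if n else 0.0
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0
    return jc(ps), jc(pn)


NON_STOP = sorted(c for c, aa in _TABLE.items() if aa != "*")


class TestNG86:
    def test_worked_example_glycine_codons(self):
        # nine GGT codons vs eight GGT plus one GGC: one synonymous change
        cols = [("GGT", "GGT")] * 8 + [("GGT", "GGC")]
        r = ks_ng86(cols)
        assert r.s_sites == pytest.approx(9.0)
        assert r.ka == 0.0
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 / 27), abs=1e-6)
        assert round(r.ks, 4) == 0.1203

    def test_identical_sequences_zero(self):
        cols = [(c, c) for c in NON_STOP[:20]]
        r = ks_ng86(cols)
        assert r.ks == 0.0 and r.ka == 0.0

    def test_site_counts_partition_three_per_codon(self):
        for codon in NON_STOP:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(_oracle_sites(codon))

    def test_pathway_averaging_matches_enumeration(self):
        for ca in NON_STOP[::7]:
            for cb in NON_STOP[::5]:
                assert codon_differences(ca, cb) == pytest.approx(
                    _oracle_diffs(ca, cb)
                )

    def test_random_ten_codon_pairs_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            cols = []
            for _ in range(10):
                ca = NON_STOP[rng.integers(len(NON_STOP))]
                # mutate up to 2 positions to keep saturation away
                cb = list(ca)
                for p in rng.choice(3, size=rng.integers(0, 3), replace=False):
                    cb[p] = "ACGT"[rng.integers(4)]
                cb = "".join(cb)
                if _TABLE[cb] == "*":
                    cb = ca
                cols.append((ca, cb))
            r = ks_ng86(cols)
            want_ks, want_ka = _oracle_ng86(cols)
            if not r.saturated:
                assert r.ks == pytest.approx(want_ks, abs=1e-9)
                assert r.ka == pytest.approx(want_ka, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(22)
        prot = random_protein(rng, 120)
        cds_a = backtranslate(prot, rng)
        cds_b = evolve_cds(cds_a, 0.1, 0.03, rng)
        prot_b = str(Seq(cds_b).translate())[:-1]
        seqs = {"a": cds_a, "b": cds_b}
        prots = {"a": prot, "b": prot_b}
        fwd = ks_pair("a", "b", prots, seqs)
        rev = ks_pair("b", "a", prots, seqs)
        assert fwd.ks == pytest.approx(rev.ks, abs=1e-12)

    def test_saturation_flagged(self):
        # wildly different codons across the board
        cols = [("GGG", "CCC")] * 30
        r = ks_ng86(cols)
        assert r.saturated


class TestCodonAlign:
    def test_identical_cds_keeps_all_codons(self):
        rng = np.random.default_rng(23)
        prot = random_protein(rng, 50)
        cds = backtranslate(prot, rng)
        cols = codon_align(prot, prot, cds, cds)
        assert len(cols) == 50
        assert all(a == b for a, b in cols)

    def test_internal_deletion_removes_columns(self):
        rng = np.random.default_rng(24)
        prot = random_protein(rng, 60)
        short = prot[:30] + prot[32:]  # two-residue internal deletion
        cds = backtranslate(prot, rng)
        cds_short = cds[:90] + cds[96:]
        cols = codon_align(prot, short, cds, cds_short)
        assert len(cols) == 58

    def test_back_translation_consistent(self):
        rng = np.random.default_rng(25)
        prot = random_protein(rng, 40)
        cds = backtranslate(prot, rng)
        cols = codon_align(prot, prot, cds, cds)
        rebuilt = "".join(a for a, _ in cols)
        assert str(Seq(rebuilt).translate()) == prot

    def test_translation_mismatch_rejected(self):
        with pytest.raises(ValueError):
            codon_align("MK", "MK", "ATGAAA", "ATGGGG")


class TestOriginCalls:
    def _rec(self, g1, g2, ks):
        return KsRecord(g1, g2, ks, ks / 5, 100.0, 200.0, 100)

    def test_rule_application(self):
        assert classify_origin(
            "g", [self._rec("g", "p", 0.05)], 0.10
        ).origin == "new_duplication"
        assert classify_origin(
            "g", [self._rec("g", "p", 0.50)], 0.10
        ).origin == "ancestral_loss"
        assert classify_origin("g", [], 0.10).origin == "unresolved"

    def test_minimum_over_paralogs(self):
        recs = [self._rec("g", "p1", 0.5), self._rec("g", "p2", 0.04),
                self._rec("x", "y", 0.001)]  # unrelated record ignored
        call = classify_origin("g", recs, 0.10)
        assert call.origin == "new_duplication"
        assert call.min_paralog_ks == pytest.approx(0.04)

    def test_divergence_recovery_on_long_sequences(self):
        # Ks estimates track the planted synonymous divergence
        rng = np.random.default_rng(26)
        for d in (0.05, 0.2):
            ests = []
            for _ in range(10):
                prot = random_protein(rng, 500)
                cds = backtranslate(prot, rng)
                other = evolve_cds(cds, d, d * 0.2, rng)
                prot_b = str(Seq(other).translate())[:-1]
                rec = ks_pair("a", "b", {"a": prot, "b": prot_b},
                              {"a": cds, "b": other})
                ests.append(rec.ks)
            assert np.mean(ests) == pytest.approx(d, rel=0.2)
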