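"""TPM computation, level binning, and sister-pair divergence classes."""

import numpy as np
import pandas as pd
import pytest

from pprdup.expression import (
    CountMatrix, PairTestResult, bin_level, classify_pair, compute_tpm,
)
from pprdup.expression import test_pairs as _pair_tests
from pprdup.simulate import ExpressionParams, simulate_counts


def _count_matrix(counts: dict, tissues=("root", "leaf"), reps=3):
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(reps)]
    df = pd.DataFrame(counts, index=samples).T
    meta = pd.DataFrame(
        [(s, s.rsplit("_", 1)[0], int(s.rsplit("_", 1)[1])) for s in samples],
        columns=["sample", "tissue", "replicate"],
    ).set_index("sample")
    return CountMatrix(df, meta)


class TestTPM:
    def test_forced_arithmetic(self):
        cm = _count_matrix({"g1": [10] * 6, "g2": [20] * 6})
        tpm = compute_tpm(cm, {"g1": 1000, "g2": 2000})
        # equal per-kb rates -> both genes at half a million
        assert tpm.tpm.iloc[:, 0].tolist() == [500_000.0, 500_000.0]

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        cm = _count_matrix({f"g{i}": rng.integers(0, 500, 6).tolist()
                            for i in range(20)})
        tpm = compute_tpm(cm, {f"g{i}": int(rng.integers(500, 5000))
                               for i in range(20)})
        assert np.allclose(tpm.tpm.sum(axis=0), 1e6)

    def test_scale_invariance(self):
        counts = {"g1": [10, 11, 12, 5, 6, 7], "g2": [100, 90, 95, 50, 60, 55]}
        cm = _count_matrix(counts)
        doubled = _count_matrix({k: [2 * x for x in v] for k, v in counts.items()})
        lengths = {"g1": 900, "g2": 2400}
        assert np.allclose(
            compute_tpm(cm, lengths).tpm, compute_tpm(doubled, lengths).tpm
        )

    def test_all_zero_sample_rejected(self):
        cm = _count_matrix({"g1": [0, 1, 1, 1, 1, 1], "g2": [0, 2, 2, 2, 2, 2]})
        with pytest.raises(ValueError):
            compute_tpm(cm, {"g1": 1000, "g2": 1000})


class TestBinLevel:
    @pytest.mark.parametrize(
        "tpm,level",
        [
            (50.0, "very_high"), (120.0, "very_high"),
            (49.999, "high"), (10.0, "high"),
            (9.999, "moderate"), (2.0, "moderate"),
            (1.999, "low"), (0.1, "low"),
            (0.0999, "very_low"), (0.05, "very_low"), (1e-9, "very_low"),
            (0.0, "none"),
        ],
    )
    def test_bin_boundaries(self, tpm, level):
        assert bin_level(tpm) == level

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_level(-0.1)


def _result(pair, tissue, call):
    lfc = {"copy1_higher": 2.0, "copy2_higher": -2.0, "no_difference": 0.0}[call]
    padj = 0.001 if call != "no_difference" else 0.8
    return PairTestResult(pair, tissue, lfc, padj, call)


class TestClassifyPair:
    PAIR = ("c1", "c2")

    def test_aed_two_wins_no_losses(self):
        res = [_result(self.PAIR, "root", "copy1_higher"),
               _result(self.PAIR, "seedling", "copy1_higher"),
               _result(self.PAIR, "leaf", "no_difference"),
               _result(self.PAIR, "panicle", "no_difference")]
        got = classify_pair(self.PAIR, res)
        assert got.expr_class == "AED" and got.higher_copy == "c1"

    def test_opposite_wins_is_sub_neo(self):
        res = [_result(self.PAIR, "root", "copy1_higher"),
               _result(self.PAIR, "panicle", "copy2_higher")]
        assert classify_pair(self.PAIR, res).expr_class == "sub_neo"

    def test_single_win_is_no_difference(self):
        res = [_result(self.PAIR, "root", "copy1_higher")]
        assert classify_pair(self.PAIR, res).expr_class == "no_difference"

    def test_invariant_to_tissue_order(self):
        res = [_result(self.PAIR, t, c) for t, c in
               [("root", "copy1_higher"), ("leaf", "no_difference"),
                ("seedling", "copy1_higher"), ("panicle", "no_difference")]]
        fwd = classify_pair(self.PAIR, res)
        rev = classify_pair(self.PAIR, res[::-1])
        assert (fwd.expr_class, fwd.higher_copy) == (rev.expr_class, rev.higher_copy)

    def test_exact_two_switch(self):
        res = [_result(self.PAIR, t, "copy1_higher")
               for t in ("root", "leaf", "seedling")]
        assert classify_pair(self.PAIR, res).expr_class == "AED"
        assert classify_pair(self.PAIR, res, exact=True).expr_class == "no_difference"


def _run_recovery(n_seeds, cls, fold=4.0):
    """Simulate planted pairs and count correct classifications."""
    params = ExpressionParams(planted_fold=fold)
    correct = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(10_000 + seed)
        genes = [f"bg{i}" for i in range(40)] + ["c1", "c2"]
        cm, truth = simulate_counts(genes, [("c1", "c2", cls)], params, rng)
        lengths = {g: 1500 for g in genes}
        tpm = compute_tpm(cm, lengths)
        tests = _pair_tests([("c1", "c2")], tpm, cm.meta)
        got = classify_pair(("c1", "c2"), tests)
        want = truth[0]
        if got.expr_class == want[2] and got.higher_copy == want[3]:
            correct += 1
    return correct


class TestRecovery:
    def test_identical_counts_no_difference(self):
        cm = _count_matrix({"c1": [50] * 6, "c2": [50] * 6})
        tpm = compute_tpm(cm, {"c1": 1000, "c2": 1000})
        tests = _pair_tests([("c1", "c2")], tpm, cm.meta)
        assert classify_pair(("c1", "c2"), tests).expr_class == "no_difference"

    @pytest.mark.parametrize("cls", ["AED", "sub_neo", "no_difference"])
    def test_planted_classes_recovered(self, cls):
        assert _run_recovery(20, cls) >= 18

    def test_sub_threshold_fold_change_not_called(self):
        # a planted 1.2-fold asymmetry stays below the 2-fold decision rule
        params = ExpressionParams(planted_fold=1.2)
        quiet = 0
        for seed in range(20):
            rng = np.random.default_rng(20_000 + seed)
            genes = [f"bg{i}" for i in range(40)] + ["c1", "c2"]
            cm, _ = simulate_counts(genes, [("c1", "c2", "AED")], params, rng)
            tpm = compute_tpm(cm, {g: 1500 for g in genes})
            tests = _pair_tests([("c1", "c2")], tpm, cm.meta)
            if classify_pair(("c1", "c2"), tests).expr_class == "no_difference":
                quiet += 1
        assert quiet >= 18

    def test_zero_mean_config_gives_zero_matrix(self):
        rng = np.random.default_rng(1)
        cm, _ = simulate_counts(
            ["g1", "g2"], [], ExpressionParams(), rng,
            base_means={"g1": 0.0, "g2": 0.0},
        )
        assert (cm.counts.to_numpy() == 0).all()


class TestClassesPartition:
    def test_three_classes_partition_pairs(self, dataset):
        from pprdup import pipeline

        for lab in ("A", "B"):
            pairs = [(g1, g2) for g1, g2, _, _ in
                     dataset.truth.expression_classes[lab]]
            er = pipeline.run_expression(
                dataset.genome(lab), dataset.counts[lab], pairs
            )
            assert len(er.classes) == len(pairs)
            assert all(
                c.expr_class in ("AED", "sub_neo", "no_difference")
                for c in er.classes
            )
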