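"""TPM, expression-level binning, and sister-duplicate divergence classes.

Replicated per-tissue read counts are normalised to transcripts per million
(TPM) over summed exon length. Duplicate pairs born of segmental
duplication are compared tissue by tissue with a moderated t-test on
log2(TPM+1): the per-pair variance is shrunk toward the transcriptome-wide
replicate variance (empirical-Bayes moderation in the limma spirit, which
recovers the power that count-model tools obtain by sharing dispersion
across genes at three replicates), and p-values are Benjamini–Hochberg
adjusted over every pair x tissue test of the run. A copy is called higher
only when the mean-TPM fold change exceeds 2 and the adjusted p-value is
below 0.05. Pairs are then classified:

* sub_neo  — each copy is called higher in at least one tissue
  (expression sub-/neo-functionalization);
* AED      — one copy is called higher in >= 2 tissues and is never called
  lower (asymmetrically expressed duplicates);
* no_difference — everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TISSUES = ("root", "leaf", "seedling", "panicle")
FC_THRESHOLD = 2.0
ALPHA = 0.05
_FC_PSEUDO = 0.1  # TPM pseudocount for fold changes at near-zero means


@dataclass
class CountMatrix:
    """genes x samples integer counts with tissue/replicate sample labels."""

    counts: pd.DataFrame
    meta: pd.DataFrame  # index = sample, columns: tissue, replicate

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("counts columns and meta index differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.meta["tissue"]))

    def samples_for(self, tissue: str) -> list[str]:
        return list(self.meta.index[self.meta["tissue"] == tissue])


@dataclass
class TPMMatrix:
    tpm: pd.DataFrame
    effective_length: pd.Series

    def __post_init__(self) -> None:
        sums = self.tpm.sum(axis=0)
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValueError("TPM columns do not sum to 1e6")


@dataclass(frozen=True)
class PairTestResult:
    pair: tuple[str, str]
    tissue: str
    log2_fold_change: float
    p_adj: float
    call: str  # copy1_higher | copy2_higher | no_difference


@dataclass(frozen=True)
class PairExpressionClass:
    pair: tuple[str, str]
    expr_class: str  # AED | sub_neo | no_difference
    higher_copy: str | None = None


def compute_tpm(
    counts: CountMatrix, gene_lengths: Mapping[str, int]
) -> TPMMatrix:
    """TPM per sample: (count / length_kb) scaled to a column sum of 1e6."""
    lengths = pd.Series(
        {g: gene_lengths[g] for g in counts.counts.index}, dtype=float
    )
    if (lengths <= 0).any():
        raise ValueError("non-positive effective gene length")
    rate = counts.counts.div(lengths / 1e3, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise ValueError(f"all-zero samples: {bad}")
    return TPMMatrix(rate.div(denom, axis=1) * 1e6, lengths)


LEVELS = ("very_high", "high", "moderate", "low", "very_low", "none")


def bin_level(tpm_value: float) -> str:
    """Five-level expression bin (plus 'none' for exactly zero).

    very high: TPM >= 50; high: 10 <= TPM < 50; moderate: 2 <= TPM < 10;
    low: 0.1 <= TPM < 2; very low: 0 < TPM < 0.1.
    """
    if tpm_value < 0:
        raise ValueError("negative TPM")
    if tpm_value >= 50:
        return "very_high"
    if tpm_value >= 10:
        return "high"
    if tpm_value >= 2:
        return "moderate"
    if tpm_value >= 0.1:
        return "low"
    if tpm_value > 0:
        return "very_low"
    return "none"


MODERATION_PRIOR_DF = 10.0


def _prior_variance(tpm: TPMMatrix, meta: pd.DataFrame) -> float:
    """Mean within-tissue replicate variance of log2(TPM+1) over all genes."""
    log_tpm = np.log2(tpm.tpm.to_numpy(dtype=float) + 1.0)
    variances = []
    for tissue in dict.fromkeys(meta["tissue"]):
        cols = np.nonzero((meta["tissue"] == tissue).to_numpy())[0]
        if len(cols) >= 2:
            variances.append(np.var(log_tpm[:, cols], axis=1, ddof=1))
    if not variances:
        return 0.0
    return float(np.mean(np.concatenate(variances)))


def _moderated_p(
    x: np.ndarray, y: np.ndarray, s0_sq: float, prior_df: float
) -> float:
    n1, n2 = len(x), len(y)
    resid_df = (n1 - 1) + (n2 - 1)
    pooled = (
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / resid_df
        if resid_df > 0
        else 0.0
    )
    s_mod = (prior_df * s0_sq + resid_df * pooled) / (prior_df + resid_df)
    if s_mod == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    t = (np.mean(x) - np.mean(y)) / np.sqrt(s_mod * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), prior_df + resid_df))


def test_pairs(
    pairs: Sequence[tuple[str, str]],
    tpm: TPMMatrix,
    meta: pd.DataFrame,
    tissues: Sequence[str] | None = None,
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
    prior_df: float = MODERATION_PRIOR_DF,
) -> list[PairTestResult]:
    """Per-tissue differential tests for sister pairs, BH-adjusted jointly.

    The variance of each pair x tissue contrast is moderated toward the
    replicate variance of the whole TPM matrix with ``prior_df`` prior
    degrees of freedom.
    """
    if tissues is None:
        tissues = list(dict.fromkeys(meta["tissue"]))
    s0_sq = _prior_variance(tpm, meta)
    rows = []
    for pair in pairs:
        g1, g2 = pair
        for tissue in tissues:
            samples = list(meta.index[meta["tissue"] == tissue])
            x = tpm.tpm.loc[g1, samples].to_numpy(dtype=float)
            y = tpm.tpm.loc[g2, samples].to_numpy(dtype=float)
            p = _moderated_p(np.log2(x + 1.0), np.log2(y + 1.0), s0_sq, prior_df)
            lfc = float(
                np.log2((x.mean() + _FC_PSEUDO) / (y.mean() + _FC_PSEUDO))
            )
            rows.append((pair, tissue, lfc, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    out = []
    log_fc_min = np.log2(fc_threshold)
    for (pair, tissue, lfc, _), padj in zip(rows, p_adj):
        if padj < alpha and abs(lfc) > log_fc_min:
            call = "copy1_higher" if lfc > 0 else "copy2_higher"
        else:
            call = "no_difference"
        out.append(PairTestResult(pair, tissue, lfc, float(padj), call))
    return out


def classify_pair(
    pair: tuple[str, str],
    results: Sequence[PairTestResult],
    min_aed_tissues: int = 2,
    exact: bool = False,
) -> PairExpressionClass:
    """Divergence class of one pair from its per-tissue test results.

    Evaluation order is sub_neo, then AED, then no_difference; the result
    does not depend on tissue order. ``exact`` switches the AED rule from
    ">= min_aed_tissues" to exact equality.
    """
    mine = [r for r in results if r.pair == pair]
    n1 = sum(r.call == "copy1_higher" for r in mine)
    n2 = sum(r.call == "copy2_higher" for r in mine)
    if n1 >= 1 and n2 >= 1:
        return PairExpressionClass(pair, "sub_neo")
    for wins, losses, copy in ((n1, n2, pair[0]), (n2, n1, pair[1])):
        hit = wins == min_aed_tissues if exact else wins >= min_aed_tissues
        if hit and losses == 0:
            return PairExpressionClass(pair, "AED", copy)
    return PairExpressionClass(pair, "no_difference")


def classify_pairs(
    pairs: Sequence[tuple[str, str]],
    results: Sequence[PairTestResult],
    min_aed_tissues: int = 2,
    exact: bool = False,
) -> list[PairExpressionClass]:
    return [classify_pair(p, results, min_aed_tissues, exact) for p in pairs]


def level_table(tpm: TPMMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression level per tissue (bin of the mean TPM)."""
    out = {}
    for tissue in dict.fromkeys(meta["tissue"]):
        samples = list(meta.index[meta["tissue"] == tissue])
        out[tissue] = tpm.tpm[samples].mean(axis=1).map(bin_level)
    return pd.DataFrame(out)


def read_counts_tsv(path: str) -> CountMatrix:
    """Counts TSV with a gene_id column; samples named <tissue>_<replicate>."""
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    meta = pd.DataFrame(
        [(c, c.rsplit("_", 1)[0], int(c.rsplit("_", 1)[1])) for c in df.columns],
        columns=["sample", "tissue", "replicate"],
    ).set_index("sample")
    return CountMatrix(df, meta)


def write_counts_tsv(cm: CountMatrix, path: str) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
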