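"""Within-genome duplicate classification: WGD / tandem / proximal / dispersed.

Paralog pairs (from the within-genome similarity search) are typed with the
usual collinearity-based scheme: anchors inside a collinear block are
whole-genome-duplication (WGD) pairs; same-chromosome pairs at adjacent gene
ranks are tandem; pairs within a small rank gap are proximal; everything
else is dispersed. Priority when a pair or gene qualifies for several types
is WGD > tandem > proximal > dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Genome
from .homology import SimilarityHit

DUP_TYPES = ("WGD", "tandem", "proximal", "dispersed")
_PRIORITY = {t: i for i, t in enumerate(DUP_TYPES)}


@dataclass(frozen=True)
class CollinearBlock:
    anchor_pairs: tuple[tuple[str, str], ...]
    chromosomes: tuple[str, str]
    orientation: str  # same | inverted

    def __len__(self) -> int:
        return len(self.anchor_pairs)


@dataclass(frozen=True)
class DuplicationPair:
    gene_1: str
    gene_2: str
    dup_type: str
    ks: float | None = None

    def __post_init__(self) -> None:
        if self.dup_type not in DUP_TYPES:
            raise ValueError(f"bad duplication type {self.dup_type}")


def gene_orders(genome: Genome) -> dict[str, tuple[str, int]]:
    return {g.gene_id: (g.chromosome, g.rank) for g in genome.genes}


def _canonical_pairs(
    hits: Iterable[SimilarityHit], orders: Mapping[str, tuple[str, int]]
) -> list[tuple[str, str]]:
    """Unique unordered paralog pairs, canonically ordered by (chrom, rank)."""
    seen = set()
    out = []
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        a, b = sorted(
            (h.query_id, h.subject_id), key=lambda g: (orders[g][0], orders[g][1])
        )
        if (a, b) not in seen:
            seen.add((a, b))
            out.append((a, b))
    return out


def _longest_chain(
    anchors: list[tuple[int, int, int]], max_gap: int, inverted: bool
) -> list[int]:
    """Indices of the longest monotone anchor chain (DP, O(n^2)).

    Anchors are (rank_i, rank_j, index) sorted by rank_i. A step is legal
    when both rank gaps are in 1..max_gap (rank_j decreasing for inverted).
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ri, rj, _ = anchors[i]
        for k in range(i):
            rk_i, rk_j, _ = anchors[k]
            di = ri - rk_i
            dj = (rk_j - rj) if inverted else (rj - rk_j)
            if 1 <= di <= max_gap and 1 <= dj <= max_gap:
                if best_len[k] + 1 > best_len[i]:
                    best_len[i] = best_len[k] + 1
                    prev[i] = k
    end = max(range(n), key=lambda i: best_len[i]) if n else -1
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    chain.reverse()
    return chain


def detect_collinear_blocks(
    paralog_hits: Iterable[SimilarityHit],
    orders: Mapping[str, tuple[str, int]],
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Maximal collinear anchor chains among within-genome paralog pairs.

    Chains are extracted greedily per chromosome pair and orientation:
    repeatedly take the longest monotone chain with consecutive rank gaps
    <= ``max_rank_gap`` on both chromosomes, keep it if it has at least
    ``min_anchors`` anchors, and remove its anchors.
    """
    pairs = _canonical_pairs(paralog_hits, orders)
    by_chrom: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in pairs:
        ca, ra = orders[a]
        cb, rb = orders[b]
        by_chrom.setdefault((ca, cb), []).append((ra, rb, a, b))

    blocks: list[CollinearBlock] = []
    for (ca, cb), recs in sorted(by_chrom.items()):
        remaining = sorted(recs)
        while True:
            anchors = [(ra, rb, i) for i, (ra, rb, _, _) in enumerate(remaining)]
            best_chain: list[int] = []
            best_orient = "same"
            for inverted in (False, True):
                chain = _longest_chain(anchors, max_rank_gap, inverted)
                if len(chain) > len(best_chain):
                    best_chain = chain
                    best_orient = "inverted" if inverted else "same"
            if len(best_chain) < min_anchors:
                break
            chosen = [anchors[i][2] for i in best_chain]
            blocks.append(
                CollinearBlock(
                    tuple((remaining[i][2], remaining[i][3]) for i in chosen),
                    (ca, cb),
                    best_orient,
                )
            )
            used = set(chosen)
            remaining = [r for i, r in enumerate(remaining) if i not in used]
    return blocks


def classify_duplications(
    paralog_hits: Iterable[SimilarityHit],
    blocks: Sequence[CollinearBlock],
    orders: Mapping[str, tuple[str, int]],
    proximal_max_gap: int = 10,
) -> list[DuplicationPair]:
    """Assign one duplication type to every paralog pair."""
    anchor_set = set()
    for blk in blocks:
        for a, b in blk.anchor_pairs:
            anchor_set.add(frozenset((a, b)))
    out = []
    for a, b in _canonical_pairs(paralog_hits, orders):
        ca, ra = orders[a]
        cb, rb = orders[b]
        if frozenset((a, b)) in anchor_set:
            dup_type = "WGD"
        elif ca == cb and abs(ra - rb) == 1:
            dup_type = "tandem"
        elif ca == cb and 2 <= abs(ra - rb) <= proximal_max_gap:
            dup_type = "proximal"
        else:
            dup_type = "dispersed"
        out.append(DuplicationPair(a, b, dup_type))
    return out


def gene_labels(pairs: Iterable[DuplicationPair]) -> dict[str, str]:
    """Per-gene duplication label: highest-priority type among its pairs."""
    labels: dict[str, str] = {}
    for p in pairs:
        for g in (p.gene_1, p.gene_2):
            cur = labels.get(g)
            if cur is None or _PRIORITY[p.dup_type] < _PRIORITY[cur]:
                labels[g] = p.dup_type
    return labels


def dup_type_proportions(
    pairs: Iterable[DuplicationPair], gene_set: Iterable[str]
) -> pd.Series:
    """Per-type proportions of duplicated genes within ``gene_set``.

    Proportions are over duplicated genes of the set (genes of the set with
    at least one paralog pair) and sum to 1.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    labels = gene_labels(pairs)
    counts = {t: 0 for t in DUP_TYPES}
    for g in genes:
        if g in labels:
            counts[labels[g]] += 1
    total = sum(counts.values())
    if total == 0:
        return pd.Series({t: 0.0 for t in DUP_TYPES}, name="proportion")
    return pd.Series({t: counts[t] / total for t in DUP_TYPES}, name="proportion")


def pair_table(pairs: Sequence[DuplicationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_1, p.gene_2, p.dup_type, p.ks) for p in pairs],
        columns=["gene_1", "gene_2", "dup_type", "ks"],
    )
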