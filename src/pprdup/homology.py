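"""Protein similarity search, reciprocal best hits, and local synteny.

Orthology between the two genomes is called with a reciprocal-best-hit (RBH)
strategy over genome-wide protein similarity, followed by a local-synteny
filter: a candidate pair passes when, on each side of the query gene, at
least one of the five nearest neighbours has an RBH partner lying near the
candidate's partner gene. The similarity search is a built-in global
aligner (BLOSUM62, affine gaps 11/1) with a shared-k-mer prefilter; tabular
results from an external search tool can be substituted via
:func:`read_tabular_hits`.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import Genome

DEFAULT_SCORE_THRESHOLD = 50.0
_PREFILTER_K = 5
_PREFILTER_MIN_SHARED = 2


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    identity: float  # % identical aligned columns
    aligned_length: int  # alignment columns (gaps included)

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity {self.identity} out of [0, 100]")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    rbh: bool
    synteny_pass: bool
    status: str  # shared | unanchored | non_syntenic

    def __post_init__(self) -> None:
        if self.synteny_pass and not self.rbh:
            raise ValueError("synteny_pass requires rbh")
        if self.status not in ("shared", "unanchored", "non_syntenic"):
            raise ValueError(f"bad status {self.status}")


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def align_stats(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[float, float, int]:
    """(score, % identity, alignment columns) of the best global alignment."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = aln.length
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return float(aln.score), identity, columns


def _kmer_set(seq: str, k: int = _PREFILTER_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(
    proteins_a: Mapping[str, str], proteins_b: Mapping[str, str]
) -> dict[str, list[str]]:
    """Subjects sharing >= 2 5-mers with each query (speed prefilter only)."""
    index: dict[str, list[str]] = {}
    for sid, seq in proteins_b.items():
        for kmer in _kmer_set(seq):
            index.setdefault(kmer, []).append(sid)
    out: dict[str, list[str]] = {}
    for qid, seq in proteins_a.items():
        counts: Counter[str] = Counter()
        for kmer in _kmer_set(seq):
            for sid in index.get(kmer, ()):
                counts[sid] += 1
        out[qid] = [s for s, n in counts.items() if n >= _PREFILTER_MIN_SHARED]
    return out


def all_vs_all(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    within: bool = False,
) -> list[SimilarityHit]:
    """All-vs-all protein similarity, best-first per query.

    ``within=True`` marks a within-genome self-comparison: self-hits are
    excluded. Empty sequences are rejected.
    """
    for name, prots in (("A", proteins_a), ("B", proteins_b)):
        if not prots:
            raise ValueError(f"empty protein set {name}")
        for pid, seq in prots.items():
            if not seq:
                raise ValueError(f"empty sequence for {pid}")
    aligner = make_aligner()
    candidates = _candidate_pairs(proteins_a, proteins_b)
    hits: list[SimilarityHit] = []
    for qid in sorted(proteins_a):
        qhits = []
        for sid in candidates.get(qid, ()):
            if within and sid == qid:
                continue
            score, identity, columns = align_stats(
                aligner, proteins_a[qid], proteins_b[sid]
            )
            if score >= score_threshold:
                qhits.append(SimilarityHit(qid, sid, score, identity, columns))
        qhits.sort(key=lambda h: (-h.score, h.subject_id))
        hits.extend(qhits)
    return hits


def read_tabular_hits(path: str | os.PathLike) -> list[SimilarityHit]:
    """Read 12-column tabular search output (outfmt-6-like) as hits."""
    cols = [
        "query_id", "subject_id", "identity", "aligned_length", "mismatches",
        "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "score",
    ]
    df = pd.read_csv(str(path), sep="\t", names=cols, comment="#")
    return [
        SimilarityHit(
            str(r.query_id), str(r.subject_id), float(r.score),
            float(r.identity), int(r.aligned_length),
        )
        for r in df.itertuples()
    ]


def best_hits(hits: Iterable[SimilarityHit]) -> dict[str, str]:
    """Unique best subject per query; queries with tied best scores dropped."""
    best: dict[str, SimilarityHit] = {}
    tied: set[str] = set()
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.score > cur.score:
            best[h.query_id] = h
            tied.discard(h.query_id)
        elif h.score == cur.score and h.subject_id != cur.subject_id:
            tied.add(h.query_id)
    return {q: h.subject_id for q, h in best.items() if q not in tied}


def reciprocal_best_hits(
    hits_ab: Iterable[SimilarityHit], hits_ba: Iterable[SimilarityHit]
) -> list[tuple[str, str]]:
    """(a, b) pairs where each is the other's unique best hit."""
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    pairs.sort()
    return pairs


def _window_ranks(genome: Genome, gene_id: str, window: int) -> tuple[list[str], list[str]]:
    """Gene ids up to ``window`` ranks up- and downstream on the chromosome."""
    g = genome.gene(gene_id)
    chrom_genes = genome.genes_on(g.chromosome)
    up = [x.gene_id for x in chrom_genes[max(0, g.rank - window) : g.rank]]
    down = [x.gene_id for x in chrom_genes[g.rank + 1 : g.rank + 1 + window]]
    return up, down


def local_synteny_filter(
    gene_a: str,
    gene_b: str,
    genome_a: Genome,
    genome_b: Genome,
    rbh_map: Mapping[str, str],
    window: int = 5,
    strict: bool = True,
) -> bool:
    """Local-synteny test for one candidate ortholog pair.

    ``rbh_map`` maps genes of genome A to their genome-wide RBH partner in
    genome B (all genes, not only family members). The pair passes when each
    existing side of ``gene_a`` (up to ``window`` genes) contains a
    neighbour whose partner lies within ``window`` ranks of ``gene_b`` on
    gene_b's chromosome (``strict``), or merely has any partner
    (``strict=False``). A side with no genes at all (chromosome end) is
    waived.
    """
    gb = genome_b.gene(gene_b)
    b_ranks = {
        g.gene_id: g.rank for g in genome_b.genes_on(gb.chromosome)
    }
    up, down = _window_ranks(genome_a, gene_a, window)

    def side_ok(neighbors: list[str]) -> bool:
        if not neighbors:
            return True  # waived: the side does not exist
        for n in neighbors:
            partner = rbh_map.get(n)
            if partner is None:
                continue
            if not strict:
                return True
            if partner in b_ranks and abs(b_ranks[partner] - gb.rank) <= window:
                return True
        return False

    return side_ok(up) and side_ok(down)


def call_orthologs(
    genome_a: Genome,
    genome_b: Genome,
    rbh_pairs: Sequence[tuple[str, str]],
    focal_genes_a: Iterable[str] | None = None,
    window: int = 5,
    strict: bool = True,
    anchored_a: set[str] | None = None,
    anchored_b: set[str] | None = None,
) -> list[OrthologPair]:
    """Apply the synteny filter to RBH pairs and assign statuses.

    ``focal_genes_a`` restricts output to pairs whose A-side gene is in the
    set (e.g. the PPR family); the RBH map used for neighbourhood support is
    always the full genome-wide set. Pairs on unanchored sequences get
    status ``unanchored`` without applying the filter.
    """
    rbh_map = dict(rbh_pairs)
    out = []
    focal = set(focal_genes_a) if focal_genes_a is not None else None
    for a, b in rbh_pairs:
        if focal is not None and a not in focal:
            continue
        chrom_a = genome_a.gene(a).chromosome
        chrom_b = genome_b.gene(b).chromosome
        if (anchored_a is not None and chrom_a not in anchored_a) or (
            anchored_b is not None and chrom_b not in anchored_b
        ):
            out.append(OrthologPair(a, b, True, False, "unanchored"))
            continue
        ok = local_synteny_filter(a, b, genome_a, genome_b, rbh_map, window, strict)
        out.append(OrthologPair(a, b, True, ok, "shared" if ok else "non_syntenic"))
    return out


def partition(
    ppr_a: Iterable[str],
    ppr_b: Iterable[str],
    ortholog_pairs: Sequence[OrthologPair],
) -> tuple[list[OrthologPair], list[str], list[str]]:
    """Split both families into shared pairs and species-specific genes.

    A pair is reported (with its status) when both members are family
    members and they are RBHs. Specific genes are family members with no
    RBH partner inside the other family.
    """
    set_a, set_b = set(ppr_a), set(ppr_b)
    shared = [
        p for p in ortholog_pairs if p.gene_a in set_a and p.gene_b in set_b
    ]
    paired_a = {p.gene_a for p in shared}
    paired_b = {p.gene_b for p in shared}
    specific_a = sorted(set_a - paired_a)
    specific_b = sorted(set_b - paired_b)
    return shared, specific_a, specific_b


def ortholog_table(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_a, p.gene_b, p.rbh, p.synteny_pass, p.status) for p in pairs],
        columns=["gene_a", "gene_b", "rbh", "synteny_pass", "status"],
    )
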