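"""End-to-end orchestration of the genome-pair analysis.

Each function runs one stage of the comparison on an annotated genome pair
(real or simulated) and returns plain in-memory results; the numbered
scripts under ``analysis/`` are thin drivers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import duptypes, expression, family, homology, kaks, sdgenes
from .core import DomainHit, Genome
from .sddetect import SDParams, SegmentalDuplication, detect_sds


def classify_family(
    genome: Genome,
    domain_hits: Sequence[DomainHit],
    evalue_cutoff: float = 10.0,
) -> dict[str, family.PPRClassification]:
    """Identify and classify the PPR family of one genome.

    Hits at or above the E-value cutoff are discarded first (file readers
    apply the same cutoff; this keeps the in-memory path consistent).
    """
    models = {g.gene_id: g for g in genome.genes}
    kept = [h for h in domain_hits if h.evalue < evalue_cutoff]
    return family.classify_all(genome.proteins, kept, models)


@dataclass
class OrthologyResult:
    rbh_all: list[tuple[str, str]]
    pairs: list[homology.OrthologPair]
    shared: list[homology.OrthologPair] = field(default_factory=list)
    specific_a: list[str] = field(default_factory=list)
    specific_b: list[str] = field(default_factory=list)


def run_orthology(
    genome_a: Genome,
    genome_b: Genome,
    ppr_a: Sequence[str],
    ppr_b: Sequence[str],
    window: int = 5,
    strict: bool = True,
) -> OrthologyResult:
    """Genome-wide RBH, synteny filtering, and the shared/specific split."""
    hits_ab = homology.all_vs_all(genome_a.proteins, genome_b.proteins)
    hits_ba = homology.all_vs_all(genome_b.proteins, genome_a.proteins)
    rbh = homology.reciprocal_best_hits(hits_ab, hits_ba)
    pairs = homology.call_orthologs(
        genome_a, genome_b, rbh, focal_genes_a=None, window=window, strict=strict
    )
    shared, specific_a, specific_b = homology.partition(ppr_a, ppr_b, pairs)
    return OrthologyResult(rbh, pairs, shared, specific_a, specific_b)


def paralog_hits(genome: Genome) -> list[homology.SimilarityHit]:
    return homology.all_vs_all(genome.proteins, genome.proteins, within=True)


@dataclass
class DupTypeResult:
    blocks: list[duptypes.CollinearBlock]
    pairs: list[duptypes.DuplicationPair]
    gene_labels: dict[str, str]


def run_duptypes(
    genome: Genome,
    hits: Sequence[homology.SimilarityHit] | None = None,
    min_anchors: int = 5,
    max_rank_gap: int = 25,
    proximal_max_gap: int = 10,
) -> DupTypeResult:
    if hits is None:
        hits = paralog_hits(genome)
    orders = duptypes.gene_orders(genome)
    blocks = duptypes.detect_collinear_blocks(hits, orders, min_anchors, max_rank_gap)
    pairs = duptypes.classify_duplications(hits, blocks, orders, proximal_max_gap)
    return DupTypeResult(blocks, pairs, duptypes.gene_labels(pairs))


@dataclass
class SDResult:
    sds: list[SegmentalDuplication]
    gene_pairs: list[sdgenes.SDGenePair]


def run_sd_analysis(
    genome: Genome,
    repeats,
    classifications: Mapping[str, family.PPRClassification],
    params: SDParams = SDParams(),
) -> SDResult:
    sds = detect_sds(genome, repeats, params)
    gene_pairs = sdgenes.map_genes_to_sds(
        sds, genome, set(classifications), classifications
    )
    return SDResult(sds, gene_pairs)


@dataclass
class OriginResult:
    ortholog_ks: list[kaks.KsRecord]
    mean_ortholog_ks: float
    calls: dict[str, list[kaks.OriginCall]]  # per genome label


def run_origin_inference(
    genome_a: Genome,
    genome_b: Genome,
    shared_pairs: Sequence[homology.OrthologPair],
    specific: Mapping[str, Sequence[str]],
    paralog_hit_sets: Mapping[str, Sequence[homology.SimilarityHit]],
) -> OriginResult:
    """Ks of shared ortholog pairs, then origin calls for specific genes.

    Shared pairs on unanchored or non-syntenic sequence are excluded from
    the ortholog mean, mirroring the exclusion applied before the
    comparison in the source analysis; specific genes' paralog Ks values
    come from their within-genome similarity hits.
    """
    merged_prot = {}
    merged_cds = {}
    for g in (genome_a, genome_b):
        merged_prot.update(g.proteins)
        merged_cds.update(g.cds_seqs)
    orth_ks = [
        kaks.ks_pair(p.gene_a, p.gene_b, merged_prot, merged_cds)
        for p in shared_pairs
        if p.status == "shared"
    ]
    mean_ks = kaks.mean_ortholog_ks(orth_ks)
    calls: dict[str, list[kaks.OriginCall]] = {}
    for label, genome in (("A", genome_a), ("B", genome_b)):
        out = []
        hit_map: dict[str, set[str]] = {}
        for h in paralog_hit_sets[label]:
            hit_map.setdefault(h.query_id, set()).add(h.subject_id)
            hit_map.setdefault(h.subject_id, set()).add(h.query_id)
        for gid in specific[label]:
            records = [
                kaks.ks_pair(gid, other, genome.proteins, genome.cds_seqs)
                for other in sorted(hit_map.get(gid, ()))
            ]
            out.append(kaks.classify_origin(gid, records, mean_ks))
        calls[label] = out
    return OriginResult(orth_ks, mean_ks, calls)


@dataclass
class ExpressionResult:
    tpm: expression.TPMMatrix
    tests: list[expression.PairTestResult]
    classes: list[expression.PairExpressionClass]


def run_expression(
    genome: Genome,
    counts: expression.CountMatrix,
    sister_pairs: Sequence[tuple[str, str]],
) -> ExpressionResult:
    lengths = {g.gene_id: g.exon_length for g in genome.genes}
    tpm = expression.compute_tpm(counts, lengths)
    tests = expression.test_pairs(sister_pairs, tpm, counts.meta)
    classes = expression.classify_pairs(sister_pairs, tests)
    return ExpressionResult(tpm, tests, classes)
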