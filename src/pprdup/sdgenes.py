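"""Intersection of segmental duplications with gene models.

A family gene is SD-derived when any of its CDS overlaps an SD copy. The
duplication partner is the gene whose CDS overlaps the projected homologous
interval (through the SD's coordinate correspondence) the most. An SD copy
that fully contains the gene span is a complete gene duplication; one whose
boundary falls inside the gene is incomplete — the mechanism by which the
family acquires foreign domains: when the homologous region projected onto
the focal protein covers a non-PPR domain shared with the partner, the
direction of the transfer is read from an outgroup (the copy whose outgroup
ortholog lacks the domain is the "accepter").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import DomainHit, GeneModel, Genome, GenomicInterval, PPR_MOTIF_TYPES
from .family import PPRClassification, dedupe_hits
from .homology import make_aligner
from .sddetect import SegmentalDuplication, _invert_map


@dataclass
class SDGenePair:
    sd: SegmentalDuplication
    focal_gene: str
    partner_gene: str | None
    completeness: str  # complete | incomplete
    pair_category: str  # PPR-same-subgroup | PPR-cross-subgroup | PPR-Other | no-partner
    pair_label: str  # e.g. "P-P", "DYW-E2", "P-Other"
    protein_similarity: float | None = None


@dataclass(frozen=True)
class DomainTransferCall:
    focal_gene: str
    partner_gene: str
    domain_type: str
    direction: str  # accepter | donor | ambiguous
    evidence: str


def _cds_tree(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chromosome, IntervalTree())
        for c in g.cds or g.exons or [g.interval]:
            tree[c.start : c.end] = g.gene_id
    return trees


def _cds_overlap(gene: GeneModel, interval: GenomicInterval) -> int:
    ivs = gene.cds or gene.exons or [gene.interval]
    return sum(iv.overlap(interval) for iv in ivs)


def classify_completeness(sd_copy: GenomicInterval, gene: GeneModel,
                          span: str = "gene") -> str:
    """complete iff the SD copy contains the gene span (or CDS span)."""
    if span == "cds" and gene.cds:
        lo = min(c.start for c in gene.cds)
        hi = max(c.end for c in gene.cds)
        target = GenomicInterval(gene.chromosome, lo, hi, gene.strand)
    else:
        target = gene.interval
    return "complete" if sd_copy.contains(target) else "incomplete"


def type_pair(
    focal: str,
    partner: str | None,
    classifications: Mapping[str, PPRClassification],
) -> tuple[str, str]:
    """(pair_category, label) for a focal family gene and its partner."""
    sub_f = classifications[focal].subgroup
    if partner is None:
        return "no-partner", f"{sub_f}-none"
    if partner in classifications:
        sub_p = classifications[partner].subgroup
        if sub_p == sub_f:
            return "PPR-same-subgroup", f"{sub_f}-{sub_p}"
        return "PPR-cross-subgroup", f"{sub_f}-{sub_p}"
    return "PPR-Other", f"{sub_f}-Other"


def protein_similarity(protein_a: str, protein_b: str) -> float:
    """% of alignment columns with identical or positively-scoring residues."""
    aligner = make_aligner()
    aln = aligner.align(protein_a, protein_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matrix = aligner.substitution_matrix
    similar = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb or matrix[ca, cb] > 0:
            similar += 1
    return 100.0 * similar / len(row_a)


def map_genes_to_sds(
    sds: Sequence[SegmentalDuplication],
    genome: Genome,
    ppr_set: Iterable[str],
    classifications: Mapping[str, PPRClassification],
    completeness_span: str = "gene",
    compute_similarity: bool = True,
) -> list[SDGenePair]:
    """One record per (SD, focal family gene overlapping either copy)."""
    ppr = set(ppr_set)
    trees = _cds_tree(genome.genes)
    out: list[SDGenePair] = []
    for sd in sds:
        maps = {"a": sd.segment_map, "b": _invert_map(sd.segment_map)}
        for side, copy, other_copy in (
            ("a", sd.copy_a, sd.copy_b),
            ("b", sd.copy_b, sd.copy_a),
        ):
            tree = trees.get(copy.chromosome)
            if tree is None:
                continue
            focal_ids = sorted(
                {iv.data for iv in tree[copy.start : copy.end]} & ppr
            )
            for fid in focal_ids:
                gene = genome.gene(fid)
                # homologous interval: projection of the overlapped region
                ov_start = max(copy.start, gene.interval.start)
                ov_end = min(copy.end, gene.interval.end)
                p0, p1 = maps[side].project_interval(ov_start, ov_end)
                projected = GenomicInterval(
                    other_copy.chromosome, p0, max(p1, p0 + 1), "."
                )
                partner = _best_partner(
                    genome, trees, projected, exclude=fid
                )
                completeness = classify_completeness(copy, gene, completeness_span)
                category, label = type_pair(fid, partner, classifications)
                sim = None
                if (
                    compute_similarity
                    and partner is not None
                    and fid in genome.proteins
                    and partner in genome.proteins
                ):
                    sim = protein_similarity(
                        genome.proteins[fid], genome.proteins[partner]
                    )
                out.append(
                    SDGenePair(sd, fid, partner, completeness, category, label, sim)
                )
    # deduplicate records seen from both sides (focal on a, partner on b)
    seen = set()
    unique = []
    for rec in out:
        key = (rec.sd.sd_id, rec.focal_gene)
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    return unique


def _best_partner(
    genome: Genome,
    trees: Mapping[str, IntervalTree],
    projected: GenomicInterval,
    exclude: str,
) -> str | None:
    tree = trees.get(projected.chromosome)
    if tree is None:
        return None
    candidates = {iv.data for iv in tree[projected.start : projected.end]}
    candidates.discard(exclude)
    if not candidates:
        return None
    scored = [
        (_cds_overlap(genome.gene(gid), projected), gid) for gid in candidates
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))  # max overlap, then smaller id
    return scored[0][1] if scored[0][0] > 0 else None


def _covered_aa(gene: GeneModel, region: GenomicInterval) -> set[int]:
    """1-based aa positions of the protein encoded inside ``region``."""
    cds = list(gene.cds)
    if gene.strand == "-":
        cds = cds[::-1]
    covered: set[int] = set()
    offset = 0  # nt offset into the spliced CDS
    for iv in cds:
        ov_start = max(iv.start, region.start)
        ov_end = min(iv.end, region.end)
        if iv.chromosome == region.chromosome and ov_start < ov_end:
            if gene.strand == "-":
                o0 = offset + (iv.end - ov_end)
                o1 = offset + (iv.end - ov_start)
            else:
                o0 = offset + (ov_start - iv.start)
                o1 = offset + (ov_end - iv.start)
            covered.update(range(o0 // 3 + 1, (o1 - 1) // 3 + 2))
        offset += len(iv)
    return covered


def detect_domain_acquisition(
    pair: SDGenePair,
    genome: Genome,
    domain_hits: Sequence[DomainHit],
    outgroup_hits: Sequence[DomainHit],
    outgroup_map: Mapping[str, str],
    min_coverage: float = 0.5,
) -> DomainTransferCall | None:
    """Domain-transfer call for an incomplete PPR-Other duplication.

    Emitted when the SD's homologous region, projected onto the focal
    protein, covers at least ``min_coverage`` of a non-PPR domain that the
    partner also carries. Direction comes from outgroup domain states:
    focal's outgroup ortholog lacks the domain while the partner's has it
    -> accepter; reversed -> donor; anything else (including missing
    outgroup orthologs) -> ambiguous.
    """
    if pair.partner_gene is None:
        return None
    gene = genome.gene(pair.focal_gene)
    copy = (
        pair.sd.copy_a
        if gene.interval.overlap(pair.sd.copy_a) > 0
        else pair.sd.copy_b
    )
    ov = GenomicInterval(
        copy.chromosome,
        max(copy.start, gene.interval.start),
        min(copy.end, gene.interval.end),
        gene.strand,
    )
    covered = _covered_aa(gene, ov)
    focal_hits = dedupe_hits(
        [h for h in domain_hits if h.protein_id == pair.focal_gene]
    )
    partner_types = {
        h.domain_type for h in domain_hits if h.protein_id == pair.partner_gene
    }
    for hit in focal_hits:
        if hit.domain_type in PPR_MOTIF_TYPES or hit.domain_type in (
            "E1", "E2", "E+", "DYW",
        ):
            continue
        span = set(range(hit.aa_start, hit.aa_end + 1))
        if len(span & covered) / len(span) < min_coverage:
            continue
        if hit.domain_type not in partner_types:
            continue
        og_focal = outgroup_map.get(pair.focal_gene)
        og_partner = outgroup_map.get(pair.partner_gene)
        if og_focal is None or og_partner is None:
            return DomainTransferCall(
                pair.focal_gene, pair.partner_gene, hit.domain_type,
                "ambiguous", "missing outgroup ortholog",
            )
        focal_og_types = {
            h.domain_type for h in outgroup_hits if h.protein_id == og_focal
        }
        partner_og_types = {
            h.domain_type for h in outgroup_hits if h.protein_id == og_partner
        }
        has_f = hit.domain_type in focal_og_types
        has_p = hit.domain_type in partner_og_types
        if not has_f and has_p:
            direction = "accepter"
        elif has_f and not has_p:
            direction = "donor"
        else:
            direction = "ambiguous"
        evidence = (
            f"outgroup {og_focal}:{'+' if has_f else '-'} "
            f"{og_partner}:{'+' if has_p else '-'}"
        )
        return DomainTransferCall(
            pair.focal_gene, pair.partner_gene, hit.domain_type, direction, evidence
        )
    return None


def sd_gene_table(pairs: Sequence[SDGenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.sd.sd_id, p.focal_gene, p.partner_gene or "",
                p.completeness, p.pair_category, p.pair_label,
                round(p.protein_similarity, 2) if p.protein_similarity is not None else "",
            )
            for p in pairs
        ],
        columns=[
            "sd_id", "focal", "partner", "completeness", "category",
            "label", "similarity",
        ],
    )
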