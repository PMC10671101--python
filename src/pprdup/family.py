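"""PPR family identification, P/PLS classification, and structure statistics.

Pentatricopeptide-repeat (PPR) proteins are built from tandem ~35-aa helical
repeat motifs. The canonical P motif and its long (L) and short (S) variants
define two subfamilies: P-class proteins carry only P motifs, PLS-class
proteins interleave P, L and S motifs and usually append C-terminal E1, E2,
E+ and/or DYW domains. Subgroup labels follow the most C-terminal of those
domains; PLS proteins lacking all of them keep the generic PLS label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import CTERM_DOMAIN_TYPES, DomainHit, GeneModel, PPR_MOTIF_TYPES

MIN_PPR_MOTIFS = 2  # single-motif proteins are discarded from the family

_SUBGROUPS = ("P", "PLS", "E1", "E2", "E+", "DYW")


@dataclass(frozen=True)
class PPRClassification:
    gene_id: str
    subfamily: str  # P | PLS
    subgroup: str  # P | PLS | E1 | E2 | E+ | DYW
    n_ppr_motifs: int
    n_exons: int = 0
    flagged: bool = False  # admixed architecture (e.g. P motifs + lone DYW)

    def __post_init__(self) -> None:
        if self.subfamily not in ("P", "PLS"):
            raise ValueError(f"bad subfamily {self.subfamily}")
        if self.subgroup not in _SUBGROUPS:
            raise ValueError(f"bad subgroup {self.subgroup}")
        if (self.subgroup == "P") != (self.subfamily == "P"):
            raise ValueError("subgroup P <=> subfamily P")


def dedupe_hits(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Collapse overlapping same-protein hits (>50% of the shorter span).

    The lower-E-value hit wins; ties keep the earlier hit. Prevents one
    physical motif reported twice from inflating motif counts.
    """
    out: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.aa_start, h.aa_end, h.evalue)):
        merged = False
        for i, kept in enumerate(out):
            ov = min(hit.aa_end, kept.aa_end) - max(hit.aa_start, kept.aa_start) + 1
            if ov > 0.5 * min(hit.aa_span, kept.aa_span):
                if hit.evalue < kept.evalue:
                    out[i] = hit
                merged = True
                break
        if not merged:
            out.append(hit)
    out.sort(key=lambda h: h.aa_start)
    return out


def _hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return {pid: dedupe_hits(hs) for pid, hs in grouped.items()}


def identify_ppr(
    proteins: Mapping[str, str],
    domain_hits: Iterable[DomainHit],
    min_motifs: int = MIN_PPR_MOTIFS,
    count_cterm: bool = False,
) -> set[str]:
    """Genes retained as PPR-family members.

    A gene qualifies when it carries at least ``min_motifs`` PPR repeat
    motifs (P/L/S). C-terminal E1/E2/E+/DYW domains do not count toward the
    minimum unless ``count_cterm`` is set.
    """
    grouped = _hits_by_protein(domain_hits)
    unknown = set(grouped) - set(proteins)
    if unknown:
        raise ValueError(f"domain hits for unknown proteins: {sorted(unknown)[:5]}")
    counted = PPR_MOTIF_TYPES | (
        set(CTERM_DOMAIN_TYPES) if count_cterm else set()
    )
    return {
        pid
        for pid, hs in grouped.items()
        if sum(h.domain_type in counted for h in hs) >= min_motifs
    }


def classify(gene_id: str, domain_hits: Sequence[DomainHit]) -> PPRClassification:
    """Classify one identified PPR gene from its (deduplicated) architecture.

    PLS iff the motif string contains an L or S motif or any C-terminal
    domain; subgroup = the most C-terminal of {E1, E2, E+, DYW} present.
    P-motif-only proteins carrying an isolated C-terminal domain are legal
    but unusual; they are classified PLS and flagged.
    """
    hits = dedupe_hits([h for h in domain_hits if h.protein_id == gene_id])
    motifs = [h.domain_type for h in hits]
    n_ppr = sum(m in PPR_MOTIF_TYPES for m in motifs)
    cterm = [m for m in motifs if m in CTERM_DOMAIN_TYPES]
    has_ls = any(m in ("L", "S") for m in motifs)
    if has_ls or cterm:
        subgroup = cterm[-1] if cterm else "PLS"
        flagged = bool(cterm) and not has_ls  # P-architecture with C-term domain
        return PPRClassification(gene_id, "PLS", subgroup, n_ppr, flagged=flagged)
    return PPRClassification(gene_id, "P", "P", n_ppr)


def classify_all(
    proteins: Mapping[str, str],
    domain_hits: Iterable[DomainHit],
    gene_models: Mapping[str, GeneModel] | None = None,
    min_motifs: int = MIN_PPR_MOTIFS,
) -> dict[str, PPRClassification]:
    """Identify and classify the whole family in one pass."""
    hits = list(domain_hits)
    members = identify_ppr(proteins, hits, min_motifs=min_motifs)
    grouped = _hits_by_protein(hits)
    out: dict[str, PPRClassification] = {}
    for gid in sorted(members):
        c = classify(gid, grouped[gid])
        if gene_models is not None and gid in gene_models:
            c = PPRClassification(
                c.gene_id, c.subfamily, c.subgroup, c.n_ppr_motifs,
                n_exons=gene_models[gid].n_exons, flagged=c.flagged,
            )
        out[gid] = c
    return out


EXON_BINS = ("1", "2", "3", "4", ">=5")


def _exon_bin(n: int) -> str:
    return str(n) if n <= 4 else ">=5"


def structure_stats(
    classifications: Mapping[str, PPRClassification],
    gene_models: Mapping[str, GeneModel],
) -> dict[str, pd.Series]:
    """Summary tables of gene structure for a classified family.

    Returns the exon-count histogram (bins 1,2,3,4,>=5), the PPR-motif-count
    histogram, per-chromosome gene counts, and per-subfamily single-exon
    gene counts.
    """
    missing = set(classifications) - set(gene_models)
    if missing:
        raise ValueError(f"classified genes without models: {sorted(missing)[:5]}")
    exon_counts = Counter()
    motif_counts = Counter()
    chrom_counts = Counter()
    single_exon = Counter()
    for gid, c in classifications.items():
        g = gene_models[gid]
        exon_counts[_exon_bin(g.n_exons)] += 1
        motif_counts[c.n_ppr_motifs] += 1
        chrom_counts[g.chromosome] += 1
        if g.n_exons == 1:
            single_exon[c.subfamily] += 1
    return {
        "exon_bins": pd.Series(
            [exon_counts.get(b, 0) for b in EXON_BINS], index=EXON_BINS, name="genes"
        ),
        "motif_counts": pd.Series(dict(sorted(motif_counts.items())), name="genes"),
        "chromosome_counts": pd.Series(dict(sorted(chrom_counts.items())), name="genes"),
        "single_exon_by_subfamily": pd.Series(
            {k: single_exon.get(k, 0) for k in ("P", "PLS")}, name="genes"
        ),
    }


def classification_table(
    classifications: Mapping[str, PPRClassification],
    gene_models: Mapping[str, GeneModel] | None = None,
) -> pd.DataFrame:
    rows = []
    for gid in sorted(classifications):
        c = classifications[gid]
        chrom = gene_models[gid].chromosome if gene_models and gid in gene_models else ""
        rows.append((gid, c.subfamily, c.subgroup, c.n_ppr_motifs, c.n_exons, chrom))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "subfamily", "subgroup", "n_motifs", "n_exons", "chromosome"],
    )
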