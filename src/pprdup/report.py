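"""Summary statistics with a single fixed rounding convention.

Every percentage or ratio in the final report is recomputed from its
integer numerator and denominator and rounded half-away-from-zero at two
decimals; the report never stores a derived value without the counts it
came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .duptypes import DUP_TYPES, DuplicationPair, gene_labels
from .expression import PairExpressionClass
from .family import PPRClassification
from .homology import OrthologPair
from .kaks import OriginCall
from .sddetect import SegmentalDuplication
from .sdgenes import SDGenePair


def _round_half_away(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """round(100 * count / total) with half-away-from-zero rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count outside [0, total]")
    return _round_half_away(100.0 * count / total, decimals)


def enrichment_ratio(
    subset_proportion: float, genome_proportion: float, decimals: int = 2
) -> float:
    """Fold enrichment of a subset proportion over the genome-wide one."""
    if genome_proportion <= 0:
        raise ValueError("genome proportion must be positive")
    return _round_half_away(subset_proportion / genome_proportion, decimals)


@dataclass
class Statistic:
    name: str
    numerator: float
    denominator: float | None
    value: float


@dataclass
class SummaryReport:
    statistics: list[Statistic] = field(default_factory=list)

    def add(self, name: str, numerator: float, denominator: float | None,
            value: float) -> None:
        self.statistics.append(Statistic(name, numerator, denominator, value))

    def add_percentage(self, name: str, count: int, total: int) -> None:
        self.add(name, count, total, percentage(count, total))

    def value(self, name: str) -> float:
        for s in self.statistics:
            if s.name == name:
                return s.value
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.numerator, s.denominator, s.value) for s in self.statistics],
            columns=["name", "numerator", "denominator", "value"],
        )

    def to_markdown(self) -> str:
        lines = ["| statistic | numerator | denominator | value |",
                 "|---|---|---|---|"]
        for s in self.statistics:
            den = "" if s.denominator is None else s.denominator
            lines.append(f"| {s.name} | {s.numerator} | {den} | {s.value} |")
        return "\n".join(lines) + "\n"


def build_report(
    genome_name: str,
    classifications: Mapping[str, PPRClassification],
    exon_bins: pd.Series | None = None,
    shared_pairs: Sequence[OrthologPair] = (),
    specific_genes: Sequence[str] = (),
    dup_pairs: Sequence[DuplicationPair] = (),
    genome_dup_pairs: Sequence[DuplicationPair] = (),
    all_gene_ids: Sequence[str] = (),
    sds: Sequence[SegmentalDuplication] = (),
    sd_gene_pairs: Sequence[SDGenePair] = (),
    origin_calls: Sequence[OriginCall] = (),
    expression_classes: Sequence[PairExpressionClass] = (),
) -> SummaryReport:
    """Aggregate stage outputs for one genome into a consistency-checked report."""
    rep = SummaryReport()
    family = sorted(classifications)
    n_family = len(family)
    rep.add(f"{genome_name}.family_size", n_family, None, n_family)
    for sub in ("P", "PLS"):
        n = sum(c.subfamily == sub for c in classifications.values())
        rep.add(f"{genome_name}.subfamily_{sub}", n, None, n)
    n_p = rep.value(f"{genome_name}.subfamily_P")
    n_pls = rep.value(f"{genome_name}.subfamily_PLS")
    if n_p + n_pls != n_family:
        raise ValueError("subfamily counts do not sum to family size")

    if exon_bins is not None and n_family:
        for label, count in exon_bins.items():
            rep.add_percentage(
                f"{genome_name}.exon_bin_{label}_pct", int(count), n_family
            )

    if n_family:
        n_shared = len(shared_pairs)
        n_both = sum(
            p.status in ("shared", "unanchored", "non_syntenic") for p in shared_pairs
        )
        if n_both != n_shared:
            raise ValueError("unknown ortholog status in shared pairs")
        n_strict = sum(p.status == "shared" for p in shared_pairs)
        rep.add(f"{genome_name}.shared_pairs", n_shared, None, n_shared)
        rep.add_percentage(
            f"{genome_name}.shared_strict_pct", n_strict, n_family
        )
        rep.add_percentage(f"{genome_name}.shared_all_pct", n_shared, n_family)
        rep.add(
            f"{genome_name}.specific_genes",
            len(specific_genes), None, len(specific_genes),
        )

    if dup_pairs and all_gene_ids:
        fam_labels = gene_labels(dup_pairs)
        fam_dup = [g for g in family if g in fam_labels]
        gen_labels_all = gene_labels(genome_dup_pairs or dup_pairs)
        gen_dup = [g for g in all_gene_ids if g in gen_labels_all]
        for t in DUP_TYPES:
            nf = sum(fam_labels[g] == t for g in fam_dup)
            if fam_dup:
                rep.add_percentage(f"{genome_name}.family_{t}_pct", nf, len(fam_dup))
            ng = sum(gen_labels_all[g] == t for g in gen_dup)
            if gen_dup:
                rep.add_percentage(f"{genome_name}.genome_{t}_pct", ng, len(gen_dup))
        if fam_dup and gen_dup:
            fam_disp = rep.value(f"{genome_name}.family_dispersed_pct")
            gen_disp = rep.value(f"{genome_name}.genome_dispersed_pct")
            if gen_disp > 0:
                rep.add(
                    f"{genome_name}.dispersed_enrichment",
                    fam_disp, gen_disp, enrichment_ratio(fam_disp, gen_disp),
                )

    n_sds = len(sds)
    rep.add(f"{genome_name}.sd_count", n_sds, None, n_sds)
    if n_sds:
        hi99 = sum(sd.identity > 99 for sd in sds)
        rep.add(f"{genome_name}.sd_identity_gt99", hi99, None, hi99)

    sd_genes = sorted({p.focal_gene for p in sd_gene_pairs})
    rep.add(f"{genome_name}.sd_derived_genes", len(sd_genes), None, len(sd_genes))
    if n_family:
        rep.add_percentage(
            f"{genome_name}.sd_derived_pct", len(sd_genes), n_family
        )
    with_partner = [p for p in sd_gene_pairs if p.partner_gene is not None]
    n_complete = sum(p.completeness == "complete" for p in with_partner)
    n_incomplete = sum(p.completeness == "incomplete" for p in with_partner)
    if n_complete + n_incomplete != len(with_partner):
        raise ValueError("completeness labels do not partition pairs")
    rep.add(f"{genome_name}.complete_pairs", n_complete, None, n_complete)
    rep.add(f"{genome_name}.incomplete_pairs", n_incomplete, None, n_incomplete)
    cats = {}
    for p in with_partner:
        cats[p.pair_category] = cats.get(p.pair_category, 0) + 1
    for cat, n in sorted(cats.items()):
        rep.add(f"{genome_name}.pairs_{cat}", n, None, n)
        rep.add_percentage(f"{genome_name}.pairs_{cat}_pct", n, len(with_partner))
    sims = [p.protein_similarity for p in with_partner
            if p.protein_similarity is not None]
    if sims:
        rep.add(
            f"{genome_name}.mean_protein_similarity",
            sum(sims), len(sims), _round_half_away(sum(sims) / len(sims), 2),
        )

    for origin in ("new_duplication", "ancestral_loss", "unresolved"):
        n = sum(c.origin == origin for c in origin_calls)
        rep.add(f"{genome_name}.origin_{origin}", n, None, n)
    if origin_calls:
        resolved = [c for c in origin_calls if c.origin != "unresolved"]
        if resolved:
            n_new = sum(c.origin == "new_duplication" for c in resolved)
            rep.add_percentage(
                f"{genome_name}.origin_new_pct", n_new, len(resolved)
            )

    for cls in ("AED", "sub_neo", "no_difference"):
        n = sum(c.expr_class == cls for c in expression_classes)
        rep.add(f"{genome_name}.expr_{cls}", n, None, n)
    if expression_classes:
        total = len(expression_classes)
        n_sum = sum(
            rep.value(f"{genome_name}.expr_{c}")
            for c in ("AED", "sub_neo", "no_difference")
        )
        if n_sum != total:
            raise ValueError("expression classes do not partition pairs")
    return rep
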