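"""Codon-aware alignment and Nei–Gojobori (NG86) Ka/Ks estimation.

Synonymous divergence (Ks) proxies the age of a duplication or speciation
event. The estimator is the classic counting method: synonymous and
nonsynonymous site fractions per codon under the standard genetic code,
pathway averaging for codons differing at 2–3 positions (uniform weights
over minimal pathways that avoid stop codons), and the Jukes–Cantor
correction d = -3/4 ln(1 - 4/3 p). Proportions >= 0.75 are flagged
saturated. Site counting treats changes to stop codons as nonsynonymous so
that S + N = 3 x codons for every alignment.

The origin of a species-specific gene is inferred by comparing the minimum
Ks over its within-genome paralogs (the most recent duplication) with the
mean ortholog Ks between the genomes: a smaller value means the gene arose
by duplication after the species split; a larger one means the other genome
lost its copy of an old duplicate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .homology import make_aligner

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
_BASES = "ACGT"


class SaturatedError(ValueError):
    pass


@dataclass(frozen=True)
class KsRecord:
    gene_1: str
    gene_2: str
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    codons_used: int
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def saturated(self) -> bool:
        return self.saturated_s or self.saturated_n


@dataclass(frozen=True)
class OriginCall:
    gene_id: str
    min_paralog_ks: float | None
    ortholog_mean_ks: float
    origin: str  # new_duplication | ancestral_loss | unresolved


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Each position contributes the fraction of its three possible changes
    that preserve the encoded amino acid; changes to stop codons count as
    nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at several positions are averaged over all orderings
    of the single-base steps; orderings that pass through a stop codon are
    excluded (all orderings are kept if every one is blocked).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*" and step < len(order) - 1:
                blocked = True
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:  # every ordering hits a stop; fall back to all orderings
        for order in itertools.permutations(diff_pos):
            cur = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            pathways.append((sd, nd))
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturatedError(f"proportion {p} saturated")
    if p <= 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def codon_align(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str
) -> list[tuple[str, str]]:
    """Protein-guided codon alignment as a list of codon-pair columns.

    The proteins are globally aligned, the alignment is back-translated
    onto the CDSs, and every column containing a gap in either sequence is
    removed. Terminal stop codons on the CDSs are tolerated and stripped.
    """
    cds_a = _strip_stop(cds_a, protein_a)
    cds_b = _strip_stop(cds_b, protein_b)
    for prot, cds, name in ((protein_a, cds_a, "a"), (protein_b, cds_b, "b")):
        if len(cds) != 3 * len(prot):
            raise ValueError(f"cds_{name} length does not match protein")
        if str(Seq(cds).translate()) != prot:
            raise ValueError(f"cds_{name} does not translate to protein_{name}")
    aln = make_aligner().align(protein_a, protein_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    out = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            out.append((cds_a[3 * ia : 3 * ia + 3], cds_b[3 * ib : 3 * ib + 3]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return out


def _strip_stop(cds: str, protein: str) -> str:
    cds = cds.upper()
    if len(cds) == 3 * len(protein) + 3 and _CODON_TABLE.get(cds[-3:]) == "*":
        return cds[:-3]
    return cds


def ks_ng86(
    codon_columns: Sequence[tuple[str, str]], gene_1: str = "a", gene_2: str = "b"
) -> KsRecord:
    """NG86 Ka/Ks from a gap-free codon alignment.

    Columns containing an ambiguous base or a stop codon in either sequence
    are skipped. Site counts are averaged over the two sequences.
    """
    if not codon_columns:
        raise ValueError("empty codon alignment")
    s_a = s_b = 0.0
    sd = nd = 0.0
    used = 0
    for ca, cb in codon_columns:
        ca, cb = ca.upper(), cb.upper()
        if any(b not in _BASES for b in ca + cb):
            continue
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            continue
        used += 1
        s_a += codon_sites(ca)[0]
        s_b += codon_sites(cb)[0]
        d = codon_differences(ca, cb)
        sd += d[0]
        nd += d[1]
    if used == 0:
        raise ValueError("no usable codon columns")
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * used - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    sat_s = ps >= 0.75
    sat_n = pn >= 0.75
    ks = math.inf if sat_s else jukes_cantor(ps)
    ka = math.inf if sat_n else jukes_cantor(pn)
    return KsRecord(gene_1, gene_2, ks, ka, s_sites, n_sites, used, sat_s, sat_n)


def ks_pair(
    gene_1: str,
    gene_2: str,
    proteins: Mapping[str, str],
    cds_seqs: Mapping[str, str],
) -> KsRecord:
    """Codon-align two genes and estimate Ka/Ks."""
    cols = codon_align(
        proteins[gene_1], proteins[gene_2], cds_seqs[gene_1], cds_seqs[gene_2]
    )
    return ks_ng86(cols, gene_1, gene_2)


def mean_ortholog_ks(records: Sequence[KsRecord]) -> float:
    vals = [r.ks for r in records if not r.saturated_s and math.isfinite(r.ks)]
    if not vals:
        raise ValueError("no unsaturated ortholog Ks values")
    return sum(vals) / len(vals)


def classify_origin(
    gene_id: str,
    paralog_ks_records: Sequence[KsRecord],
    ortholog_mean_ks: float,
) -> OriginCall:
    """Infer whether a species-specific gene is a new duplicate or a relic.

    The minimum paralog Ks approximates the most recent duplication event;
    below the mean ortholog Ks the gene post-dates the species split
    (new_duplication), above it the other species lost its ortholog copy
    (ancestral_loss). Genes with no detectable paralog stay unresolved.
    """
    vals = [
        r.ks
        for r in paralog_ks_records
        if gene_id in (r.gene_1, r.gene_2)
        and not r.saturated_s
        and math.isfinite(r.ks)
    ]
    if not vals:
        return OriginCall(gene_id, None, ortholog_mean_ks, "unresolved")
    min_ks = min(vals)
    origin = "new_duplication" if min_ks < ortholog_mean_ks else "ancestral_loss"
    return OriginCall(gene_id, min_ks, ortholog_mean_ks, origin)
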