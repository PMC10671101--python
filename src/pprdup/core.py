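"""Shared genomic data structures.

All coordinates inside the package are 0-based, half-open. Conversion to the
1-based inclusive conventions of GFF3 happens only in :mod:`pprdup.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval on a chromosome (0-based, half-open)."""

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if different chromosomes)."""
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """One protein-coding gene, reduced to its representative transcript.

    ``rank`` is the 0-based order index of the gene on its chromosome when
    genes are sorted by start coordinate; it is the unit of distance for the
    local-synteny filter and duplication typing.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    rank: int = -1
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for ivs, label in ((self.exons, "exons"), (self.cds, "CDS")):
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"{self.gene_id}: overlapping {label}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {c} outside exons")

    @property
    def chromosome(self) -> str:
        return self.interval.chromosome

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def cds_sequence(self, chromosome_seq: str) -> str:
        """Spliced CDS in transcription order (reverse-complemented on -)."""
        parts = [chromosome_seq[c.start : c.end] for c in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class Genome:
    """An annotated genome: sequences, gene models, protein and CDS sets."""

    name: str
    sequences: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str] = field(default_factory=dict)
    cds_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            if g.chromosome not in self.sequences:
                raise ValueError(
                    f"{g.gene_id}: chromosome {g.chromosome} not in genome"
                )

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def chromosome_length(self, chromosome: str) -> int:
        return len(self.sequences[chromosome])

    def assign_ranks(self) -> None:
        """(Re-)assign per-chromosome order indices by start coordinate."""
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: (g.interval.start, g.gene_id))
            for i, g in enumerate(genes):
                g.rank = i

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        out = [g for g in self.genes if g.chromosome == chromosome]
        out.sort(key=lambda g: g.rank)
        return out

    def validate_coding(self) -> None:
        """Check CDS/protein consistency (stop codon excluded from protein)."""
        for g in self.genes:
            if g.gene_id not in self.cds_seqs:
                continue
            cds = self.cds_seqs[g.gene_id]
            if len(cds) % 3:
                raise ValueError(f"{g.gene_id}: CDS length not divisible by 3")
            prot = str(Seq(cds).translate())
            if prot.endswith("*"):
                prot = prot[:-1]
            if self.proteins.get(g.gene_id) not in (None, prot):
                raise ValueError(f"{g.gene_id}: CDS does not translate to protein")


@dataclass(frozen=True)
class DomainHit:
    """A motif/domain match on a protein (1-based inclusive aa coordinates)."""

    protein_id: str
    domain_type: str
    aa_start: int
    aa_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.aa_start < 1 or self.aa_end < self.aa_start:
            raise ValueError(
                f"{self.protein_id}: bad domain coordinates "
                f"{self.aa_start}-{self.aa_end}"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative E-value")

    @property
    def aa_span(self) -> int:
        return self.aa_end - self.aa_start + 1


# PPR repeat motif types; C-terminal domains appended to PLS-class proteins.
PPR_MOTIF_TYPES = frozenset({"P", "L", "S"})
CTERM_DOMAIN_TYPES = ("E1", "E2", "E+", "DYW")  # N->C order in canonical PLS genes
PPR_DOMAIN_TYPES = PPR_MOTIF_TYPES | set(CTERM_DOMAIN_TYPES)
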