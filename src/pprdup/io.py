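"""Readers and writers for the formats the pipeline touches.

GFF3 is parsed through :mod:`gffutils`; FASTA through Biopython. File
coordinates (1-based inclusive for GFF3) are converted to the package's
internal 0-based half-open convention here and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DomainHit, GeneModel, Genome, GenomicInterval


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _transcript_models(db: gffutils.FeatureDB, gene) -> list[tuple[str, list, list]]:
    """(transcript_id, exons, cds) triples for each mRNA of a gene."""
    out = []
    for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
        exons = list(db.children(mrna, featuretype="exon", order_by="start"))
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        out.append((mrna.id, exons, cds))
    return out


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from GFF3, one representative transcript per gene.

    The representative transcript is the one with the longest total CDS;
    ties break on lexicographic transcript ID. Ranks are assigned per
    chromosome by start position.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise FormatError(f"failed to parse GFF3 {path}: {exc}") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = _transcript_models(db, gene)
        if not transcripts:
            # gene without mRNA children: treat the gene itself as one exon
            iv = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
            models.append(GeneModel(gene.id, iv, exons=[iv], cds=[]))
            continue
        transcripts.sort(
            key=lambda t: (-sum(c.end - c.start + 1 for c in t[2]), t[0])
        )
        tid, exons, cds = transcripts[0]
        iv = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        exon_ivs = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand) for e in exons
        ]
        cds_ivs = [
            GenomicInterval(c.seqid, c.start - 1, c.end, c.strand) for c in cds
        ]
        try:
            models.append(
                GeneModel(gene.id, iv, exons=exon_ivs, cds=cds_ivs, transcript_id=tid)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc

    _assign_ranks(models)
    return models


def _assign_ranks(models: list[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.interval.start, g.gene_id))
        for i, g in enumerate(genes):
            g.rank = i


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as gene/mRNA/exon/CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chromosome, m.interval.start)):
            iv = g.interval
            tid = g.transcript_id or f"{g.gene_id}.1"
            fh.write(
                f"{iv.chromosome}\tpprdup\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{iv.chromosome}\tpprdup\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.chromosome}\tpprdup\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{iv.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )
            for i, c in enumerate(g.cds, 1):
                fh.write(
                    f"{c.chromosome}\tpprdup\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{iv.strand}\t0\tID={tid}.cds{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# Domain-hit tables
# ---------------------------------------------------------------------------

DOMAIN_COLUMNS = ["protein_id", "domain_type", "aa_start", "aa_end", "evalue"]


def read_domain_hits(
    path: str | os.PathLike, evalue_cutoff: float = 10.0
) -> list[DomainHit]:
    """Read a hmmscan-domtblout-like TSV of domain hits.

    Rows with ``evalue >= evalue_cutoff`` are dropped (the identification
    pipeline keeps matches strictly below E-value 10). Output is sorted by
    (protein_id, aa_start).
    """
    df = pd.read_csv(str(path), sep="\t")
    missing = set(DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing domain-hit columns {sorted(missing)}")
    df = df[df["evalue"] < evalue_cutoff]
    hits = [
        DomainHit(
            str(r.protein_id),
            str(r.domain_type),
            int(r.aa_start),
            int(r.aa_end),
            float(r.evalue),
        )
        for r in df.itertuples()
    ]
    hits.sort(key=lambda h: (h.protein_id, h.aa_start, h.aa_end))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(h.protein_id, h.domain_type, h.aa_start, h.aa_end, h.evalue) for h in hits],
        columns=DOMAIN_COLUMNS,
    )
    df.to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Standard 6-column BED (name and score written as '.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t.\t.\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Genome bundles
# ---------------------------------------------------------------------------

def load_genome(
    name: str,
    fasta: str | os.PathLike,
    gff3: str | os.PathLike,
    protein_fasta: str | os.PathLike | None = None,
    cds_fasta: str | os.PathLike | None = None,
) -> Genome:
    """Assemble a :class:`Genome` from its on-disk parts.

    When protein/CDS FASTAs are not given, CDS and protein sequences are
    derived from the genome sequence and the gene models.
    """
    sequences = read_fasta(fasta)
    genes = read_gff3(gff3)
    cds_seqs: dict[str, str] = {}
    proteins: dict[str, str] = {}
    if cds_fasta is not None:
        cds_seqs = read_fasta(cds_fasta)
    else:
        for g in genes:
            if g.cds:
                cds_seqs[g.gene_id] = g.cds_sequence(sequences[g.chromosome])
    if protein_fasta is not None:
        proteins = read_fasta(protein_fasta)
    else:
        for gid, cds in cds_seqs.items():
            prot = str(Seq(cds).translate())
            proteins[gid] = prot[:-1] if prot.endswith("*") else prot
    genome = Genome(name, sequences, genes, proteins, cds_seqs)
    genome.validate_coding()
    return genome


def write_genome(genome: Genome, outdir: str | os.PathLike) -> dict[str, str]:
    """Write FASTA/GFF3/protein/CDS files for a genome; returns the paths."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, f"{genome.name}.fa"),
        "gff3": os.path.join(outdir, f"{genome.name}.gff3"),
        "proteins": os.path.join(outdir, f"{genome.name}.pep.fa"),
        "cds": os.path.join(outdir, f"{genome.name}.cds.fa"),
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_gff3(genome.genes, paths["gff3"])
    write_fasta(genome.proteins, paths["proteins"])
    write_fasta(genome.cds_seqs, paths["cds"])
    return paths
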