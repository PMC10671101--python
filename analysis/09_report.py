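#!/usr/bin/env python
"""Aggregate all stage outputs into the per-genome summary report.

Rebuilds every percentage and ratio from the integer counts in the stage
tables (nothing is copied), runs the internal consistency checks, and
writes report.tsv / report.md.
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from common import GENOME_FILES, load_genome, load_hits, out_path

from pprdup import pipeline
from pprdup.duptypes import DuplicationPair
from pprdup.family import structure_stats
from pprdup.homology import OrthologPair
from pprdup.expression import PairExpressionClass
from pprdup.kaks import OriginCall
from pprdup.report import build_report
from pprdup.sdgenes import SDGenePair


def _read(name):
    return pd.read_csv(out_path(name), sep="\t")


def main() -> None:
    reports = []
    orth_df = _read("ppr_orthologs.tsv")
    for label in ("A", "B"):
        genome = load_genome(label)
        name = GENOME_FILES[label]
        cls = pipeline.classify_family(genome, load_hits(label))
        models = {g.gene_id: g for g in genome.genes}
        stats = structure_stats(cls, models)
        col = "gene_a" if label == "A" else "gene_b"
        shared = [
            OrthologPair(r.gene_a, r.gene_b, bool(r.rbh),
                         bool(r.synteny_pass), r.status)
            for r in orth_df.itertuples()
        ]
        specific = _read(f"{name}.specific.tsv")["gene_id"].tolist()
        dup_df = _read(f"{name}.dup_pairs.tsv")
        dup_pairs = [DuplicationPair(r.gene_1, r.gene_2, r.dup_type)
                     for r in dup_df.itertuples()]
        sd_df = _read(f"{name}.sds.tsv")
        from pprdup.core import GenomicInterval
        from pprdup.sddetect import SegmentalDuplication

        sds = [
            SegmentalDuplication(
                GenomicInterval(r.chrA, r.startA, r.endA, "+"),
                GenomicInterval(r.chrB, r.startB, r.endB, "+"),
                float(r.identity), int(r.aligned_length),
                "forward" if r.orientation == "forward" else "reverse",
            )
            for r in sd_df.itertuples()
        ]
        sdg_df = _read(f"{name}.sd_genes.tsv")
        sd_pairs = [
            SDGenePair(None, r.focal, r.partner if isinstance(r.partner, str)
                       else None, r.completeness, r.category, r.label,
                       float(r.similarity) if str(r.similarity) not in ("", "nan")
                       else None)
            for r in sdg_df.itertuples()
        ]
        orig_df = _read(f"{name}.origins.tsv")
        origin_calls = [
            OriginCall(r.gene_id,
                       None if pd.isna(r.min_paralog_ks) else r.min_paralog_ks,
                       0.0, r.origin)
            for r in orig_df.itertuples()
        ]
        expr_df = _read(f"{name}.expression_classes.tsv")
        expr_classes = [
            PairExpressionClass((r.copy1, r.copy2), getattr(r, "_3"),
                                r.higher if isinstance(r.higher, str) else None)
            for r in expr_df.itertuples()
        ]
        rep = build_report(
            name, cls, stats["exon_bins"], shared, specific, dup_pairs,
            dup_pairs, [g.gene_id for g in genome.genes], sds, sd_pairs,
            origin_calls, expr_classes,
        )
        reports.append(rep)
        _ = col

    frames = [r.to_frame() for r in reports]
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out_path("report.tsv"), sep="\t", index=False)
    with open(out_path("report.md"), "w") as fh:
        for r in reports:
            fh.write(r.to_markdown() + "\n")
    for r in reports:
        genome = r.statistics[0].name.split(".")[0]
        print(f"--- {genome} ---")
        for s in r.statistics:
            print(f"  {s.name.split('.', 1)[1]:34s} {s.value}")


if __name__ == "__main__":
    main()
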