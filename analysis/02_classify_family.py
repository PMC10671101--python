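#!/usr/bin/env python
"""Identify the PPR family in each genome and tabulate gene structure.

Reads the domain-hit tables (E-value < 10 retained, two-motif minimum) and
writes per-genome classification tables and exon/motif/chromosome summary
statistics.
"""

import sys

sys.path.insert(0, "analysis")
from common import load_genome, load_hits, out_path

from pprdup import pipeline
from pprdup.family import classification_table, structure_stats


def main() -> None:
    for label in ("A", "B"):
        genome = load_genome(label)
        cls = pipeline.classify_family(genome, load_hits(label))
        models = {g.gene_id: g for g in genome.genes}
        table = classification_table(cls, models)
        table.to_csv(out_path(f"{genome.name}.family.tsv"), sep="\t", index=False)
        stats = structure_stats(cls, models)
        stats["exon_bins"].to_csv(out_path(f"{genome.name}.exon_bins.tsv"), sep="\t")
        n_p = (table.subfamily == "P").sum()
        n_pls = (table.subfamily == "PLS").sum()
        motifs = table.n_motifs
        print(f"{genome.name}: {len(table)} PPR genes "
              f"({n_p} P-class, {n_pls} PLS-class); "
              f"motifs per protein {motifs.min()}-{motifs.max()}; "
              f"single-exon: {stats['exon_bins']['1']} "
              f"({100 * stats['exon_bins']['1'] / len(table):.2f}%)")


if __name__ == "__main__":
    main()
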