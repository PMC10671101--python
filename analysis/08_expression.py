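#!/usr/bin/env python
"""Expression of SD sister pairs: TPM levels and divergence classes.

Normalises the replicated counts to TPM, bins per-tissue expression into
the five-level scheme, and classifies each PPR-PPR sister pair as AED
(asymmetrically expressed), sub-/neo-functionalized, or no-difference.
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from common import genome_paths, load_genome, load_hits, load_repeats, out_path

from pprdup import pipeline
from pprdup.expression import level_table, read_counts_tsv


def main() -> None:
    for label in ("A", "B"):
        genome = load_genome(label)
        counts = read_counts_tsv(genome_paths(label)["counts"])
        cls = pipeline.classify_family(genome, load_hits(label))
        sd_res = pipeline.run_sd_analysis(genome, load_repeats(label), cls)
        pairs = sorted({
            tuple(sorted((p.focal_gene, p.partner_gene)))
            for p in sd_res.gene_pairs
            if p.partner_gene and p.pair_category.startswith("PPR-")
            and p.partner_gene in cls
        })
        er = pipeline.run_expression(genome, counts, pairs)
        er.tpm.tpm.round(3).to_csv(out_path(f"{genome.name}.tpm.tsv"), sep="\t")
        level_table(er.tpm, counts.meta).to_csv(
            out_path(f"{genome.name}.levels.tsv"), sep="\t")
        rows = [(c.pair[0], c.pair[1], c.expr_class, c.higher_copy or "")
                for c in er.classes]
        pd.DataFrame(rows, columns=["copy1", "copy2", "class", "higher"]).to_csv(
            out_path(f"{genome.name}.expression_classes.tsv"), sep="\t", index=False)
        tally = {}
        for c in er.classes:
            tally[c.expr_class] = tally.get(c.expr_class, 0) + 1
        print(f"{genome.name}: {len(pairs)} PPR-PPR sister pairs -> {tally}")


if __name__ == "__main__":
    main()
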