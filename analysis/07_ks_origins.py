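#!/usr/bin/env python
"""Ks of ortholog pairs and the origin of species-specific genes.

Codon-aware NG86 Ks for every syntenic ortholog pair; each specific gene's
minimum paralog Ks is compared against the ortholog mean to call it a new
duplication or the relic of an ancestral duplicate whose twin was lost.
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from common import load_genome, load_hits, out_path

from pprdup import pipeline


def main() -> None:
    genome_a = load_genome("A")
    genome_b = load_genome("B")
    cls_a = pipeline.classify_family(genome_a, load_hits("A"))
    cls_b = pipeline.classify_family(genome_b, load_hits("B"))
    orth = pipeline.run_orthology(genome_a, genome_b, sorted(cls_a), sorted(cls_b))
    hit_sets = {"A": pipeline.paralog_hits(genome_a),
                "B": pipeline.paralog_hits(genome_b)}
    res = pipeline.run_origin_inference(
        genome_a, genome_b, orth.shared,
        {"A": orth.specific_a, "B": orth.specific_b}, hit_sets)

    pd.DataFrame(
        [(r.gene_1, r.gene_2, round(r.ks, 4), round(r.ka, 4), r.codons_used)
         for r in res.ortholog_ks],
        columns=["gene_a", "gene_b", "ks", "ka", "codons"],
    ).to_csv(out_path("ortholog_ks.tsv"), sep="\t", index=False)
    print(f"mean ortholog Ks over {len(res.ortholog_ks)} syntenic pairs: "
          f"{res.mean_ortholog_ks:.4f}")
    for label, genome in (("A", genome_a), ("B", genome_b)):
        rows = [(c.gene_id, c.min_paralog_ks, c.origin) for c in res.calls[label]]
        pd.DataFrame(rows, columns=["gene_id", "min_paralog_ks", "origin"]).to_csv(
            out_path(f"{genome.name}.origins.tsv"), sep="\t", index=False)
        n_new = sum(c.origin == "new_duplication" for c in res.calls[label])
        n_loss = sum(c.origin == "ancestral_loss" for c in res.calls[label])
        n_unres = sum(c.origin == "unresolved" for c in res.calls[label])
        print(f"{genome.name}: {n_new} new duplications, {n_loss} copy losses, "
              f"{n_unres} unresolved among {len(res.calls[label])} specific genes")


if __name__ == "__main__":
    main()
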