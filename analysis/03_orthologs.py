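#!/usr/bin/env python
"""Shared vs species-specific PPR genes via RBH plus local synteny.

Computes genome-wide reciprocal best hits, applies the five-gene
local-synteny filter to family pairs, and writes the ortholog table and
per-genome specific-gene lists.
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from common import load_genome, load_hits, out_path

from pprdup import pipeline
from pprdup.homology import ortholog_table


def main() -> None:
    genome_a = load_genome("A")
    genome_b = load_genome("B")
    cls_a = pipeline.classify_family(genome_a, load_hits("A"))
    cls_b = pipeline.classify_family(genome_b, load_hits("B"))
    res = pipeline.run_orthology(genome_a, genome_b, sorted(cls_a), sorted(cls_b))

    ortholog_table(res.shared).to_csv(
        out_path("ppr_orthologs.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"gene_id": res.specific_a}).to_csv(
        out_path(f"{genome_a.name}.specific.tsv"), sep="\t", index=False)
    pd.DataFrame({"gene_id": res.specific_b}).to_csv(
        out_path(f"{genome_b.name}.specific.tsv"), sep="\t", index=False)
    pd.DataFrame(res.rbh_all, columns=["gene_a", "gene_b"]).to_csv(
        out_path("rbh_all_genes.tsv"), sep="\t", index=False)

    n_strict = sum(p.status == "shared" for p in res.shared)
    print(f"genome-wide RBH pairs: {len(res.rbh_all)}")
    print(f"shared PPR pairs: {len(res.shared)} "
          f"({n_strict} passing the synteny filter); "
          f"{100 * n_strict / len(cls_a):.2f}% of the {genome_a.name} family")
    print(f"species-specific PPR genes: {len(res.specific_a)} in "
          f"{genome_a.name}, {len(res.specific_b)} in {genome_b.name}")


if __name__ == "__main__":
    main()
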