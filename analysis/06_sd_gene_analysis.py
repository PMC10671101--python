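#!/usr/bin/env python
"""Intersect SDs with PPR genes: completeness, pair types, acquisitions.

Classifies each SD-derived family gene as a complete or incomplete
duplication, types the duplicate pair by subgroup, computes protein-product
similarity, and calls domain-acquisition direction against the outgroup
(outgroup orthologs from reciprocal best hits).
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from common import load_genome, load_hits, load_repeats, out_path

from pprdup import pipeline
from pprdup.homology import all_vs_all, reciprocal_best_hits
from pprdup.sdgenes import detect_domain_acquisition, sd_gene_table


def main() -> None:
    outgroup = load_genome("O")
    out_hits = load_hits("O")
    for label in ("A", "B"):
        genome = load_genome(label)
        cls = pipeline.classify_family(genome, load_hits(label))
        res = pipeline.run_sd_analysis(genome, load_repeats(label), cls)
        table = sd_gene_table(res.gene_pairs)
        table.to_csv(out_path(f"{genome.name}.sd_genes.tsv"), sep="\t", index=False)

        og_map = dict(reciprocal_best_hits(
            all_vs_all(genome.proteins, outgroup.proteins),
            all_vs_all(outgroup.proteins, genome.proteins),
        ))
        calls = []
        for pair in res.gene_pairs:
            if pair.pair_category == "PPR-Other" and pair.completeness == "incomplete":
                call = detect_domain_acquisition(
                    pair, genome, load_hits(label), out_hits, og_map)
                if call:
                    calls.append((call.focal_gene, call.partner_gene,
                                  call.domain_type, call.direction, call.evidence))
        pd.DataFrame(calls, columns=["focal", "partner", "domain", "direction",
                                     "evidence"]).to_csv(
            out_path(f"{genome.name}.acquisitions.tsv"), sep="\t", index=False)

        with_partner = [p for p in res.gene_pairs if p.partner_gene]
        n_c = sum(p.completeness == "complete" for p in with_partner)
        sims = [p.protein_similarity for p in with_partner
                if p.protein_similarity is not None]
        print(f"{genome.name}: {len({p.focal_gene for p in res.gene_pairs})} "
              f"SD-derived PPR genes; {n_c} complete / "
              f"{len(with_partner) - n_c} incomplete duplications")
        if sims:
            print(f"  mean protein similarity of duplicate pairs: "
                  f"{sum(sims) / len(sims):.2f}%")
        for c in calls:
            print(f"  domain acquisition: {c[0]} gained {c[2]} from {c[1]} "
                  f"({c[3]}; {c[4]})")


if __name__ == "__main__":
    main()
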