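#!/usr/bin/env python
"""Type within-genome duplicate pairs: WGD / tandem / proximal / dispersed.

Runs the within-genome similarity search, chains collinear anchors for WGD
calls, and writes pair tables, per-gene labels, and family vs genome-wide
proportions with the dispersed-duplication enrichment ratio.
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from common import load_genome, load_hits, out_path

from pprdup import pipeline
from pprdup.duptypes import dup_type_proportions, pair_table
from pprdup.report import enrichment_ratio


def main() -> None:
    for label in ("A", "B"):
        genome = load_genome(label)
        cls = pipeline.classify_family(genome, load_hits(label))
        res = pipeline.run_duptypes(genome)
        pair_table(res.pairs).to_csv(
            out_path(f"{genome.name}.dup_pairs.tsv"), sep="\t", index=False)
        fam = dup_type_proportions(res.pairs, cls)
        allg = dup_type_proportions(res.pairs, [g.gene_id for g in genome.genes])
        pd.DataFrame({"family": fam, "genome": allg}).to_csv(
            out_path(f"{genome.name}.dup_proportions.tsv"), sep="\t")
        print(f"{genome.name}: {len(res.pairs)} paralog pairs, "
              f"{len(res.blocks)} collinear blocks")
        for t in fam.index:
            print(f"  {t:9s} family {100 * fam[t]:6.2f}%   "
                  f"genome {100 * allg[t]:6.2f}%")
        if allg["dispersed"] > 0 and fam["dispersed"] > 0:
            ratio = enrichment_ratio(100 * fam["dispersed"], 100 * allg["dispersed"])
            print(f"  dispersed enrichment (family over genome): {ratio}")


if __name__ == "__main__":
    main()
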