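#!/usr/bin/env python
"""Generate the synthetic genome pair (plus outgroup) used by the analysis.

Writes the full fixture set — FASTA/GFF3/protein/CDS per genome, domain-hit
TSVs, repeat BEDs, replicated count matrices — plus the planted-truth
ortholog table under results/data/.
"""

import argparse
import sys

sys.path.insert(0, "analysis")
from common import DATA_DIR

from pprdup.simulate import SimulationConfig, simulate, write_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default=DATA_DIR)
    args = parser.parse_args()

    ds = simulate(SimulationConfig(seed=args.seed))
    paths = write_dataset(ds, args.out)
    for lab in ("A", "B"):
        g = ds.genome(lab)
        sizes = {c: len(s) for c, s in g.sequences.items()}
        print(f"{g.name}: {len(g.genes)} genes, "
              f"{len(ds.truth.ppr_genes[lab])} planted PPR genes, "
              f"chromosomes {sizes}")
    print(f"planted SDs per genome: {len(ds.config.planted_sds)}")
    print(f"wrote {len(paths)} files under {args.out}")


if __name__ == "__main__":
    main()
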