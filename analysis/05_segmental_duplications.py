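#!/usr/bin/env python
"""Detect segmental duplications by whole-genome self-comparison.

Repeat removal, 400-kb fragmentation, k-mer seeded alignment, repeat
reinsertion with end trimming, and the >1 kb / >90% identity finalization.
Writes the SD table, BED pairs, and a 1-Mb density track per genome.
"""

import sys

sys.path.insert(0, "analysis")
from common import load_genome, load_repeats, out_path

from pprdup import io as pio
from pprdup.sddetect import density_track, detect_sds, sd_table


def main() -> None:
    for label in ("A", "B"):
        genome = load_genome(label)
        sds = detect_sds(genome, load_repeats(label))
        table = sd_table(sds)
        table.to_csv(out_path(f"{genome.name}.sds.tsv"), sep="\t", index=False)
        pio.write_bed(
            [iv for sd in sds for iv in (sd.copy_a, sd.copy_b)],
            out_path(f"{genome.name}.sds.bed"),
        )
        density_track(sds, genome.sequences).to_csv(
            out_path(f"{genome.name}.sd_density.tsv"), sep="\t", index=False)
        print(f"{genome.name}: {len(sds)} segmental duplications")
        for sd in sds:
            print(f"  {sd.copy_a.chromosome}:{sd.copy_a.start}-{sd.copy_a.end} <-> "
                  f"{sd.copy_b.chromosome}:{sd.copy_b.start}-{sd.copy_b.end}  "
                  f"{sd.identity:.2f}% over {sd.aligned_length} bp "
                  f"({sd.orientation})")


if __name__ == "__main__":
    main()
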