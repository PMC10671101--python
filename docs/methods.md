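# Methods

`pprdup` re-implements, as a tested pipeline, a comparative analysis of the
pentatricopeptide-repeat (PPR) gene family between two closely related
annotated genomes (a cultivated rice-like genome and its wild-progenitor-like
counterpart, plus an outgroup). This note documents the models, the
parameters that matter, the synthetic data the pipeline is validated on, and
the design choices made where the design was genuinely open.

## Family identification and classification

PPR proteins are tandem arrays of ~35-aa helical repeats. Identification
works from a domain-hit table (protein, motif type, aa coordinates,
E-value); running the profile search itself is out of scope — hits are an
input. Hits at E-value ≥ 10 are discarded; a protein is a family member when
it retains at least two PPR repeat motifs (types P, L, S). C-terminal E1,
E2, E+ and DYW domains do not count toward that minimum (the rule concerns
repeat motifs; a `count_cterm` switch restores the permissive reading).
Overlapping hits on one protein (>50% of the shorter span) are collapsed
keeping the lower E-value, so a motif reported twice cannot inflate counts.

Classification: a protein is PLS-class iff its architecture contains an L or
S motif or any C-terminal domain, else P-class. The subgroup of a PLS
protein is the most C-terminal of {E1, E2, E+, DYW} present (matching the
E→E+→DYW architecture order); PLS proteins with none keep the generic PLS
label. P-motif-only proteins with an isolated C-terminal domain are legal
but unusual; they are classified PLS and flagged for review.

## Orthology: reciprocal best hits with a local-synteny filter

Similarity search is a built-in global protein aligner (BLOSUM62, affine
gaps open 11 / extend 1, score threshold 50) with a shared-5-mer prefilter
for speed; 12-column tabular output from an external search tool can be
substituted. Reciprocal best hits (RBH) require each gene to be the other's
unique best scorer; tied best scores disqualify a gene (conservative — a tie
means the data cannot distinguish the candidates).

The local-synteny filter asks, for a candidate pair (a, b): on each side of
`a`, do any of the five nearest genes have an RBH partner within five gene
ranks of `b` on b's chromosome? A side with no genes at all (chromosome end)
is waived; strict mode (partner must be near `b`) is the default, an
"anywhere" mode only requires the neighbour to have some partner. Both modes
are exposed because the published criterion states the window but not the
partner constraint. Family genes in no RBH pair with a family partner are
species-specific.

## Duplication typing

Within-genome paralog pairs are typed with the standard collinearity-based
scheme: WGD (pair is an anchor in a collinear block of ≥ 5 anchors with
consecutive rank gaps ≤ 25 on both chromosomes), tandem (same chromosome,
adjacent ranks), proximal (rank distance 2–10), dispersed (the rest);
priority WGD > tandem > proximal > dispersed, for pairs and for per-gene
labels. Blocks are extracted greedily: repeated longest-monotone-chain
dynamic programming per chromosome pair and orientation (same/inverted),
verified against exhaustive search on small instances. The transposed
category of some tools is deliberately omitted; results are reported over
the four categories above.

## Segmental-duplication (SD) detection

Whole-genome assembly self-comparison in four stages:

1. **Repeat removal.** Annotated repeats are excised; an exact piecewise
   coordinate map converts condensed ↔ assembly coordinates.
2. **Fragmentation.** Condensed sequence is cut into trackable ≤ 400-kb
   fragments carrying their origin offsets.
3. **Seeded alignment.** Exact 16-mer seeds over the fragment set (both
   orientations; k-mers occurring > 64 times masked), two-hit chaining per
   diagonal (seed gaps ≤ 400 bp, chained span ≥ 120 bp), candidate boxes
   globally realigned with edlib. Raw alignments must exceed 88% identity
   over more than 200 bp. The trivial self-diagonal is excluded.
4. **Reinsertion and finalization.** Alignments are lifted back to assembly
   coordinates (re-acquiring interior repeats); neighbours separated only by
   repeat-annotated sequence on both copies (gap ≤ 10 kb, ≥ 80%
   repeat-covered) are merged, as are abutting alignments with gaps
   ≤ 200 bp on both copies (these arise when an event straddles a 400-kb
   fragment boundary); each candidate is realigned on the assembly
   with a 400-bp margin and trimmed from both ends while terminal 50-bp
   windows fall below 85% identity. Kept iff aligned length > 1 kb and
   identity > 90%.

Identity is matches / alignment columns, indel columns counting against it
— the stricter of the two common conventions, asserted in tests. Copies
overlapping each other by more than 10% of the shorter copy are dropped
(tandem-repeat self-hits), and near-duplicate calls (≥ 80% reciprocal
overlap on both copies) are collapsed keeping the longer. The end-trimming
criterion is this package's own: the assembly-comparison recipe says only
that ends are trimmed. With indels the chainer may split one event across
nearby diagonals; the realignment margin and deduplication re-join moderate
cases.

## SD–gene intersection and domain acquisition

A family gene is SD-derived when any CDS base overlaps an SD copy. The
partner is the gene whose CDS most overlaps the homologous interval obtained
by projecting the overlapped region through the SD's piecewise coordinate
map (ties break to the smaller gene id; positions falling in alignment gaps
project to the nearest mapped base). A duplication is complete iff the SD
copy contains the full gene span, transcription start to end (UTRs
included; a CDS-span mode exists). Pairs are typed by subgroup
("P-P", "DYW-E2", "P-Other", …). Protein-product similarity is the
percentage of global-alignment columns with identical or positively-scoring
(BLOSUM62) residues.

Domain acquisition: for an incomplete duplication with a non-PPR partner, a
transfer is called when the homologous region projected onto the focal
protein covers ≥ 50% of a non-PPR domain the partner also carries. Direction
comes from the outgroup: if the focal gene's outgroup ortholog lacks the
domain while the partner's has it, the focal gene is the *accepter*;
reversed states give *donor*; anything else (including missing outgroup
orthologs) is ambiguous. The 50% coverage rule is this package's choice —
the underlying idea is only that the shared sequence is a domain, not a PPR
motif.

## Ks estimation and the origin of specific genes

Pairs are codon-aligned by back-translating a global protein alignment;
gap-containing columns are removed. Ka/Ks uses the Nei–Gojobori counting
method: synonymous site fractions per codon under the standard code (changes
to stops counted as nonsynonymous, so S + N = 3 × codons), pathway averaging
for codons differing at 2–3 positions with uniform weights over minimal
pathways avoiding stop codons, and the Jukes–Cantor correction
d = −3/4·ln(1 − 4/3·p). Proportions ≥ 0.75 are flagged saturated. NG86 is
used instead of a maximum-likelihood estimator because it is fully
specifiable and oracle-checkable (tests compare it against an independent
enumeration); validation is property-based (divergence recovery), not
numeric reproduction of any published Ks value.

Origin inference: a species-specific gene's minimum Ks over its
within-genome paralogs approximates its most recent duplication; below the
mean Ks of syntenic ortholog pairs the gene post-dates the species split
(new duplication), above it the other genome lost its copy of an old
duplicate (ancestral loss). Paralogs default to all within-genome similarity
hits (an option restricts to typed pairs). Ortholog pairs on unanchored or
non-syntenic sequence are excluded from the mean.

## Expression divergence of sister duplicates

Counts are normalised to TPM over summed exon length (columns sum to 10⁶).
Mean TPM per tissue is binned: very high ≥ 50, high [10, 50), moderate
[2, 10), low [0.1, 2), very low (0, 0.1), plus a sixth level "none" for
exactly zero (the published "very low" bin is open at 0).

Per-tissue differential tests on sister pairs use a moderated t on
log2(TPM+1): the per-contrast variance is shrunk toward the
transcriptome-wide replicate variance with 10 prior degrees of freedom
(limma-style empirical Bayes). A plain Welch t at three replicates does not
reach the power that count-model tools obtain by sharing dispersion across
genes; moderation restores it while keeping the published decision rule
verbatim: a copy is called higher only when fold change > 2 (on mean TPM,
pseudocount 0.1) and BH-adjusted p < 0.05, adjusted over every pair × tissue
test of the run. Classes: *sub_neo* if each copy is called higher somewhere;
*AED* if one copy is called higher in ≥ 2 tissues and never lower ("not
lower" read as "not significantly lower", the only testable reading; an
exact-two switch exists); otherwise *no difference*. Evaluation order
sub_neo → AED → no_difference; the result is invariant to tissue order.

## Reporting conventions

Every percentage is recomputed from its integer numerator and denominator
and rounded half-away-from-zero at two decimals; enrichment ratios divide
the rounded percentages. This convention reproduces published values such
as 52/460 → 11.30 and 87.99/69.99 → 1.26. One published ratio (~1.40) is
not reproducible from its own printed inputs (82.64/58.63 = 1.4095 → 1.41);
the report prints the computed 1.41 and the discrepancy is documented here
rather than patched.

## The synthetic genome pair

The generator builds an ancestral gene layout, realizes genome A from it
unchanged, genome B by evolving every part at the configured ortholog
divergence (default Ks 0.05, Ka/Ks ω = 0.2; non-coding sequence at the
synonymous rate), and an outgroup at Ks 0.15. Defaults: 2 chromosomes × 300
genes (≈ 2.1 Mb each, ≈ 4.3 Mb per genome), 60 PPR genes with subgroup mix
P 0.48 / E1 0.10 / E2 0.14 / E+ 0.10 / DYW 0.18, log-normal intergenic
spacers (median 4.5 kb), ~20% of spacers carrying an annotated repeat drawn
from a small mutated repeat library, 35-aa P motifs (L 36, S 31) and
C-terminal domains of 70–100 aa. Planted structures:

* **Orthologs** — shared layout order, so local synteny holds exactly.
* **Specific genes** — per genome, 4 *new duplications* (intron-less copies
  of short PPR genes at Ks ≈ 0.01, protein divergence inflated so RBH stays
  with the true ortholog, CDS ≤ ~900 bp so they sit below the SD length
  cutoff) and 3 *copy losses* (ancestral PPR duplicate pairs at Ks ≈ 0.35;
  the other genome deletes one copy).
* **Duplicate pairs** — 4 tandem (half PPR), 3 proximal, one 6-gene WGD
  block, 6 dispersed pairs, at ~80% DNA identity so none qualifies as an SD.
  Cross-chromosome plantings avoid the WGD block's rank neighbourhood, where
  the chainer would legitimately absorb them.
* **SDs** — per genome: a 2-kb complete duplication of a PPR gene at 95%
  identity, a 1.5-kb incomplete domain-acquisition event at 92% (a shared
  PPR gene gains an in-frame non-PPR domain copied from a donor gene; its
  outgroup ortholog keeps the ancestral, domain-free state), and a 3-kb
  incomplete 5′ duplication of a PPR gene at 98%. Substitution-only
  mutation places an exact number of substitutions, so realized identity
  equals the target; coding regions are mutated stop-aware.
* **Expression** — negative-binomial counts (dispersion 0.1, log-normal
  base means ≈ 120), 4 tissues × 3 replicates; planted AED pairs get a
  4-fold mean excess in two tissues, sub_neo pairs opposite excesses, and
  no-difference pairs equal means.

Unrelated genes get independent random sequences, so the similarity graph
contains exactly the planted edges. That is the generator's main departure
from real data, along with: all genes on the forward strand, no
transposon sequence evolution (repeats are annotated intervals), no
alternative splicing, substitution-only divergence by default (an indel
mode exists for robustness tests), and no residual family-wide similarity
between unrelated PPR genes. Passing the recovery tests therefore shows the
pipeline implements its rules correctly under the stated noise models — not
that it is robust to annotation error, assembly gaps, or deep family
paralogy in real genomes.

## Numerical choices and degenerate inputs

Ties: RBH ties disqualify; partner-gene ties break to the smaller id;
representative transcript is the longest CDS, ties lexicographic. Empty
inputs: empty protein/gene sets and all-zero count columns raise; an empty
SD table produces an all-zero report section rather than an error. Genome
sizes in the validation runs (≈ 4.3 Mb per genome, 100-kb null genomes ×
100 seeds, 1000-codon × 50-seed Ks recovery, 50-seed expression recovery)
were chosen to exercise every stage at full fidelity on a single CPU in
minutes.

## Known limitations

* SD detection assumes a repeat annotation of the quality the generator
  provides; unannotated high-copy repeats would surface as SD calls (as in
  the original assembly-comparison method).
* The collinearity chainer can absorb a genuinely collinear-looking
  dispersed pair adjacent to a real block — an ambiguity inherent to
  rank-based typing, handled in the generator rather than the classifier.
* NG86 saturates above p ≈ 0.75; old duplicates near saturation are flagged
  rather than dated.
* The moderated-t expression test assumes roughly homoscedastic log-scale
  noise across genes; strongly expression-dependent dispersion would
  call for a full count model.
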