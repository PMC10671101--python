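"""Synthetic annotated genome pairs with planted truth.

The generator emulates the data a cultivated/wild genome-pair comparison
consumes: two annotated genomes that share most genes in conserved order
(so local synteny holds for true orthologs), an outgroup genome frozen in
the ancestral state, PPR genes with planted motif architectures, species-
specific genes created either by post-split duplication (low paralog Ks) or
by loss of one ortholog copy (high paralog Ks), tandem / proximal / WGD /
dispersed paralog pairs, sequence-level segmental duplications of
controlled identity that cover genes completely or partially (including
in-frame domain acquisitions from non-PPR donors), annotated repeats, and
negative-binomial expression counts with planted asymmetries.

Every sequence relationship is planted explicitly: unrelated genes get
independent random sequences, so the similarity graph contains exactly the
planted edges. Mutations are substitution-only by default, which keeps
identity arithmetic exact; an indel mode exists for robustness tests.
All randomness flows from one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from functools import lru_cache as _lru_cache
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DomainHit, GeneModel, Genome, GenomicInterval
from .expression import CountMatrix
from .kaks import _CODON_TABLE

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c, _a in _CODON_TABLE.items():
    if _a != "*":
        _CODONS_BY_AA.setdefault(_a, []).append(_c)
for _a in _CODONS_BY_AA:
    _CODONS_BY_AA[_a].sort()

MOTIF_LENGTHS = {"P": 35, "L": 36, "S": 31}
CTERM_LENGTHS = {"E1": 86, "E2": 76, "E+": 70, "DYW": 100}
_FOREIGN_DOMAINS = ("S_TKc", "Calreticulin", "Mem_trans", "Gal-bind_lectin", "p450")

GENOME_LABELS = ("A", "B", "O")


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSDSpec:
    length: int
    identity: float  # percent, in (88, 100]
    completeness: str  # complete | incomplete
    partner_class: str  # PPR-same | PPR-other | non-PPR

    def __post_init__(self) -> None:
        if not 88 < self.identity <= 100:
            raise ConfigError(f"SD identity {self.identity} outside (88, 100]")
        if self.completeness not in ("complete", "incomplete"):
            raise ConfigError(f"bad completeness {self.completeness}")
        if self.partner_class not in ("PPR-same", "PPR-other", "non-PPR"):
            raise ConfigError(f"bad partner class {self.partner_class}")
        if self.length < 900:
            raise ConfigError("planted SDs must be at least 900 bp")


@dataclass(frozen=True)
class ExpressionParams:
    tissues: tuple[str, ...] = ("root", "leaf", "seedling", "panicle")
    replicates: int = 3
    dispersion: float = 0.1
    base_log_mean: float = math.log(120.0)
    base_log_sigma: float = 0.6
    planted_fold: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 2
    genes_per_chromosome: int = 300
    mean_gene_length: int = 2400
    mean_intergenic: int = 4500
    n_ppr_genes: int = 60
    subfamily_mix: tuple[tuple[str, float], ...] = (
        ("P", 0.48), ("E1", 0.10), ("E2", 0.14), ("E+", 0.10), ("DYW", 0.18),
    )
    ortholog_divergence: float = 0.05  # expected Ks between the two genomes
    outgroup_divergence: float = 0.15
    omega: float = 0.2  # Ka/Ks for lineage divergence
    n_specific_new: int = 4  # per genome
    n_specific_loss: int = 3  # per genome
    planted_sds: tuple[PlantedSDSpec, ...] = (
        PlantedSDSpec(2000, 95.0, "complete", "PPR-same"),
        PlantedSDSpec(1500, 92.0, "incomplete", "PPR-other"),
        PlantedSDSpec(3000, 98.0, "incomplete", "PPR-same"),
    )
    n_tandem: int = 4  # half PPR, half plain
    n_proximal: int = 3
    n_wgd_block_genes: int = 6
    n_dispersed_pairs: int = 6
    repeat_fraction: float = 0.2  # of intergenic spacers carrying a repeat
    expression: ExpressionParams = ExpressionParams()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "genes_per_chromosome", "n_ppr_genes",
            "n_specific_new", "n_specific_loss", "n_tandem", "n_proximal",
            "n_dispersed_pairs",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        total = sum(w for _, w in self.subfamily_mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("subfamily mix proportions must sum to 1")
        approx_chrom = self.genes_per_chromosome * (
            self.mean_gene_length + self.mean_intergenic
        )
        for sd in self.planted_sds:
            if sd.length > approx_chrom // 4:
                raise ConfigError("planted SD longer than a chromosome quarter")
        if self.n_ppr_genes > self.n_chromosomes * self.genes_per_chromosome // 3:
            raise ConfigError("too many PPR genes for the gene space")


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

@dataclass
class SDTruth:
    source: GenomicInterval
    copy: GenomicInterval
    identity: float
    completeness: str
    partner_class: str
    focal_gene: str | None
    partner_gene: str | None


@dataclass
class TruthTables:
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    ppr_genes: dict[str, dict[str, tuple[str, str, int]]] = field(default_factory=dict)
    specific_genes: dict[str, set[str]] = field(default_factory=dict)
    origin_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    dup_pairs: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    sds: dict[str, list[SDTruth]] = field(default_factory=dict)
    acquisitions: dict[str, list[tuple[str, str, str, str]]] = field(default_factory=dict)
    expression_classes: dict[str, list[tuple[str, str, str, str | None]]] = field(
        default_factory=dict
    )
    outgroup_map: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome_a: Genome
    genome_b: Genome
    outgroup: Genome
    domain_hits: dict[str, list[DomainHit]]
    repeats: dict[str, list[GenomicInterval]]
    counts: dict[str, CountMatrix]
    truth: TruthTables

    def genome(self, label: str) -> Genome:
        return {"A": self.genome_a, "B": self.genome_b, "O": self.outgroup}[label]


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def backtranslate(protein: str, rng: np.random.Generator) -> str:
    """Random codon choice per residue; terminal stop appended."""
    codons = [_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein]
    codons.append(("TAA", "TAG", "TGA")[rng.integers(3)])
    return "".join(codons)


def _p_from_d(d: float) -> float:
    """Expected mismatch proportion for Jukes-Cantor divergence d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def mutate_neutral(seq: str, d: float, rng: np.random.Generator) -> str:
    """Substitution-only neutral mutation at JC divergence d."""
    if d <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < _p_from_d(d)
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


@_lru_cache(maxsize=None)
def _syn_alternatives(codon: str, pos: int) -> list[str]:
    aa = _CODON_TABLE[codon]
    out = []
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if _CODON_TABLE[alt] == aa:
            out.append(b)
    return out


@_lru_cache(maxsize=None)
def _nonsyn_alternatives(codon: str, pos: int) -> list[str]:
    aa = _CODON_TABLE[codon]
    out = []
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if _CODON_TABLE[alt] not in ("*", aa):
            out.append(b)
    return out


def evolve_cds(cds: str, d_s: float, d_n: float, rng: np.random.Generator) -> str:
    """Evolve a CDS at synonymous divergence d_s and nonsynonymous d_n.

    Substitutions are placed per position with Jukes-Cantor-consistent
    probabilities, separately over the synonymous and nonsynonymous
    fractions of each site; stop codons are never created and a terminal
    stop codon is preserved.
    """
    p_s = _p_from_d(d_s)
    p_n = _p_from_d(d_n)
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    out = []
    for ci, codon in enumerate(codons):
        if _CODON_TABLE.get(codon) == "*":
            out.append(codon)  # terminal stop kept as-is
            continue
        cur = codon
        for pos in range(3):
            syn = _syn_alternatives(cur, pos)
            non = _nonsyn_alternatives(cur, pos)
            r = rng.random()
            p_syn_here = p_s * len(syn) / 3.0
            p_non_here = p_n * len(non) / 3.0
            if r < p_syn_here:
                cur = cur[:pos] + syn[rng.integers(len(syn))] + cur[pos + 1 :]
            elif r < p_syn_here + p_non_here:
                cur = cur[:pos] + non[rng.integers(len(non))] + cur[pos + 1 :]
        out.append(cur)
    tail = cds[len(codons) * 3 :]
    return "".join(out) + tail


def mutate_to_identity(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    coding_ranges: Sequence[tuple[int, int]] = (),
    indel_rate: float = 0.0,
    indel_mean: float = 3.0,
) -> str:
    """Mutate a sequence so realized identity equals the target.

    Exactly ``round((1 - target/100) * len)`` positions are substituted,
    uniformly at random. Within ``coding_ranges`` (frame-0 half-open
    segments) substitutions never create a stop codon and existing stop
    codons are left intact. With ``indel_rate`` > 0, short indels
    (geometric lengths, mean ``indel_mean``) replace part of the
    substitution budget.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    n = len(seq)
    n_sub = round((1.0 - target_identity / 100.0) * n)
    if n_sub == 0 and indel_rate == 0:
        return seq
    arr = list(seq)
    protected: set[int] = set()
    coding_pos: dict[int, int] = {}  # position -> codon start
    for start, end in coding_ranges:
        for cstart in range(start, end - 2, 3):
            codon = seq[cstart : cstart + 3]
            if codon in _STOPS:
                protected.update((cstart, cstart + 1, cstart + 2))
            else:
                for off in range(3):
                    coding_pos[cstart + off] = cstart
    candidates = [i for i in range(n) if i not in protected]
    rng.shuffle(candidates)
    n_indel_events = rng.poisson(indel_rate * n) if indel_rate > 0 else 0
    placed = 0
    it = iter(candidates)
    while placed < n_sub:
        try:
            i = next(it)
        except StopIteration:
            break
        cur = arr[i]
        options = [b for b in "ACGT" if b != cur]
        if i in coding_pos:
            cstart = coding_pos[i]
            safe = []
            for b in options:
                codon = "".join(arr[cstart : cstart + 3])
                off = i - cstart
                alt = codon[:off] + b + codon[off + 1 :]
                if alt not in _STOPS:
                    safe.append(b)
            options = safe
        if not options:
            continue
        arr[i] = options[rng.integers(len(options))]
        placed += 1
    seq_out = "".join(arr)
    for _ in range(n_indel_events):
        length = int(rng.geometric(1.0 / indel_mean))
        pos = int(rng.integers(1, max(2, len(seq_out) - length - 1)))
        if rng.random() < 0.5:
            seq_out = seq_out[:pos] + seq_out[pos + length :]
        else:
            seq_out = seq_out[:pos] + random_dna(rng, length) + seq_out[pos:]
    return seq_out


def random_genome(length: int, seed: int, n_chromosomes: int = 1) -> dict[str, str]:
    """Plain random chromosomes (null model for detector false positives)."""
    rng = np.random.default_rng(seed)
    per = length // n_chromosomes
    return {f"chr{i + 1}": random_dna(rng, per) for i in range(n_chromosomes)}


# ---------------------------------------------------------------------------
# PPR architectures
# ---------------------------------------------------------------------------

@dataclass
class Architecture:
    subfamily: str  # P | PLS
    subgroup: str  # P | E1 | E2 | E+ | DYW
    motifs: list[str]  # N->C order of motif/domain tokens
    extra_domain: str | None = None  # acquired non-PPR domain (fusion genes)

    @property
    def n_ppr_motifs(self) -> int:
        return sum(m in MOTIF_LENGTHS for m in self.motifs)

    def aa_length(self) -> int:
        return sum(
            MOTIF_LENGTHS.get(m) or CTERM_LENGTHS[m] for m in self.motifs
        )

    def hits(self, protein_id: str, rng: np.random.Generator) -> list[DomainHit]:
        out = []
        pos = 1
        for m in self.motifs:
            length = MOTIF_LENGTHS.get(m) or CTERM_LENGTHS[m]
            evalue = float(10.0 ** rng.uniform(-40, -2))
            out.append(DomainHit(protein_id, m, pos, pos + length - 1, evalue))
            pos += length
        return out


def _make_architecture(
    subgroup: str, rng: np.random.Generator, n_motifs: int | None = None
) -> Architecture:
    if n_motifs is None:
        n_motifs = int(np.clip(rng.poisson(12), 3, 28))
    if subgroup == "P":
        return Architecture("P", "P", ["P"] * n_motifs)
    pattern = ["P", "L", "S"]
    motifs = [pattern[i % 3] for i in range(n_motifs)]
    cterm_chain = {"E1": ["E1"], "E2": ["E1", "E2"], "E+": ["E1", "E2", "E+"],
                   "DYW": ["E1", "E2", "E+", "DYW"]}[subgroup]
    return Architecture("PLS", subgroup, motifs + cterm_chain)


def _ppr_protein(arch: Architecture, rng: np.random.Generator) -> str:
    return random_protein(rng, arch.aa_length())


# ---------------------------------------------------------------------------
# Gene specifications (ancestral state)
# ---------------------------------------------------------------------------

@dataclass
class GeneSpec:
    index: int
    chrom: int
    kind: str  # plain | ppr | pseudo1
    protein: str
    cds: str  # includes terminal stop codon
    exon_pieces: list[int]  # CDS nt per exon (codon multiples)
    introns: list[str]
    utr5: str
    utr3: str
    spacer_before: str
    repeat_span: tuple[int, int] | None  # within spacer_before
    tail: str = ""  # intergenic sequence glued after the gene (SD flanks)
    architecture: Architecture | None = None
    foreign_domain: tuple[str, int, int] | None = None  # (name, aa_start, aa_end)
    present: set[str] = field(default_factory=lambda: {"A", "B", "O"})
    # planted-role bookkeeping
    role: str = ""

    def base_id(self) -> str:
        return f"{self.index:05d}"


def _gene_id(label: str, spec_index: int) -> str:
    prefix = {"A": "OsA", "B": "OsB", "O": "Out"}[label]
    return f"{prefix}g{spec_index:05d}"


def _split_cds(cds_len_nostop: int, n_exons: int, rng: np.random.Generator) -> list[int]:
    """Split a CDS (without stop) into exon pieces at codon boundaries."""
    n_codons = cds_len_nostop // 3
    if n_exons <= 1 or n_codons < 2 * n_exons:
        return [cds_len_nostop + 3]
    cuts = sorted(rng.choice(np.arange(1, n_codons), size=n_exons - 1, replace=False))
    pieces = []
    prev = 0
    for c in list(cuts) + [n_codons]:
        pieces.append((c - prev) * 3)
        prev = c
    pieces[-1] += 3  # stop codon rides in the last exon
    return pieces


_EXON_COUNT_CHOICES = np.array([1, 2, 3, 4, 5, 6, 7])
_EXON_COUNT_PROBS = np.array([0.46, 0.21, 0.13, 0.08, 0.06, 0.04, 0.02])


# ---------------------------------------------------------------------------
# Planted-structure plans
# ---------------------------------------------------------------------------

@dataclass
class _NewDupPlan:
    genome: str
    source_index: int
    new_index: int
    insert: tuple[int, int]  # (chromosome, after_slot)


@dataclass
class _SDPlan:
    spec: PlantedSDSpec
    genome: str
    donor_index: int
    focal_index: int | None = None  # PPR-other: shared focal gene
    new_index: int | None = None  # PPR-same / non-PPR: the copy gene
    insert: tuple[int, int] | None = None
    kept_cds: int = 0
    dom_off: int = 0


@dataclass
class _Plan:
    grid: list[list[GeneSpec]]  # [chromosome][slot]
    specs: dict[int, GeneSpec]
    new_dups: list[_NewDupPlan]
    sd_plans: list[_SDPlan]
    dup_pairs: list[tuple[int, int, str]]  # spec-index pairs + type (shared)
    loss_pairs: dict[str, list[tuple[int, int]]]  # genome -> (survivor, paralog)
    tandem_ppr: list[tuple[int, int]]
    forbidden_inserts: set[tuple[int, int]]
    repeat_library: list[str]


def _draw_plain_protein_len(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    mean_aa = max(150, cfg.mean_gene_length // 8)
    return int(np.clip(rng.lognormal(math.log(mean_aa), 0.35), 120, 700))


def _make_spacer(
    cfg: SimulationConfig, rng: np.random.Generator, library: list[str]
) -> tuple[str, tuple[int, int] | None]:
    length = max(600, int(rng.lognormal(math.log(cfg.mean_intergenic), 0.5)))
    seq = random_dna(rng, length)
    repeat_span = None
    if library and rng.random() < cfg.repeat_fraction:
        rep = library[rng.integers(len(library))]
        rep = mutate_neutral(rep, 0.10, rng)
        if len(rep) + 200 < length:
            off = int(rng.integers(100, length - len(rep) - 100))
            seq = seq[:off] + rep + seq[off + len(rep):]
            repeat_span = (off, len(rep))
    return seq, repeat_span


def _plain_spec(
    index: int, chrom: int, cfg: SimulationConfig, rng: np.random.Generator,
    library: list[str], n_aa: int | None = None, n_exons: int | None = None,
    role: str = "",
) -> GeneSpec:
    n_aa = n_aa or _draw_plain_protein_len(cfg, rng)
    protein = random_protein(rng, n_aa)
    cds = backtranslate(protein, rng)
    if n_exons is None:
        n_exons = int(rng.choice(_EXON_COUNT_CHOICES, p=_EXON_COUNT_PROBS))
    pieces = _split_cds(len(cds) - 3, n_exons, rng)
    introns = [random_dna(rng, int(rng.integers(150, 800))) for _ in pieces[:-1]]
    spacer, repeat_span = _make_spacer(cfg, rng, library)
    return GeneSpec(
        index, chrom, "plain", protein, cds, pieces, introns,
        random_dna(rng, 150), random_dna(rng, 150), spacer, repeat_span, role=role,
    )


def _ppr_spec(
    index: int, chrom: int, cfg: SimulationConfig, rng: np.random.Generator,
    library: list[str], subgroup: str, n_motifs: int | None = None,
    single_exon: bool = False, role: str = "",
) -> GeneSpec:
    arch = _make_architecture(subgroup, rng, n_motifs)
    protein = _ppr_protein(arch, rng)
    cds = backtranslate(protein, rng)
    if single_exon:
        n_exons = 1
    else:
        n_exons = int(rng.choice(_EXON_COUNT_CHOICES, p=_EXON_COUNT_PROBS))
    pieces = _split_cds(len(cds) - 3, n_exons, rng)
    introns = [random_dna(rng, int(rng.integers(150, 800))) for _ in pieces[:-1]]
    spacer, repeat_span = _make_spacer(cfg, rng, library)
    return GeneSpec(
        index, chrom, "ppr", protein, cds, pieces, introns,
        random_dna(rng, 150), random_dna(rng, 150), spacer, repeat_span,
        architecture=arch, role=role,
    )


def _derived_spec(
    src: GeneSpec, index: int, chrom: int, d_s: float, d_n: float,
    rng: np.random.Generator, cfg: SimulationConfig, library: list[str],
    role: str = "",
) -> GeneSpec:
    from Bio.Seq import Seq

    cds = evolve_cds(src.cds, d_s, d_n, rng)
    protein = str(Seq(cds).translate())[:-1]
    spacer, repeat_span = _make_spacer(cfg, rng, library)
    return GeneSpec(
        index, chrom, src.kind, protein, cds, list(src.exon_pieces),
        [mutate_neutral(iv, 0.3, rng) for iv in src.introns],
        random_dna(rng, 150), random_dna(rng, 150), spacer, repeat_span,
        architecture=src.architecture, role=role,
    )


def _plan(cfg: SimulationConfig, rng: np.random.Generator) -> _Plan:
    C, G = cfg.n_chromosomes, cfg.genes_per_chromosome
    library = [random_dna(rng, int(rng.integers(800, 2500))) for _ in range(3)]
    counter = 0

    def next_index() -> int:
        nonlocal counter
        counter += 1
        return counter - 1

    grid: list[list[GeneSpec | None]] = [[None] * G for _ in range(C)]
    free: list[tuple[int, int]] = [(c, s) for c in range(C) for s in range(G)]
    rng.shuffle(free)
    used: set[tuple[int, int]] = set()

    def claim(c: int, s: int) -> None:
        used.add((c, s))

    def pop_free(pred=None) -> tuple[int, int]:
        rejected: list[tuple[int, int]] = []
        choice = None
        while free:
            c, s = free.pop()
            if (c, s) in used:
                continue
            if pred is None or pred(c, s):
                choice = (c, s)
                break
            rejected.append((c, s))
        free.extend(rejected)
        if choice is None:
            if rejected:  # fall back to a constrained-but-free slot
                choice = rejected[-1]
                free.remove(choice)
            else:
                raise ConfigError(
                    "gene grid exhausted; increase genes_per_chromosome"
                )
        claim(*choice)
        return choice

    def pop_run(length: int, chrom: int | None = None) -> tuple[int, int]:
        order = list(range(C)) if chrom is None else [chrom]
        for _ in range(4000):
            c = order[rng.integers(len(order))]
            s = int(rng.integers(0, G - length))
            if all((c, s + k) not in used for k in range(length)):
                for k in range(length):
                    claim(c, s + k)
                return c, s
        raise ConfigError("could not place a consecutive gene run")

    dup_pairs: list[tuple[int, int, str]] = []
    tandem_ppr: list[tuple[int, int]] = []
    forbidden: set[tuple[int, int]] = set()
    loss_pairs: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    new_dups: list[_NewDupPlan] = []
    sd_plans: list[_SDPlan] = []

    # --- tandem pairs (alternate PPR / plain sources) -----------------------
    for t in range(cfg.n_tandem):
        c, s = pop_run(2)
        if t % 2 == 0:
            src = _ppr_spec(next_index(), c, cfg, rng, library, "P",
                            n_motifs=int(rng.integers(6, 12)), single_exon=True,
                            role="tandem_src")
            cp = _derived_spec(src, next_index(), c, 0.35, 0.15, rng, cfg,
                               library, role="tandem_copy")
            tandem_ppr.append((src.index, cp.index))
        else:
            src = _plain_spec(next_index(), c, cfg, rng, library, role="tandem_src")
            cp = _derived_spec(src, next_index(), c, 0.45, 0.20, rng, cfg,
                               library, role="tandem_copy")
        grid[c][s], grid[c][s + 1] = src, cp
        dup_pairs.append((src.index, cp.index, "tandem"))
        forbidden.add((c, s))  # no insertion between tandem mates

    # --- proximal pairs -----------------------------------------------------
    for _ in range(cfg.n_proximal):
        gap = int(rng.integers(2, 9))
        for _ in range(2000):
            c = int(rng.integers(C))
            s = int(rng.integers(0, G - gap - 1))
            if (c, s) not in used and (c, s + gap) not in used:
                break
        else:
            raise ConfigError("could not place proximal pair")
        claim(c, s)
        claim(c, s + gap)
        src = _plain_spec(next_index(), c, cfg, rng, library, role="proximal_src")
        cp = _derived_spec(src, next_index(), c, 0.45, 0.20, rng, cfg, library,
                           role="proximal_copy")
        grid[c][s], grid[c][s + gap] = src, cp
        dup_pairs.append((src.index, cp.index, "proximal"))

    # --- one WGD block ------------------------------------------------------
    wgd_zones: list[tuple[int, int, int]] = []
    if cfg.n_wgd_block_genes >= 5:
        L = cfg.n_wgd_block_genes
        c1, s1 = pop_run(L, 0)
        c2, s2 = pop_run(L, C - 1 if C > 1 else 0)
        # other cross-chromosome plantings must stay out of the block's rank
        # neighbourhood, or the chainer would legitimately absorb them
        margin = min(27, max(3, G // 6))
        wgd_zones = [(c1, s1 - margin, s1 + L + margin),
                     (c2, s2 - margin, s2 + L + margin)]
        for k in range(L):
            src = _plain_spec(next_index(), c1, cfg, rng, library, role="wgd_src")
            cp = _derived_spec(src, next_index(), c2, 0.45, 0.20, rng, cfg,
                               library, role="wgd_copy")
            grid[c1][s1 + k], grid[c2][s2 + k] = src, cp
            dup_pairs.append((src.index, cp.index, "WGD"))


    def _in_zone(c: int, s: int) -> bool:
        return any(c == zc and lo <= s <= hi for zc, lo, hi in wgd_zones)

    def _cross_conflict(c1: int, s1: int, c2: int, s2: int) -> bool:
        return _in_zone(c1, s1) and _in_zone(c2, s2)

    # --- dispersed pairs ----------------------------------------------------
    for _ in range(cfg.n_dispersed_pairs):
        c1, s1 = pop_free()
        c2, s2 = pop_free(
            lambda c, s: (C == 1 or c != c1) and not _cross_conflict(c1, s1, c, s)
        )
        src = _plain_spec(next_index(), c1, cfg, rng, library, role="disp_src")
        cp = _derived_spec(src, next_index(), c2, 0.45, 0.20, rng, cfg, library,
                           role="disp_copy")
        grid[c1][s1], grid[c2][s2] = src, cp
        dup_pairs.append((src.index, cp.index, "dispersed"))

    # --- loss pairs (ancestral duplicate; one genome keeps both) ------------
    for genome in ("A", "B"):
        for _ in range(cfg.n_specific_loss):
            c1, s1 = pop_free()
            c2, s2 = pop_free(
                lambda c, s: (C == 1 or c != c1)
                and not _cross_conflict(c1, s1, c, s)
            )
            keeper = _ppr_spec(next_index(), c1, cfg, rng, library, "P",
                               n_motifs=int(rng.integers(4, 8)),
                               single_exon=True, role="loss_keeper")
            survivor = _derived_spec(keeper, next_index(), c2, 0.35, 0.15, rng,
                                     cfg, library, role="loss_survivor")
            survivor.present = {genome, "O"}
            grid[c1][s1], grid[c2][s2] = keeper, survivor
            loss_pairs[genome].append((survivor.index, keeper.index))

    # --- new-duplication sources (copies added per genome at realization) ---
    for genome in ("A", "B"):
        for _ in range(cfg.n_specific_new):
            c, s = pop_free()
            src = _ppr_spec(next_index(), c, cfg, rng, library, "P",
                            n_motifs=int(rng.integers(4, 9)), single_exon=True,
                            role="newdup_src")
            grid[c][s] = src
            target_chrom = (c + 1) % C if C > 1 else c
            after = int(rng.integers(0, G - 1))
            for _ in range(2000):
                if (target_chrom, after) not in forbidden and not _cross_conflict(
                    c, s, target_chrom, after
                ):
                    break
                after = int(rng.integers(0, G - 1))
            new_dups.append(
                _NewDupPlan(genome, src.index, next_index(), (target_chrom, after))
            )

    # --- planted segmental duplications -------------------------------------
    domain_cycle = 0
    for genome in ("A", "B"):
        for sd in cfg.planted_sds:
            c, s = pop_free()
            L = sd.length
            if sd.partner_class == "PPR-other":
                if sd.completeness != "incomplete":
                    raise ConfigError("PPR-other SDs must be incomplete")
                cf, sf = pop_free(
                    lambda cc, ss: not _cross_conflict(c, s, cc, ss)
                )
                focal = _ppr_spec(next_index(), cf, cfg, rng, library, "P",
                                  n_motifs=8, single_exon=True, role="sd_focal")
                grid[cf][sf] = focal
                dom_name = _FOREIGN_DOMAINS[domain_cycle % len(_FOREIGN_DOMAINS)]
                domain_cycle += 1
                donor = _plain_spec(next_index(), c, cfg, rng, library,
                                    n_aa=300, n_exons=1, role="sd_donor")
                donor.foreign_domain = (dom_name, 101, 250)
                donor.utr3 = random_dna(rng, max(150, L - 603))
                grid[c][s] = donor
                sd_plans.append(_SDPlan(sd, genome, donor.index,
                                        focal_index=focal.index, dom_off=300))
                continue
            if sd.completeness == "complete":
                if sd.partner_class == "PPR-same":
                    n_motifs = max(3, (L - 603) // 105)
                    donor = _ppr_spec(next_index(), c, cfg, rng, library, "P",
                                      n_motifs=n_motifs, single_exon=True,
                                      role="sd_donor")
                else:
                    donor = _plain_spec(next_index(), c, cfg, rng, library,
                                        n_aa=max(120, (L - 603) // 3),
                                        n_exons=1, role="sd_donor")
                donor.tail = random_dna(rng, 150)
                kept = 0
            else:
                kept = ((L - 300) // 105) * 105
                if kept < 210:
                    raise ConfigError("incomplete SD too short to keep 2 motifs")
                donor = _ppr_spec(next_index(), c, cfg, rng, library, "P",
                                  n_motifs=kept // 105 + 3, single_exon=True,
                                  role="sd_donor")
            grid[c][s] = donor
            target_chrom = (c + 1) % C if C > 1 else c
            after = int(rng.integers(0, G - 1))
            for _ in range(2000):
                if (target_chrom, after) not in forbidden and not _cross_conflict(
                    c, s, target_chrom, after
                ):
                    break
                after = int(rng.integers(0, G - 1))
            sd_plans.append(
                _SDPlan(sd, genome, donor.index, new_index=next_index(),
                        insert=(target_chrom, after), kept_cds=kept)
            )

    # --- PPR family fill ----------------------------------------------------
    subgroups, weights = zip(*cfg.subfamily_mix)
    n_placed_ppr = sum(
        1 for row in grid for g in row if g is not None and g.kind == "ppr"
    )
    for _ in range(max(0, cfg.n_ppr_genes - n_placed_ppr)):
        c, s = pop_free()
        sub = str(rng.choice(subgroups, p=np.array(weights)))
        grid[c][s] = _ppr_spec(next_index(), c, cfg, rng, library, sub)

    # --- single-motif decoy genes (discarded by the >=2 motif rule) ---------
    for _ in range(3):
        c, s = pop_free()
        spec = _plain_spec(next_index(), c, cfg, rng, library, role="pseudo1")
        spec.kind = "pseudo1"
        grid[c][s] = spec

    # --- plain filler -------------------------------------------------------
    for c in range(C):
        for s in range(G):
            if grid[c][s] is None:
                grid[c][s] = _plain_spec(next_index(), c, cfg, rng, library)

    specs = {g.index: g for row in grid for g in row}
    return _Plan(grid, specs, new_dups, sd_plans, dup_pairs, loss_pairs,
                 tandem_ppr, forbidden, library)


# ---------------------------------------------------------------------------
# Realization
# ---------------------------------------------------------------------------

@dataclass
class _Realized:
    spacer: str
    utr5: str
    utr3: str
    tail: str
    introns: list[str]
    cds: str  # includes stop


@dataclass
class _LocusInfo:
    gene_id: str
    spec_index: int | None
    gene_start: int = 0
    gene_end: int = 0
    cds_start: int = 0
    pre_start: int = 0
    post_end: int = 0
    chrom: str = ""


def _realize_parts(
    spec: GeneSpec, d_s: float, d_n: float, rng: np.random.Generator
) -> _Realized:
    if d_s <= 0 and d_n <= 0:
        return _Realized(spec.spacer_before, spec.utr5, spec.utr3, spec.tail,
                         list(spec.introns), spec.cds)
    return _Realized(
        mutate_neutral(spec.spacer_before, d_s, rng),
        mutate_neutral(spec.utr5, d_s, rng),
        mutate_neutral(spec.utr3, d_s, rng),
        mutate_neutral(spec.tail, d_s, rng),
        [mutate_neutral(iv, d_s, rng) for iv in spec.introns],
        evolve_cds(spec.cds, d_s, d_n, rng),
    )


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class _LocusBuild:
    """Everything needed to append one gene locus to a chromosome."""

    gene_id: str
    spec_index: int | None
    spacer: str
    pre: str
    utr5: str
    pieces: list[str]  # CDS pieces (last one carries the stop codon)
    introns: list[str]
    utr3: str
    post: str
    protein: str
    arch_hits: list[tuple[str, int, int]]  # (type, aa_start, aa_end)
    is_ppr: bool
    sd_copy_len: int = 0  # bp of copied sequence (SD truth), from cds/pre anchor
    sd_copy_anchor: str = ""  # "pre" (copy starts at pre) | "cds_end" (fusion)
    fusion_cds_extra: int = 0


def _arch_hit_tuples(arch: Architecture) -> list[tuple[str, int, int]]:
    out = []
    pos = 1
    for m in arch.motifs:
        length = MOTIF_LENGTHS.get(m) or CTERM_LENGTHS[m]
        out.append((m, pos, pos + length - 1))
        pos += length
    return out


def _standard_build(
    spec: GeneSpec, parts: _Realized, gene_id: str
) -> _LocusBuild:
    pieces = []
    off = 0
    for n in spec.exon_pieces:
        pieces.append(parts.cds[off : off + n])
        off += n
    arch_hits = _arch_hit_tuples(spec.architecture) if spec.architecture else []
    if spec.kind == "pseudo1":
        arch_hits = [("P", 10, 44)]
    if spec.foreign_domain is not None:
        name, a0, a1 = spec.foreign_domain
        arch_hits = arch_hits + [(name, a0, a1)]
    return _LocusBuild(
        gene_id, spec.index, parts.spacer, "", parts.utr5, pieces,
        parts.introns, parts.utr3, parts.tail, _translate(parts.cds),
        arch_hits, spec.kind == "ppr",
    )


def _assemble(
    label: str,
    plan: _Plan,
    cfg: SimulationConfig,
    builds_by_slot: dict[tuple[int, int], _LocusBuild],
    inserts: dict[tuple[int, int], list[_LocusBuild]],
) -> tuple[Genome, dict[str, _LocusInfo], list[GenomicInterval]]:
    C, G = cfg.n_chromosomes, cfg.genes_per_chromosome
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_seqs: dict[str, str] = {}
    infos: dict[str, _LocusInfo] = {}
    repeats: list[GenomicInterval] = []

    for c in range(C):
        chrom = f"chr{c + 1}"
        cursor = 0
        chunks: list[str] = []

        def place(build: _LocusBuild, repeat_span=None) -> None:
            nonlocal cursor
            chunks.append(build.spacer)
            if repeat_span is not None:
                off, length = repeat_span
                repeats.append(
                    GenomicInterval(chrom, cursor + off, cursor + off + length, "+")
                )
            cursor += len(build.spacer)
            info = _LocusInfo(build.gene_id, build.spec_index, chrom=chrom)
            info.pre_start = cursor
            chunks.append(build.pre)
            cursor += len(build.pre)
            gene_start = cursor
            # exon/CDS layout
            exons: list[GenomicInterval] = []
            cds_ivs: list[GenomicInterval] = []
            pos = gene_start
            n = len(build.pieces)
            for i, piece in enumerate(build.pieces):
                exon_start = pos
                if i == 0:
                    chunks.append(build.utr5)
                    pos += len(build.utr5)
                cds_ivs.append(GenomicInterval(chrom, pos, pos + len(piece), "+"))
                chunks.append(piece)
                pos += len(piece)
                if i == n - 1:
                    chunks.append(build.utr3)
                    pos += len(build.utr3)
                exons.append(GenomicInterval(chrom, exon_start, pos, "+"))
                if i < n - 1:
                    chunks.append(build.introns[i])
                    pos += len(build.introns[i])
            gene_end = pos
            cursor = pos
            chunks.append(build.post)
            cursor += len(build.post)
            info.gene_start = gene_start
            info.gene_end = gene_end
            info.cds_start = cds_ivs[0].start
            info.post_end = cursor
            infos[build.gene_id] = info
            model = GeneModel(
                build.gene_id,
                GenomicInterval(chrom, gene_start, gene_end, "+"),
                exons=exons, cds=cds_ivs,
            )
            genes.append(model)
            proteins[build.gene_id] = build.protein
            cds_seqs[build.gene_id] = "".join(build.pieces)

        for s in range(G):
            key = (c, s)
            if key in builds_by_slot:
                spec = plan.grid[c][s]
                build = builds_by_slot[key]
                place(build, spec.repeat_span)
            for extra in inserts.get(key, []):
                place(extra)
        sequences[chrom] = "".join(chunks)

    genome = Genome({"A": "sativa_like", "B": "rufipogon_like", "O": "outgroup"}[label],
                    sequences, genes, proteins, cds_seqs)
    genome.assign_ranks()
    genome.validate_coding()
    return genome, infos, repeats


def _realize_genome(
    label: str, plan: _Plan, cfg: SimulationConfig, seed: np.random.SeedSequence
) -> tuple[Genome, dict[str, _LocusInfo], list[GenomicInterval],
           list[DomainHit], dict[int, str]]:
    """Build one genome; returns (genome, loci, repeats, hits, addition_ids)."""
    rng = np.random.default_rng(seed)
    d_s, d_n = {
        "A": (0.0, 0.0),
        "B": (cfg.ortholog_divergence, cfg.ortholog_divergence * cfg.omega),
        "O": (cfg.outgroup_divergence, cfg.outgroup_divergence * cfg.omega),
    }[label]

    realized: dict[int, _Realized] = {}
    for idx in sorted(plan.specs):
        spec = plan.specs[idx]
        if label in spec.present:
            realized[idx] = _realize_parts(spec, d_s, d_n, rng)

    # fusion plans (PPR-other) keyed by focal spec index
    fusions: dict[int, tuple[_SDPlan, str]] = {}
    for sdp in plan.sd_plans:
        if sdp.genome == label and sdp.spec.partner_class == "PPR-other":
            donor = realized[sdp.donor_index]
            source_seq = donor.cds[sdp.dom_off :] + donor.utr3
            copy_seq = mutate_to_identity(
                source_seq, sdp.spec.identity, rng,
                coding_ranges=[(0, len(donor.cds) - sdp.dom_off)],
            )
            fusions[sdp.focal_index] = (sdp, copy_seq)

    builds_by_slot: dict[tuple[int, int], _LocusBuild] = {}
    for c in range(cfg.n_chromosomes):
        for s in range(cfg.genes_per_chromosome):
            spec = plan.grid[c][s]
            if label not in spec.present:
                continue
            gene_id = _gene_id(label, spec.index)
            parts = realized[spec.index]
            if spec.index in fusions:
                sdp, copy_seq = fusions[spec.index]
                donor_spec = plan.specs[sdp.donor_index]
                cds_nostop = parts.cds[:-3]
                copied_cds = copy_seq[: len(donor_spec.cds) - sdp.dom_off]
                utr3 = copy_seq[len(copied_cds) : len(copied_cds) + 150]
                post = copy_seq[len(copied_cds) + 150 :]
                protein = _translate(cds_nostop + copied_cds)
                arch_hits = _arch_hit_tuples(spec.architecture)
                n_motif_aa = len(cds_nostop) // 3
                dom_name = donor_spec.foreign_domain[0]
                arch_hits = arch_hits + [
                    (dom_name, n_motif_aa + 1, n_motif_aa + 150)
                ]
                builds_by_slot[(c, s)] = _LocusBuild(
                    gene_id, spec.index, parts.spacer, "", parts.utr5,
                    [cds_nostop + copied_cds], [], utr3, post, protein,
                    arch_hits, True,
                    sd_copy_len=len(copy_seq), sd_copy_anchor="cds_end",
                    fusion_cds_extra=len(copied_cds),
                )
            else:
                builds_by_slot[(c, s)] = _standard_build(
                    spec, parts, gene_id
                )

    # per-genome additions
    inserts: dict[tuple[int, int], list[_LocusBuild]] = {}
    addition_ids: dict[int, str] = {}

    def fresh_spacer() -> str:
        return random_dna(rng, int(rng.integers(800, 1600)))

    for nd in plan.new_dups:
        if nd.genome != label:
            continue
        src = realized[nd.source_index]
        src_spec = plan.specs[nd.source_index]
        new_cds = evolve_cds(src.cds, 0.01, 0.08, rng)
        gene_id = _gene_id(label, nd.new_index)
        addition_ids[nd.new_index] = gene_id
        build = _LocusBuild(
            gene_id, None, fresh_spacer(), "", random_dna(rng, 150),
            [new_cds], [], random_dna(rng, 150), "", _translate(new_cds),
            _arch_hit_tuples(src_spec.architecture), True,
        )
        inserts.setdefault(nd.insert, []).append(build)

    for sdp in plan.sd_plans:
        if sdp.genome != label or sdp.spec.partner_class == "PPR-other":
            continue
        donor = realized[sdp.donor_index]
        donor_spec = plan.specs[sdp.donor_index]
        gene_id = _gene_id(label, sdp.new_index)
        addition_ids[sdp.new_index] = gene_id
        flank = donor.spacer[-150:]
        if sdp.spec.completeness == "complete":
            source_seq = flank + donor.utr5 + donor.cds + donor.utr3 + donor.tail
            cstart = 150 + len(donor.utr5)
            copy_seq = mutate_to_identity(
                source_seq, sdp.spec.identity, rng,
                coding_ranges=[(cstart, cstart + len(donor.cds))],
            )
            pre = copy_seq[:150]
            utr5 = copy_seq[150:cstart]
            cds = copy_seq[cstart : cstart + len(donor.cds)]
            utr3 = copy_seq[cstart + len(donor.cds) : len(copy_seq) - len(donor.tail)]
            post = copy_seq[len(copy_seq) - len(donor.tail) :]
            arch = donor_spec.architecture
            build = _LocusBuild(
                gene_id, None, fresh_spacer(), pre, utr5, [cds], [], utr3,
                post, _translate(cds),
                _arch_hit_tuples(arch) if arch else [],
                donor_spec.kind == "ppr",
                sd_copy_len=len(copy_seq), sd_copy_anchor="pre",
            )
        else:  # incomplete PPR-same: 5' portion of the donor gene
            kept = sdp.kept_cds
            source_seq = flank + donor.utr5 + donor.cds[:kept]
            cstart = 150 + len(donor.utr5)
            copy_seq = mutate_to_identity(
                source_seq, sdp.spec.identity, rng,
                coding_ranges=[(cstart, cstart + kept)],
            )
            pre = copy_seq[:150]
            utr5 = copy_seq[150:cstart]
            cds = copy_seq[cstart:] + "TAA"
            utr3 = random_dna(rng, 150)
            n_kept = kept // 105
            arch = Architecture("P", "P", ["P"] * n_kept)
            build = _LocusBuild(
                gene_id, None, fresh_spacer(), pre, utr5, [cds], [], utr3,
                "", _translate(cds), _arch_hit_tuples(arch), True,
                sd_copy_len=len(copy_seq), sd_copy_anchor="pre",
            )
        inserts.setdefault(sdp.insert, []).append(build)

    genome, infos, repeats = _assemble(label, plan, cfg, builds_by_slot, inserts)

    # domain hits
    hits: list[DomainHit] = []
    all_builds = list(builds_by_slot.values()) + [
        b for lst in inserts.values() for b in lst
    ]
    for build in sorted(all_builds, key=lambda b: b.gene_id):
        for dom, a0, a1 in build.arch_hits:
            evalue = float(10.0 ** rng.uniform(-40, -2))
            hits.append(DomainHit(build.gene_id, dom, a0, a1, evalue))
    gene_ids = sorted(proteins_ids := list(genome.proteins))
    for _ in range(8):  # decoy rows above the E-value cutoff
        gid = gene_ids[rng.integers(len(gene_ids))]
        plen = max(40, len(genome.proteins[gid]) - 1)
        start = int(rng.integers(1, plen - 34))
        hits.append(
            DomainHit(gid, "P", start, start + 34, float(rng.uniform(10, 200)))
        )
    hits.sort(key=lambda h: (h.protein_id, h.aa_start, h.evalue))
    return genome, infos, repeats, hits, addition_ids


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def simulate_counts(
    gene_ids: Sequence[str],
    planted_pairs: Sequence[tuple[str, str, str]],
    params: ExpressionParams,
    rng: np.random.Generator,
    base_means: Mapping[str, float] | None = None,
) -> tuple[CountMatrix, list[tuple[str, str, str, str | None]]]:
    """Negative-binomial counts with planted sister-pair asymmetries.

    ``planted_pairs`` are (copy1, copy2, class) with class in
    {AED, sub_neo, no_difference}; AED pairs get a ``planted_fold`` mean
    excess for copy1 in two tissues (equal means elsewhere), sub_neo pairs
    get opposite excesses in two different tissues. Returns the counts and
    the realized truth records (copy1, copy2, class, higher_copy).
    """
    tissues = list(params.tissues)
    n_t = len(tissues)
    means = {}
    for g in gene_ids:
        if base_means is not None:
            base = float(base_means.get(g, 0.0))
        else:
            base = float(rng.lognormal(params.base_log_mean, params.base_log_sigma))
        means[g] = np.full(n_t, base)
    truth: list[tuple[str, str, str, str | None]] = []
    for g1, g2, cls in planted_pairs:
        base = float(rng.lognormal(params.base_log_mean, params.base_log_sigma))
        m1 = np.full(n_t, base)
        m2 = np.full(n_t, base)
        if cls == "AED":
            up = rng.choice(n_t, size=2, replace=False)
            m1[up] *= params.planted_fold
            truth.append((g1, g2, "AED", g1))
        elif cls == "sub_neo":
            t1, t2 = rng.choice(n_t, size=2, replace=False)
            m1[t1] *= params.planted_fold
            m2[t2] *= params.planted_fold
            truth.append((g1, g2, "sub_neo", None))
        else:
            truth.append((g1, g2, "no_difference", None))
        means[g1] = m1
        means[g2] = m2
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(params.replicates)]
    mean_mat = np.zeros((len(gene_ids), len(samples)))
    for i, g in enumerate(gene_ids):
        for ti in range(n_t):
            for r in range(params.replicates):
                mean_mat[i, ti * params.replicates + r] = means[g][ti]
    r_param = 1.0 / params.dispersion
    with np.errstate(divide="ignore"):
        p = r_param / (r_param + mean_mat)
    counts = np.where(
        mean_mat > 0, rng.negative_binomial(r_param, np.where(p > 0, p, 1.0)), 0
    )
    df = pd.DataFrame(counts, index=list(gene_ids), columns=samples)
    meta = pd.DataFrame(
        [(s, s.rsplit("_", 1)[0], int(s.rsplit("_", 1)[1])) for s in samples],
        columns=["sample", "tissue", "replicate"],
    ).set_index("sample")
    return CountMatrix(df, meta), truth


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Generate the full paired dataset (genomes A and B plus outgroup)."""
    ss = np.random.SeedSequence(config.seed)
    s_plan, s_a, s_b, s_o, s_ca, s_cb = ss.spawn(6)
    plan = _plan(config, np.random.default_rng(s_plan))

    genomes: dict[str, Genome] = {}
    infos: dict[str, dict[str, _LocusInfo]] = {}
    repeats: dict[str, list[GenomicInterval]] = {}
    hits: dict[str, list[DomainHit]] = {}
    added: dict[str, dict[int, str]] = {}
    for label, seed in (("A", s_a), ("B", s_b), ("O", s_o)):
        g, inf, rep, h, add = _realize_genome(label, plan, config, seed)
        genomes[label] = g
        infos[label] = inf
        repeats[label] = rep
        hits[label] = h
        added[label] = add

    truth = TruthTables()
    # orthologs and outgroup maps
    for idx in sorted(plan.specs):
        spec = plan.specs[idx]
        if {"A", "B"} <= spec.present:
            truth.ortholog_pairs.append((_gene_id("A", idx), _gene_id("B", idx)))
    for label in ("A", "B"):
        truth.outgroup_map[label] = {
            _gene_id(label, idx): _gene_id("O", idx)
            for idx, spec in sorted(plan.specs.items())
            if label in spec.present and "O" in spec.present
        }

    # family membership with planted labels
    for label in ("A", "B", "O"):
        fam: dict[str, tuple[str, str, int]] = {}
        for idx, spec in sorted(plan.specs.items()):
            if label in spec.present and spec.kind == "ppr":
                a = spec.architecture
                fam[_gene_id(label, idx)] = (a.subfamily, a.subgroup, a.n_ppr_motifs)
        if label in ("A", "B"):
            for nd in plan.new_dups:
                if nd.genome == label:
                    a = plan.specs[nd.source_index].architecture
                    fam[added[label][nd.new_index]] = (
                        a.subfamily, a.subgroup, a.n_ppr_motifs
                    )
            for sdp in plan.sd_plans:
                if sdp.genome != label or sdp.spec.partner_class != "PPR-same":
                    continue
                if sdp.spec.completeness == "complete":
                    a = plan.specs[sdp.donor_index].architecture
                    fam[added[label][sdp.new_index]] = (
                        a.subfamily, a.subgroup, a.n_ppr_motifs
                    )
                else:
                    n_kept = sdp.kept_cds // 105
                    fam[added[label][sdp.new_index]] = ("P", "P", n_kept)
        truth.ppr_genes[label] = fam

    # species-specific genes and origins
    for label in ("A", "B"):
        specific: set[str] = set()
        origins: dict[str, str] = {}
        for survivor_idx, _keeper_idx in plan.loss_pairs[label]:
            gid = _gene_id(label, survivor_idx)
            specific.add(gid)
            origins[gid] = "loss"
        for nd in plan.new_dups:
            if nd.genome == label:
                gid = added[label][nd.new_index]
                specific.add(gid)
                origins[gid] = "new"
        for sdp in plan.sd_plans:
            if sdp.genome == label and sdp.spec.partner_class == "PPR-same":
                specific.add(added[label][sdp.new_index])
        truth.specific_genes[label] = specific
        truth.origin_labels[label] = origins

    # duplication pairs
    for label in ("A", "B"):
        pairs: list[tuple[str, str, str]] = []
        for i, j, t in plan.dup_pairs:
            pairs.append((_gene_id(label, i), _gene_id(label, j), t))
        for surv, keeper in plan.loss_pairs[label]:
            pairs.append((_gene_id(label, surv), _gene_id(label, keeper), "dispersed"))
        for nd in plan.new_dups:
            if nd.genome == label:
                pairs.append(
                    (added[label][nd.new_index], _gene_id(label, nd.source_index),
                     "dispersed")
                )
        for sdp in plan.sd_plans:
            if sdp.genome == label and sdp.spec.partner_class == "PPR-same":
                pairs.append(
                    (added[label][sdp.new_index], _gene_id(label, sdp.donor_index),
                     "dispersed")
                )
        truth.dup_pairs[label] = pairs

    # planted SDs and acquisitions
    for label in ("A", "B"):
        sd_truths: list[SDTruth] = []
        acq: list[tuple[str, str, str, str]] = []
        for sdp in plan.sd_plans:
            if sdp.genome != label:
                continue
            donor_id = _gene_id(label, sdp.donor_index)
            dinfo = infos[label][donor_id]
            if sdp.spec.partner_class == "PPR-other":
                focal_id = _gene_id(label, sdp.focal_index)
                finfo = infos[label][focal_id]
                focal_spec = plan.specs[sdp.focal_index]
                source = GenomicInterval(
                    dinfo.chrom, dinfo.cds_start + sdp.dom_off, dinfo.gene_end, "+"
                )
                copy_start = finfo.cds_start + len(focal_spec.cds) - 3
                copy = GenomicInterval(
                    finfo.chrom, copy_start, copy_start + len(source), "+"
                )
                sd_truths.append(
                    SDTruth(source, copy, sdp.spec.identity, "incomplete",
                            "PPR-other", focal_id, donor_id)
                )
                dom_name = plan.specs[sdp.donor_index].foreign_domain[0]
                acq.append((focal_id, donor_id, dom_name, "accepter"))
                continue
            copy_id = added[label][sdp.new_index]
            cinfo = infos[label][copy_id]
            if sdp.spec.completeness == "complete":
                source = GenomicInterval(
                    dinfo.chrom, dinfo.gene_start - 150, dinfo.post_end, "+"
                )
            else:
                source = GenomicInterval(
                    dinfo.chrom, dinfo.gene_start - 150,
                    dinfo.cds_start + sdp.kept_cds, "+"
                )
            copy = GenomicInterval(
                cinfo.chrom, cinfo.pre_start, cinfo.pre_start + len(source), "+"
            )
            focal = copy_id if sdp.spec.partner_class == "PPR-same" else None
            partner = donor_id if sdp.spec.partner_class == "PPR-same" else None
            sd_truths.append(
                SDTruth(source, copy, sdp.spec.identity, sdp.spec.completeness,
                        sdp.spec.partner_class, focal, partner)
            )
        truth.sds[label] = sd_truths
        truth.acquisitions[label] = acq

    # expression: planted sister-pair classes over PPR-PPR duplicate pairs
    counts: dict[str, CountMatrix] = {}
    cls_cycle = ("AED", "no_difference", "sub_neo")
    for label, seed in (("A", s_ca), ("B", s_cb)):
        sister: list[tuple[str, str, str]] = []
        k = 0
        for sdp in plan.sd_plans:
            if sdp.genome == label and sdp.spec.partner_class == "PPR-same":
                sister.append(
                    (added[label][sdp.new_index], _gene_id(label, sdp.donor_index),
                     cls_cycle[k % 3])
                )
                k += 1
        for i, j in plan.tandem_ppr:
            sister.append((_gene_id(label, i), _gene_id(label, j), cls_cycle[k % 3]))
            k += 1
        cm, expr_truth = simulate_counts(
            sorted(genomes[label].proteins), sister, config.expression,
            np.random.default_rng(seed),
        )
        counts[label] = cm
        truth.expression_classes[label] = expr_truth

    return SimulatedDataset(
        config, genomes["A"], genomes["B"], genomes["O"], hits, repeats,
        counts, truth,
    )


# ---------------------------------------------------------------------------
# On-disk fixture sets
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write the full fixture set (FASTA/GFF3/TSV/BED) for downstream runs."""
    import os

    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for label in ("A", "B", "O"):
        genome = ds.genome(label)
        paths.update(
            {f"{label}_{k}": v
             for k, v in pio.write_genome(genome, outdir).items()}
        )
        hp = os.path.join(outdir, f"{genome.name}.domains.tsv")
        pio.write_domain_hits(ds.domain_hits[label], hp)
        paths[f"{label}_domains"] = hp
        bp = os.path.join(outdir, f"{genome.name}.repeats.bed")
        pio.write_bed(ds.repeats[label], bp)
        paths[f"{label}_repeats"] = bp
    from .expression import write_counts_tsv

    for label in ("A", "B"):
        cp = os.path.join(outdir, f"{ds.genome(label).name}.counts.tsv")
        write_counts_tsv(ds.counts[label], cp)
        paths[f"{label}_counts"] = cp
    tp = os.path.join(outdir, "truth_orthologs.tsv")
    pd.DataFrame(ds.truth.ortholog_pairs, columns=["gene_a", "gene_b"]).to_csv(
        tp, sep="\t", index=False
    )
    paths["truth_orthologs"] = tp
    return paths
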