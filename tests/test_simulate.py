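"""Generator contracts: determinism, identity arithmetic, truth bookkeeping."""

import edlib
import numpy as np
import pytest

from pprdup.simulate import (
    ConfigError, PlantedSDSpec, SimulationConfig, evolve_cds,
    mutate_to_identity, random_dna, simulate,
)

SMALL = dict(
    n_chromosomes=2, genes_per_chromosome=40, n_ppr_genes=14, n_tandem=2,
    n_proximal=2, n_wgd_block_genes=5, n_dispersed_pairs=2, n_specific_new=2,
    n_specific_loss=1, mean_intergenic=2000,
)


class TestMutateToIdentity:
    def test_target_hundred_unchanged(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 500)
        assert mutate_to_identity(seq, 100.0, rng) == seq

    def test_exact_substitution_count(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 1000)
        out = mutate_to_identity(seq, 90.0, rng)
        diffs = sum(a != b for a, b in zip(seq, out))
        assert diffs == 100
        assert len(out) == 1000

    def test_realigned_identity_matches_target(self):
        # independent oracle: global alignment of original vs mutated copy
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 2000)
        out = mutate_to_identity(seq, 94.0, rng)
        res = edlib.align(seq, out, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, seq, out)
        identity = 100.0 * nice["matched_aligned"].count("|") / len(
            nice["matched_aligned"]
        )
        assert abs(identity - 94.0) <= 0.5

    def test_coding_ranges_never_create_stops(self):
        rng = np.random.default_rng(3)
        from pprdup.simulate import backtranslate, random_protein
        from Bio.Seq import Seq

        prot = random_protein(rng, 200)
        cds = backtranslate(prot, rng)
        for _ in range(10):
            out = mutate_to_identity(cds, 90.0, rng, coding_ranges=[(0, len(cds))])
            translated = str(Seq(out).translate())
            assert translated.count("*") == 1 and translated.endswith("*")

    def test_indel_mode_changes_length(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 2000)
        out = mutate_to_identity(seq, 95.0, rng, indel_rate=0.005)
        assert len(out) != len(seq)


class TestEvolveCds:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(5)
        from pprdup.simulate import backtranslate, random_protein

        cds = backtranslate(random_protein(rng, 100), rng)
        assert evolve_cds(cds, 0.0, 0.0, rng) == cds

    def test_nonsynonymous_rate_controls_protein_change(self):
        rng = np.random.default_rng(6)
        from pprdup.simulate import backtranslate, random_protein
        from Bio.Seq import Seq

        prot = random_protein(rng, 500)
        cds = backtranslate(prot, rng)
        syn_only = evolve_cds(cds, 0.2, 0.0, rng)
        assert str(Seq(syn_only).translate())[:-1] == prot
        assert syn_only != cds


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        a = simulate(SimulationConfig(seed=7, **SMALL))
        b = simulate(SimulationConfig(seed=7, **SMALL))
        assert a.genome_a.sequences == b.genome_a.sequences
        assert a.genome_b.sequences == b.genome_b.sequences
        assert a.counts["A"].counts.equals(b.counts["A"].counts)
        assert a.truth.ortholog_pairs == b.truth.ortholog_pairs

    def test_different_seed_different_sequences(self):
        a = simulate(SimulationConfig(seed=7, **SMALL))
        b = simulate(SimulationConfig(seed=8, **SMALL))
        assert a.genome_a.sequences["chr1"] != b.genome_a.sequences["chr1"]


class TestBookkeeping:
    def test_truth_references_existing_objects(self, small_dataset):
        ds = small_dataset
        for a, b in ds.truth.ortholog_pairs:
            assert a in ds.genome_a and b in ds.genome_b
        for lab in ("A", "B"):
            genome = ds.genome(lab)
            for gid in ds.truth.ppr_genes[lab]:
                assert gid in genome
            for t in ds.truth.sds[lab]:
                for iv in (t.source, t.copy):
                    assert iv.end <= genome.chromosome_length(iv.chromosome)
            for g1, g2, _ in ds.truth.dup_pairs[lab]:
                assert g1 in genome and g2 in genome

    def test_planted_sd_count_matches_config(self, small_dataset):
        for lab in ("A", "B"):
            assert len(small_dataset.truth.sds[lab]) == len(
                small_dataset.config.planted_sds
            )

    def test_planted_sd_realized_identity(self, small_dataset):
        ds = small_dataset
        for t in ds.truth.sds["A"]:
            genome = ds.genome_a
            sa = genome.sequences[t.source.chromosome][t.source.start:t.source.end]
            sb = genome.sequences[t.copy.chromosome][t.copy.start:t.copy.end]
            res = edlib.align(sa, sb, mode="NW", task="path")
            nice = edlib.getNiceAlignment(res, sa, sb)
            identity = 100.0 * nice["matched_aligned"].count("|") / len(
                nice["matched_aligned"]
            )
            assert abs(identity - t.identity) <= 1.0

    def test_outgroup_lacks_acquired_domains(self, small_dataset):
        ds = small_dataset
        for lab in ("A", "B"):
            for focal, _, dom, _ in ds.truth.acquisitions[lab]:
                og = ds.truth.outgroup_map[lab][focal]
                og_types = {h.domain_type for h in ds.domain_hits["O"]
                            if h.protein_id == og}
                assert dom not in og_types


class TestConfigValidation:
    def test_bad_identity_rejected(self):
        with pytest.raises(ConfigError):
            PlantedSDSpec(2000, 80.0, "complete", "PPR-same")

    def test_bad_mix_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(subfamily_mix=(("P", 0.5), ("DYW", 0.2)))

    def test_oversized_sd_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                genes_per_chromosome=10, mean_intergenic=1000,
                planted_sds=(PlantedSDSpec(500_000, 95.0, "complete", "PPR-same"),),
            )


class TestDatasetOutput:
    def test_written_fixture_set_reloads(self, tmp_path, small_dataset):
        from pprdup.simulate import write_dataset
        from pprdup import io as pio

        paths = write_dataset(small_dataset, tmp_path)
        genome = pio.load_genome(
            "sativa_like", paths["A_fasta"], paths["A_gff3"],
            paths["A_proteins"], paths["A_cds"],
        )
        assert len(genome.genes) == len(small_dataset.genome_a.genes)
        hits = pio.read_domain_hits(paths["A_domains"])
        # decoy rows above the cutoff are dropped on reading
        assert len(hits) < len(small_dataset.domain_hits["A"])
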