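"""Shared fixtures: one default synthetic genome pair reused across tests.

The default dataset and the heavier pipeline stages run once per session;
truth-recovery tests and the acceptance suite read from these fixtures.
"""

from __future__ import annotations

import pytest

from pprdup import pipeline
from pprdup.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    return simulate(default_config)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(
        n_chromosomes=2, genes_per_chromosome=40, n_ppr_genes=14,
        n_tandem=2, n_proximal=2, n_wgd_block_genes=5, n_dispersed_pairs=2,
        n_specific_new=2, n_specific_loss=1, mean_intergenic=2000, seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def classifications(dataset):
    return {
        lab: pipeline.classify_family(dataset.genome(lab), dataset.domain_hits[lab])
        for lab in ("A", "B")
    }


@pytest.fixture(scope="session")
def orthology(dataset, classifications):
    return pipeline.run_orthology(
        dataset.genome_a, dataset.genome_b,
        sorted(classifications["A"]), sorted(classifications["B"]),
    )


@pytest.fixture(scope="session")
def paralog_hit_sets(dataset):
    return {lab: pipeline.paralog_hits(dataset.genome(lab)) for lab in ("A", "B")}


@pytest.fixture(scope="session")
def sd_results(dataset, classifications):
    return {
        lab: pipeline.run_sd_analysis(
            dataset.genome(lab), dataset.repeats[lab], classifications[lab]
        )
        for lab in ("A", "B")
    }
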