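"""SD-gene intersection: completeness, pair typing, domain acquisition."""

import numpy as np
import pytest

from pprdup.core import GeneModel, GenomicInterval
from pprdup.family import PPRClassification
from pprdup.sdgenes import (
    classify_completeness, detect_domain_acquisition, protein_similarity,
    type_pair,
)
from pprdup.simulate import random_protein


def _gene(gene_id, start, end, chrom="chr1"):
    iv = GenomicInterval(chrom, start, end, "+")
    return GeneModel(gene_id, iv, exons=[iv], cds=[iv])


class TestCompleteness:
    def test_contained_gene_is_complete(self):
        sd = GenomicInterval("chr1", 1000, 8000)
        assert classify_completeness(sd, _gene("g", 2000, 5000)) == "complete"

    def test_boundary_inside_gene_is_incomplete(self):
        sd = GenomicInterval("chr1", 1000, 8000)
        assert classify_completeness(sd, _gene("g", 6000, 9500)) == "incomplete"

    def test_exact_span_is_complete(self):
        sd = GenomicInterval("chr1", 2000, 5000)
        assert classify_completeness(sd, _gene("g", 2000, 5000)) == "complete"


class TestTypePair:
    CLS = {
        "f_p": PPRClassification("f_p", "P", "P", 5),
        "p_p": PPRClassification("p_p", "P", "P", 7),
        "f_dyw": PPRClassification("f_dyw", "PLS", "DYW", 9),
        "p_e2": PPRClassification("p_e2", "PLS", "E2", 8),
    }

    def test_same_subgroup(self):
        assert type_pair("f_p", "p_p", self.CLS) == ("PPR-same-subgroup", "P-P")

    def test_cross_subgroup(self):
        assert type_pair("f_dyw", "p_e2", self.CLS) == (
            "PPR-cross-subgroup", "DYW-E2"
        )

    def test_non_ppr_partner(self):
        assert type_pair("f_p", "kinase1", self.CLS) == ("PPR-Other", "P-Other")

    def test_missing_partner(self):
        assert type_pair("f_p", None, self.CLS)[0] == "no-partner"


class TestProteinSimilarity:
    def test_identical_is_hundred(self):
        rng = np.random.default_rng(0)
        p = random_protein(rng, 200)
        assert protein_similarity(p, p) == 100.0

    def test_n_terminal_half_tracks_length_ratio(self):
        rng = np.random.default_rng(1)
        p = random_protein(rng, 300)
        half = p[:150]
        sim = protein_similarity(p, half)
        assert abs(sim - 50.0) <= 5.0

    def test_average_matches_brute_force(self, sd_results, dataset):
        pairs = [p for p in sd_results["A"].gene_pairs
                 if p.protein_similarity is not None]
        recomputed = [
            protein_similarity(
                dataset.genome_a.proteins[p.focal_gene],
                dataset.genome_a.proteins[p.partner_gene],
            )
            for p in pairs
        ]
        mean_pipeline = np.mean([p.protein_similarity for p in pairs])
        assert mean_pipeline == pytest.approx(np.mean(recomputed), abs=1e-9)


class TestTruthRecovery:
    def test_sd_derived_genes_and_completeness(self, dataset, sd_results):
        for lab in ("A", "B"):
            truth_focal = {}
            for t in dataset.truth.sds[lab]:
                if t.focal_gene:
                    truth_focal[t.focal_gene] = (t.completeness, t.partner_gene)
                if t.partner_gene and t.partner_class == "PPR-same":
                    # the donor gene is SD-derived as well
                    truth_focal.setdefault(t.partner_gene, (None, t.focal_gene))
            found = {p.focal_gene: p for p in sd_results[lab].gene_pairs}
            assert set(found) == set(truth_focal)
            for gid, (completeness, partner) in truth_focal.items():
                assert found[gid].partner_gene == partner
                if completeness is not None:
                    assert found[gid].completeness == completeness

    def test_pair_categories_match_planted_classes(self, dataset, sd_results):
        want = {"PPR-same": "PPR-same-subgroup", "PPR-other": "PPR-Other"}
        for lab in ("A", "B"):
            found = {p.focal_gene: p for p in sd_results[lab].gene_pairs}
            for t in dataset.truth.sds[lab]:
                if t.focal_gene:
                    assert found[t.focal_gene].pair_category == want[t.partner_class]

    def test_acquisition_direction_recovered(self, dataset, sd_results):
        for lab in ("A", "B"):
            calls = []
            for p in sd_results[lab].gene_pairs:
                if p.pair_category == "PPR-Other" and p.completeness == "incomplete":
                    call = detect_domain_acquisition(
                        p, dataset.genome(lab), dataset.domain_hits[lab],
                        dataset.domain_hits["O"], dataset.truth.outgroup_map[lab],
                    )
                    if call is not None:
                        calls.append(
                            (call.focal_gene, call.partner_gene,
                             call.domain_type, call.direction)
                        )
            assert sorted(calls) == sorted(dataset.truth.acquisitions[lab])

    def test_outgroup_present_domain_gives_ambiguous(self, dataset, sd_results):
        # grafting the domain onto the outgroup ortholog removes the signal
        from pprdup.core import DomainHit

        lab = "A"
        pair = next(
            p for p in sd_results[lab].gene_pairs
            if p.pair_category == "PPR-Other" and p.completeness == "incomplete"
        )
        og = dataset.truth.outgroup_map[lab][pair.focal_gene]
        call = detect_domain_acquisition(
            pair, dataset.genome(lab), dataset.domain_hits[lab],
            list(dataset.domain_hits["O"])
            + [DomainHit(og, "S_TKc", 1, 150, 1e-20)],
            dataset.truth.outgroup_map[lab],
        )
        assert call.direction == "ambiguous"

    def test_missing_outgroup_ortholog_is_ambiguous(self, dataset, sd_results):
        lab = "A"
        pair = next(
            p for p in sd_results[lab].gene_pairs
            if p.pair_category == "PPR-Other" and p.completeness == "incomplete"
        )
        call = detect_domain_acquisition(
            pair, dataset.genome(lab), dataset.domain_hits[lab],
            dataset.domain_hits["O"], {},
        )
        assert call.direction == "ambiguous"

    def test_complete_incomplete_partition(self, sd_results):
        for lab in ("A", "B"):
            with_partner = [p for p in sd_results[lab].gene_pairs
                            if p.partner_gene is not None]
            n_c = sum(p.completeness == "complete" for p in with_partner)
            n_i = sum(p.completeness == "incomplete" for p in with_partner)
            assert n_c + n_i == len(with_partner)
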