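"""Four-criterion candidate filter, atranorin rule, divergent FAS detector."""

import pytest

from conftest import all_shared_comparison, build_catalog_clusters

from chemotri.filters import (AmbiguousClusterError, ClassifiedCluster,
                              detect_atranorin_cluster, evaluate_candidates,
                              find_divergent_pair, locate_pair)
from chemotri.homology import ChemotypeComparison
from chemotri.simulate import FixtureConfig, generate_fixture


class TestEvaluateCandidates:
    def test_published_catalog_single_pass(self):
        classified = build_catalog_clusters()
        verdicts = evaluate_candidates(classified,
                                       all_shared_comparison(classified))
        passed = [v for v in verdicts if v.passed]
        assert [v.cluster_id for v in passed] == ["c04"]
        arch = next(cc.architecture for cc in classified
                    if cc.cluster.cluster_id == "c04")
        assert arch.acp_count == 2 and arch.has_TE

    def test_azaphilone_type_cluster_fails_with_cmt_evidence(self):
        classified = build_catalog_clusters()
        verdicts = {v.cluster_id: v for v in evaluate_candidates(
            classified, all_shared_comparison(classified))}
        v1 = verdicts["c01"]
        assert not v1.passed
        assert not v1.criteria["has_CytP450"]
        assert {"has_cMT"} <= set(v1.negative_evidence)
        # divergently transcribed R-PKS neighbour recorded for cluster 5
        assert "divergent_R_PKS_neighbor" in verdicts["c05"].negative_evidence
        # OMT-bearing melanin-group clusters fail on CytP450 only
        for cid in ("c07", "c08"):
            v = verdicts[cid]
            assert [k for k, ok in v.criteria.items() if not ok] == \
                ["has_CytP450"]
            assert "has_OMT_in_cluster" in v.negative_evidence

    def test_removing_cytp450_toggles_single_criterion(self):
        classified = build_catalog_clusters(drop_labels={4: "CytP450"})
        verdicts = {v.cluster_id: v for v in evaluate_candidates(
            classified, all_shared_comparison(classified))}
        v = verdicts["c04"]
        assert not v.passed
        assert [k for k, ok in v.criteria.items() if not ok] == \
            ["has_CytP450"]

    def test_unshared_cluster_fails_presence_criterion(self):
        classified = build_catalog_clusters()
        comparison = ChemotypeComparison([], [], [], [], [])
        verdicts = evaluate_candidates(classified, comparison)
        assert all(not v.criteria["in_both_chemotypes"] for v in verdicts)
        assert not any(v.passed for v in verdicts)

    def test_verdicts_invariant_under_input_order(self):
        classified = build_catalog_clusters()
        comparison = all_shared_comparison(classified)
        forward = evaluate_candidates(classified, comparison)
        backward = evaluate_candidates(list(reversed(classified)), comparison)
        assert {v.cluster_id: (v.passed, v.negative_evidence)
                for v in forward} == \
            {v.cluster_id: (v.passed, v.negative_evidence) for v in backward}

    def test_pks_free_cluster_skipped(self):
        classified = build_catalog_clusters()
        stub = ClassifiedCluster(classified[0].cluster, None, None)
        verdicts = evaluate_candidates([stub],
                                       all_shared_comparison(classified))
        assert verdicts == []


class TestAtranorinRule:
    def test_detected_on_published_catalog(self):
        classified = build_catalog_clusters()
        assert detect_atranorin_cluster(classified) == "c06"

    def test_absent_without_omt(self):
        classified = build_catalog_clusters(
            drop_labels={6: "O-methyltransferase"})
        assert detect_atranorin_cluster(classified) is None

    def test_two_matches_raise_ambiguity_error(self):
        classified = build_catalog_clusters()
        six = next(cc for cc in classified
                   if cc.cluster.cluster_id == "c06")
        import dataclasses
        twin_cluster = dataclasses.replace(six.cluster, cluster_id="c99")
        twin = ClassifiedCluster(twin_cluster, six.architecture,
                                 six.classification)
        with pytest.raises(AmbiguousClusterError):
            detect_atranorin_cluster(classified + [twin])


class TestDivergentPair:
    def test_mirror_fixture_pair_found_with_published_lengths(
            self, mirror_fixture):
        for chem in ("physodic", "olivetoric"):
            genome = mirror_fixture.genome(chem)
            locus = find_divergent_pair(genome, mirror_fixture.hexa_query,
                                        mirror_fixture.hexb_query)
            assert locus is not None
            assert locus.orientation == "divergent"
            assert genome.gene(locus.gene_a_id).length_bp == 5619
            assert genome.gene(locus.gene_b_id).length_bp == 6285

    def test_tandem_variant_reports_orientation_but_no_locus(self):
        fx = generate_fixture(FixtureConfig(seed=19, n_shared_clusters=2,
                                            background_contig_bp=6000,
                                            fas_orientation="tandem"))
        genome = fx.genome_physodic
        loc = locate_pair(genome, fx.hexa_query, fx.hexb_query)
        assert loc.orientation == "tandem"
        assert find_divergent_pair(genome, fx.hexa_query,
                                   fx.hexb_query) is None

    def test_hits_on_different_contigs_yield_none(self, small_fixture):
        genome = small_fixture.genome_physodic
        cluster_core = genome.gene_sequence(genome.clusters[0].core_genes[0])
        assert find_divergent_pair(genome, small_fixture.hexa_query,
                                   cluster_core) is None

    def test_query_without_hit_yields_none(self, small_fixture):
        import numpy as np
        rng = np.random.default_rng(0)
        random_query = "".join(rng.choice(list("ACGT"), 2000))
        assert find_divergent_pair(small_fixture.genome_physodic,
                                   random_query,
                                   small_fixture.hexb_query) is None
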