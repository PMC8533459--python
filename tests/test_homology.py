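"""Alignment scoring, RBH matching, partition and synteny tables."""

import dataclasses

import numpy as np
import pytest

from oracles import brute_mutual_best, gotoh_score

from chemotri.homology import (CoreGene, core_genes_of, partition_chemotypes,
                               reciprocal_best_hit, score_pair,
                               synteny_table)
from chemotri.model import ChemotriError
from chemotri.simulate import FixtureConfig, generate_fixture, simulate_reads


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestScorePair:
    def test_identical_sequences(self):
        seq = "ACGT" * 75
        sim = score_pair(seq, seq)
        assert sim.identity == 1.0
        assert sim.score == 300
        assert sim.aligned_length == 300

    def test_three_substitutions_in_hundred(self):
        rng = np.random.default_rng(0)
        a = _random_seq(rng, 100)
        b = list(a)
        for i in (10, 50, 90):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        sim = score_pair(a, "".join(b))
        assert sim.identity == pytest.approx(0.97)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ChemotriError):
            score_pair("", "ACGT")

    def test_matches_dynamic_programming_oracle(self):
        """Aligner score equals an independent Gotoh DP on random <=60-mers."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = _random_seq(rng, int(rng.integers(5, 61)))
            b = _random_seq(rng, int(rng.integers(5, 61)))
            assert score_pair(a, b).score == gotoh_score(a, b)
            assert score_pair(a, b).score == score_pair(b, a).score


class TestReciprocalBestHit:
    def test_identical_singletons_pair_up(self):
        core = CoreGene("cA", "gA", "ACGT" * 100)
        other = CoreGene("cB", "gB", "ACGT" * 100)
        matches = reciprocal_best_hit([core], [other])
        assert len(matches) == 1
        assert (matches[0].cluster_a, matches[0].cluster_b) == ("cA", "cB")
        assert matches[0].reciprocal

    def test_equals_exhaustive_enumeration_with_decoy(self):
        """3x3 sets with a planted paralog decoy: pairs equal the brute-force
        mutual-best enumeration over all 9 alignment scores."""
        rng = np.random.default_rng(1)
        base = [_random_seq(rng, 300) for _ in range(3)]

        def mutate(seq, rate):
            out = list(seq)
            for i in np.flatnonzero(rng.random(len(seq)) < rate):
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        # a2 is a decoy paralog of a0; true partner of b0 is a0
        cores_a = [CoreGene(f"ca{i}", f"ga{i}", s) for i, s in enumerate(
            [base[0], base[1], mutate(base[0], 0.15)])]
        cores_b = [CoreGene(f"cb{i}", f"gb{i}", s) for i, s in enumerate(
            [mutate(base[0], 0.03), mutate(base[1], 0.03), base[2]])]
        scores = {(a.gene_id, b.gene_id): score_pair(a.sequence,
                                                     b.sequence).score
                  for a in cores_a for b in cores_b}
        expected = brute_mutual_best(scores,
                                     [a.gene_id for a in cores_a],
                                     [b.gene_id for b in cores_b])
        got = reciprocal_best_hit(cores_a, cores_b, min_identity=0.0,
                                  seed_max_distance=None)
        got_genes = {(m.core_similarity.query_id,
                      m.core_similarity.subject_id) for m in got}
        assert got_genes == expected
        assert ("ga2", "gb0") not in got_genes  # decoy defeated

    def test_swap_invariance_on_fixture(self, small_fixture):
        ca = core_genes_of(small_fixture.genome_physodic)
        cb = core_genes_of(small_fixture.genome_olivetoric)
        forward = {(m.cluster_a, m.cluster_b)
                   for m in reciprocal_best_hit(ca, cb)}
        backward = {(m.cluster_b, m.cluster_a)
                    for m in reciprocal_best_hit(cb, ca)}
        assert forward == backward

    def test_empty_side_returns_empty(self):
        assert reciprocal_best_hit([], [CoreGene("c", "g", "ACGT")]) == []


class TestPartition:
    def test_all_specific_without_matches(self, small_fixture):
        comp = partition_chemotypes(small_fixture.genome_physodic,
                                    small_fixture.genome_olivetoric, [])
        assert len(comp.specific_a) == \
            len(small_fixture.genome_physodic.clusters)
        assert len(comp.specific_b) == \
            len(small_fixture.genome_olivetoric.clusters)

    def test_partition_covers_every_cluster(self, small_fixture):
        ca = core_genes_of(small_fixture.genome_physodic)
        cb = core_genes_of(small_fixture.genome_olivetoric)
        matches = reciprocal_best_hit(ca, cb)
        comp = partition_chemotypes(small_fixture.genome_physodic,
                                    small_fixture.genome_olivetoric, matches)
        n_a = (len(comp.shared_pairs) + len(comp.specific_a)
               + len(comp.ambiguous_a))
        n_b = (len(comp.shared_pairs) + len(comp.specific_b)
               + len(comp.ambiguous_b))
        assert n_a == len(small_fixture.genome_physodic.clusters)
        assert n_b == len(small_fixture.genome_olivetoric.clusters)

    def test_planted_cross_reads_flag_cluster_ambiguous(self, small_fixture):
        """A 'specific' cluster with read support in the other chemotype must
        be reported ambiguous, not specific."""
        ga = small_fixture.genome_physodic
        gb = small_fixture.genome_olivetoric
        matches = reciprocal_best_hit(core_genes_of(ga), core_genes_of(gb))
        specific_id = small_fixture.manifest["specific"]["physodic"][0]
        core = ga.cluster(specific_id).core_genes[0]
        seq = ga.gene_sequence(core)
        cross = [(f"x{i}", seq[i * 10:i * 10 + 150]) for i in range(5)]
        comp = partition_chemotypes(ga, gb, matches,
                                    reads_a=[("pad", "A" * 150)],
                                    reads_b=cross)
        assert specific_id in {c for c, _ in comp.ambiguous_a}
        assert specific_id not in {c for c, _ in comp.specific_a}


class TestSynteny:
    def test_cluster_against_itself(self, small_fixture):
        cluster = small_fixture.genome_physodic.clusters[0]
        df = synteny_table(cluster, cluster)
        diagonal = df[df["gene_a"] == df["gene_b"]]
        assert len(diagonal) == len(cluster.genes)
        assert (diagonal["identity_pct"] == 100.0).all()

    def test_candidate_pair_reports_all_ten_genes(self, mirror_fixture):
        m = mirror_fixture.manifest
        ca = mirror_fixture.genome_physodic.cluster(
            m["candidate"]["physodic"])
        cb = mirror_fixture.genome_olivetoric.cluster(
            m["candidate"]["olivetoric"])
        df = synteny_table(ca, cb)
        matched_a = set(df["gene_a"])
        assert len(matched_a) == 10
        assert df["identity_pct"].between(95, 99).all()

    def test_high_divergence_pair_yields_no_rows(self):
        fx = generate_fixture(FixtureConfig(
            seed=17, n_shared_clusters=4, background_contig_bp=6000,
            shared_core_divergence=0.15))
        ca, cb = fx.manifest["pairs"][-1]
        df = synteny_table(fx.genome_physodic.cluster(ca),
                           fx.genome_olivetoric.cluster(cb))
        assert df.empty
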