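"""Domain parsing, PKS categories, k-mer distances, group placement, NJ."""

import numpy as np
import pytest

from oracles import additive_distance_matrix, jaccard_kmer_distance

from chemotri.model import ChemotriError
from chemotri.pks import (GroupReference, UnknownDomainError, assign_group,
                          classify_category, kmer_distance, nj_tree,
                          parse_domain_string)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestParseDomainString:
    def test_candidate_architecture(self):
        arch = parse_domain_string("SAT-KS-AT-ACP-ACP-TE")
        assert arch.acp_count == 2
        assert not arch.has_cMT
        assert arch.has_TE
        assert not arch.has_reducing

    def test_atranorin_architecture(self):
        arch = parse_domain_string("SAT-KS-AT-PT-ACP-cMT-TE")
        assert arch.has_cMT and arch.has_PT and arch.has_SAT

    def test_mixed_separators_as_published(self):
        arch = parse_domain_string("SAT-KS-AT-ACP ACP-TE")
        assert arch.tokens == ("SAT", "KS", "AT", "ACP", "ACP", "TE")

    def test_unknown_token_named_in_error(self):
        with pytest.raises(UnknownDomainError, match="XYZ"):
            parse_domain_string("XYZ-KS")

    def test_empty_rejected(self):
        with pytest.raises(ChemotriError):
            parse_domain_string("  ")


@pytest.mark.parametrize("domains,expected", [
    ("SAT-KS-AT-ACP-ACP-TE", "NR-PKS"),
    ("KS-AT-DH-KR-ACP", "R-PKS"),
    ("ACP", "other"),
    ("SAT-KS-AT-ACP cMT-TD", "NR-PKS"),   # TD is a release domain, not reducing
])
def test_classify_category(domains, expected):
    assert classify_category(parse_domain_string(domains)) == expected


class TestKmerDistance:
    def test_identical_sequences_at_zero(self):
        seq = "ACGTACGTACGTAGCT"
        assert kmer_distance(seq, seq) == 0.0

    def test_disjoint_sequences_at_one(self):
        assert kmer_distance("A" * 30, "C" * 30) == 1.0

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = _random_seq(rng, int(rng.integers(30, 200)))
            b = _random_seq(rng, int(rng.integers(30, 200)))
            assert kmer_distance(a, b) == jaccard_kmer_distance(a, b, 8)
            assert kmer_distance(a, b) == kmer_distance(b, a)

    def test_monotone_in_mutation_rate(self):
        rng = np.random.default_rng(4)
        for seed in range(3):
            base = _random_seq(np.random.default_rng(seed), 2000)
            near = _mutate(rng, base, 0.02)
            far = _mutate(rng, base, 0.10)
            assert kmer_distance(base, near) < kmer_distance(base, far)

    def test_too_short_rejected(self):
        with pytest.raises(ChemotriError):
            kmer_distance("ACG", "ACGT")


class TestAssignGroup:
    @pytest.fixture()
    def references(self):
        rng = np.random.default_rng(5)
        return [GroupReference(f"ref_{g}", g, _random_seq(rng, 2000))
                for g in ("I", "II", "IX")]

    def test_reference_maps_to_its_own_group(self, references):
        cls = assign_group(references[0].sequence, references)
        assert cls.group == "I"
        assert cls.distance == 0.0
        assert cls.nearest_reference_id == "ref_I"

    def test_five_percent_mutant_recovers_group(self, references):
        rng = np.random.default_rng(6)
        query = _mutate(rng, references[0].sequence, 0.05)
        assert assign_group(query, references).group == "I"

    def test_unrelated_query_is_unknown(self, references):
        rng = np.random.default_rng(7)
        cls = assign_group(_random_seq(rng, 2000), references)
        assert cls.group == "unknown"

    def test_stable_under_reference_duplication(self, references):
        rng = np.random.default_rng(8)
        query = _mutate(rng, references[2].sequence, 0.05)
        before = assign_group(query, references)
        dup = references + [GroupReference("ref_IX_copy", "IX",
                                           references[2].sequence)]
        after = assign_group(query, dup)
        assert (before.group, before.distance) == (after.group,
                                                   after.distance)

    def test_no_references_rejected(self):
        with pytest.raises(ChemotriError):
            assign_group("ACGT" * 10, [])


class TestNJTree:
    @staticmethod
    def _splits(newick, taxa):
        from io import StringIO
        from skbio import TreeNode
        tree = TreeNode.read(StringIO(newick))
        splits = set()
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                splits.add(min(side, frozenset(taxa) - side, key=sorted))
        return splits

    def test_three_taxa_single_topology(self):
        d = {"A": {"A": 0, "B": 2, "C": 3},
             "B": {"A": 2, "B": 0, "C": 4},
             "C": {"A": 3, "B": 4, "C": 0}}
        newick = nj_tree(d)
        assert all(t in newick for t in "ABC")

    def test_recovers_additive_four_taxon_tree(self):
        tree = {"A": ("u", 2.0), "B": ("u", 3.0), "u": ("v", 1.0),
                "C": ("v", 4.0), "D": ("v", 5.0)}
        leaves = ["A", "B", "C", "D"]
        d = additive_distance_matrix(tree, leaves)
        splits = self._splits(nj_tree(d), leaves)
        assert frozenset({"A", "B"}) in splits

    def test_label_invariance_under_permutation(self):
        tree = {"A": ("u", 1.0), "B": ("u", 2.0), "u": ("v", 1.5),
                "C": ("w", 1.0), "D": ("w", 2.5), "w": ("v", 0.5),
                "E": ("v", 3.0)}
        leaves = ["A", "B", "C", "D", "E"]
        d = additive_distance_matrix(tree, leaves)
        perm = ["D", "A", "E", "B", "C"]
        mat = np.array([[d[i][j] for j in leaves] for i in leaves])
        mat_perm = np.array([[d[i][j] for j in perm] for i in perm])
        assert self._splits(nj_tree(mat, ids=leaves), leaves) == \
            self._splits(nj_tree(mat_perm, ids=perm), leaves)
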