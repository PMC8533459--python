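"""RPKM arithmetic, library-size calibration, read counting, activity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemotri import refdata
from chemotri.expression import (CalibrationError, ExpressionRecord,
                                 calibrate_library_size, expression_table,
                                 map_and_count, rank_activity, rpkm)
from chemotri.model import ChemotriError, CountTable, GeneRecord, \
    GenomeAnnotation


class TestRpkm:
    def test_zero_count_is_zero(self):
        assert rpkm(0, 1_000_000, 500) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ChemotriError):
            rpkm(1, 0, 100)
        with pytest.raises(ChemotriError):
            rpkm(1, 100, 0)

    @settings(derandomize=True, max_examples=50)
    @given(raw=st.integers(0, 10**6), lib=st.integers(1, 10**8),
           length=st.integers(1, 10**5), factor=st.integers(1, 1000))
    def test_scale_invariance(self, raw, lib, length, factor):
        """Scaling counts and library size together leaves RPKM unchanged."""
        assert rpkm(raw * factor, lib * factor, length) == \
            pytest.approx(rpkm(raw, lib, length), rel=1e-12)


class TestCalibration:
    def test_single_row_inverts_formula(self):
        lib = calibrate_library_size([(936, 2191, 12.35)])
        assert lib == pytest.approx(34_594_000, rel=0.005)
        # exact inversion: refitting the same row returns the printed value
        assert rpkm(936, lib, 2191) == pytest.approx(12.35, abs=1e-6)

    def test_weighted_least_squares_matches_closed_form(self):
        rows = [(1000, 2000, 9.0), (4000, 1000, 50.0)]  # inconsistent pair
        lib, residuals = calibrate_library_size(rows, return_details=True)
        x = np.array([r * 1e9 / l for r, l, _ in rows])
        p = np.array([v for *_, v in rows])
        assert lib == int(round((x @ x) / (x @ p)))
        assert residuals == pytest.approx(p - x / lib)

    def test_zero_rpkm_rows_unusable(self):
        with pytest.raises(CalibrationError):
            calibrate_library_size([(10, 100, 0.0), (5, 50, None)])


def _toy_genome(genes):
    contig = "".join(seq for _, seq in genes)
    records, pos = [], 1
    out_genes = []
    for gid, seq in genes:
        out_genes.append(GeneRecord(gid, "ctg", pos, pos + len(seq) - 1,
                                    "+", sequence=seq))
        pos += len(seq)
    return GenomeAnnotation("toy", {"ctg": contig}, out_genes)


class TestMapAndCount:
    def test_empty_read_set(self, small_fixture):
        table = map_and_count([], small_fixture.genome_physodic)
        assert table.counts == {} and table.library_size == 0

    def test_fixture_reads_recover_manifest_counts(self, small_fixture):
        from chemotri.simulate import simulate_reads
        genome = small_fixture.genome_physodic
        reads = simulate_reads(genome, small_fixture.counts_physodic,
                               read_length=150, seed=21)
        table = map_and_count(reads, genome)
        assert table.counts == small_fixture.manifest["counts"]["physodic"]
        assert (sum(table.counts.values()) + table.background
                + table.discarded == table.library_size)

    def test_background_reads_count_only_toward_library(self, small_fixture):
        genome = small_fixture.genome_physodic
        bg = genome.contigs["phys_bg"]
        reads = [(f"r{i}", bg[i * 50:i * 50 + 150]) for i in range(20)]
        table = map_and_count(reads, genome)
        assert table.counts == {}
        assert table.library_size == 20
        assert table.background == 20

    def test_read_tied_between_identical_decoys_is_discarded(self):
        rng = np.random.default_rng(23)
        gene = "".join(rng.choice(list("ACGT"), 400))
        spacer = "".join(rng.choice(list("ACGT"), 200))
        genome = _toy_genome([("g1", gene), ("sp", spacer), ("g2", gene)])
        table = map_and_count([("r0", gene[100:250])], genome)
        assert table.counts == {}
        assert table.discarded == 1


class TestRankActivity:
    @pytest.mark.parametrize("chem,expected_top3", [
        ("physodic", ["gene5", "gene6", "gene4"]),
        ("olivetoric", ["gene6", "gene4", "gene5"]),
    ])
    def test_published_columns_rank_order(self, chem, expected_top3):
        rows = refdata.expression_rows(chem)[:10]
        lib = calibrate_library_size(
            [(raw, l, p) for _, _, l, raw, p in
             refdata.expression_rows(chem)])
        table = CountTable(counts={g: raw for g, _, _, raw, _ in rows},
                           library_size=lib)
        records = expression_table(table, [(g, l) for g, _, l, _, _ in rows])
        df = rank_activity([g for g, *_ in rows], records)
        assert df.head(3)["gene_id"].tolist() == expected_top3

    def test_three_active_genes_in_physodic_cluster(self):
        rows = refdata.expression_rows("physodic")[:10]
        lib = calibrate_library_size(
            [(raw, l, p) for _, _, l, raw, p in
             refdata.expression_rows("physodic")])
        table = CountTable(counts={g: raw for g, _, _, raw, _ in rows},
                           library_size=lib)
        records = expression_table(table, [(g, l) for g, _, l, _, _ in rows])
        df = rank_activity([g for g, *_ in rows], records)
        assert set(df[df["active"]]["gene_id"]) == {"gene4", "gene5",
                                                    "gene6"}

    def test_all_zero_cluster_has_no_active_genes(self):
        table = CountTable(counts={}, library_size=100)
        records = expression_table(table, [("a", 100), ("b", 200)])
        df = rank_activity(["a", "b"], records)
        assert not df["active"].any()


def test_expression_record_consistency_enforced():
    with pytest.raises(ChemotriError):
        ExpressionRecord("g", raw_count=10, length_bp=1000,
                         library_size=10**6, rpkm=99.0)
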