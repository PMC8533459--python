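from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chemotri import refdata
from chemotri.filters import ClassifiedCluster
from chemotri.homology import (ChemotypeComparison, HomologyMatch,
                               SimilarityScore)
from chemotri.model import ClusterRecord, GeneRecord
from chemotri.pipeline import RunConfig, run_pipeline
from chemotri.pks import PKSClassification, classify_category, \
    parse_domain_string
from chemotri.simulate import FixtureConfig, generate_fixture, write_fixture

MIRROR_SEED = 7


@pytest.fixture(scope="session")
def mirror_fixture():
    """The full paper-mirror two-genome fixture (51 shared + 5/1 specific)."""
    return generate_fixture(FixtureConfig(seed=MIRROR_SEED))


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced fixture (8 shared clusters — all NR-PKS — plus specifics)."""
    return generate_fixture(FixtureConfig(seed=11, n_shared_clusters=8,
                                          background_contig_bp=8000))


@pytest.fixture(scope="session")
def small_dir(small_fixture, tmp_path_factory):
    d = tmp_path_factory.mktemp("small_fixture")
    write_fixture(small_fixture, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the mirror fixture, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    summary = run_pipeline(RunConfig(out_dir=str(out), seed=MIRROR_SEED))
    return out, summary


def build_catalog_clusters(drop_labels: dict[int, str] | None = None,
                           ) -> list[ClassifiedCluster]:
    """The eight published shared NR-PKS clusters as classified stubs.

    Gene content and domain strings follow the published catalog; gene
    coordinates are laid out schematically (1 kb genes, 100 bp apart).
    ``drop_labels`` maps a cluster number to a companion label to omit.
    """
    drop_labels = drop_labels or {}
    out = []
    for spec in refdata.NR_PKS_CATALOG:
        if spec.number == refdata.CANDIDATE_CLUSTER_NUMBER:
            labels = list(refdata.CANDIDATE_GENE_LABELS)
            core_index = labels.index("NR-PKS")
        else:
            labels = list(spec.companions)
            labels += ["unidentified"] * (spec.total_genes - 1 - len(labels))
            if "red-PKS" in labels:
                # divergently transcribed R-PKS right before the NR-PKS
                labels.remove("red-PKS")
                labels = ["red-PKS", "NR-PKS"] + labels
            else:
                labels = [labels[0], "NR-PKS"] + labels[1:]
            core_index = 1
        dropped = drop_labels.get(spec.number)
        if dropped is not None:
            labels = [("unidentified" if l == dropped else l)
                      for l in labels]
        genes = []
        pos = 1
        for k, label in enumerate(labels):
            strand = "+"
            if label == "red-PKS" and k == core_index - 1:
                strand = "-"
            genes.append(GeneRecord(gene_id=f"c{spec.number:02d}_g{k + 1}",
                                    contig_id=f"c{spec.number:02d}_ctg",
                                    start=pos, end=pos + 999, strand=strand,
                                    product_label=label))
            pos += 1100
        cluster = ClusterRecord(
            cluster_id=f"c{spec.number:02d}", genome_id="catalog",
            region_label=refdata.REGION_LABELS.get(spec.number, ""),
            core_gene_ids=(genes[core_index].gene_id,),
            core_type="NR-PKS", genes=tuple(genes))
        arch = parse_domain_string(spec.domains)
        cls = PKSClassification(category=classify_category(arch),
                                group=spec.group)
        out.append(ClassifiedCluster(cluster, arch, cls))
    return out


def all_shared_comparison(classified) -> ChemotypeComparison:
    """A comparison stub marking every given cluster as shared."""
    sim = SimilarityScore("q", "s", 1.0, 1, 1.0)
    matches = [HomologyMatch(cc.cluster.cluster_id,
                             cc.cluster.cluster_id + "_b", sim)
               for cc in classified]
    return ChemotypeComparison(shared_pairs=matches, specific_a=[],
                               specific_b=[], ambiguous_a=[], ambiguous_b=[])
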