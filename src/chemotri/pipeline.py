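"""End-to-end orchestration: simulate/load → compare → classify → filter →
quantify → report, as one reproducible, seed-deterministic run.

Outputs in the run directory: ``pairs.tsv`` (RBH homolog pairs),
``specific.tsv`` (chemotype-specific clusters with absence evidence),
``classifications.tsv``, ``verdicts.tsv``, ``expression.tsv``,
``synteny.tsv``, ``nj_tree.nwk``, ``scheme.json`` and ``summary.json``.
Every number in the summary is recomputable from the stage tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import refdata
from .expression import expression_table, map_and_count, rank_activity
from .filters import (ClassifiedCluster, detect_atranorin_cluster,
                      evaluate_candidates, find_divergent_pair)
from .homology import (core_genes_of, partition_chemotypes,
                       reciprocal_best_hit, synteny_table)
from .model import ChemotriError, GenomeAnnotation, read_genome, write_report
from .pks import (GroupReference, assign_group, classify_category,
                  kmer_distance, nj_tree, parse_domain_string)
from .scheme import assemble_depside, build_ring, depsidonize
from .simulate import FixtureConfig, generate_fixture, simulate_reads

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "PipelineStageError", "run_pipeline",
           "load_genome_dir"]


class ConfigError(ChemotriError):
    """A run configuration value is out of its documented range."""


class PipelineStageError(ChemotriError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = type(cause).__name__
        super().__init__(f"stage {stage} failed [{self.code}]: {cause}")


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    With ``genome_a_dir``/``genome_b_dir`` unset the run operates on the
    seed-determined synthetic fixture.  Thresholds: ``min_identity`` (RBH
    acceptance, fraction), ``synteny_min_identity_pct``/``synteny_min_length``
    (synteny rows), ``min_read_identity`` (read counting),
    ``group_max_distance`` (group placement), ``activity_factor``
    (transcription flag), ``fas_max_intergenic_bp`` (FAS adjacency).
    """

    out_dir: str = "chemotri_run"
    seed: int = 7
    genome_a_dir: str | None = None
    genome_b_dir: str | None = None
    reads_a: str | None = None
    reads_b: str | None = None
    references_fasta: str | None = None
    min_identity: float = 0.7
    synteny_min_identity_pct: float = 90.0
    synteny_min_length: int = 50
    min_read_identity: float = 0.95
    group_max_distance: float = 0.6
    activity_factor: float = 10.0
    fas_max_intergenic_bp: int = 5000
    read_length: int = 150
    simulate_reads: bool = True
    #: overrides forwarded to FixtureConfig in fixture mode (e.g. scale the
    #: run down with {"n_shared_clusters": 5})
    fixture_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
                ("min_identity", self.min_identity, 0.0, 1.0),
                ("min_read_identity", self.min_read_identity, 0.0, 1.0),
                ("group_max_distance", self.group_max_distance, 0.0, 1.0),
                ("synteny_min_identity_pct", self.synteny_min_identity_pct,
                 0.0, 100.0)):
            if not lo <= v <= hi:
                raise ConfigError(f"{name} {v} outside [{lo}, {hi}]")
        if self.activity_factor <= 0 or self.fas_max_intergenic_bp < 0:
            raise ConfigError("activity_factor/fas_max_intergenic_bp invalid")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def load_genome_dir(path: str | Path,
                    genome_id: str | None = None) -> tuple[GenomeAnnotation,
                                                           dict[str, str]]:
    """Load a fixture-layout genome directory; returns (genome, domains)."""
    path = Path(path)
    genome = read_genome(path / "contigs.fasta", path / "genes.gff3",
                         path / "clusters.tsv",
                         genome_id=genome_id or path.name)
    domains: dict[str, str] = {}
    dom_path = path / "domains.tsv"
    if dom_path.exists():
        df = pd.read_csv(dom_path, sep="\t")
        domains = dict(zip(df["cluster_id"], df["domains"]))
    return genome, domains


def _read_references(path: str | Path) -> list[GroupReference]:
    from Bio import SeqIO
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        group = dict(kv.split("=") for kv in rec.description.split()
                     if "=" in kv).get("group", "unknown")
        refs.append(GroupReference(rec.id, group, str(rec.seq)))
    return refs


def _classify_genome(genome: GenomeAnnotation, domains: dict[str, str],
                     references, max_distance: float,
                     ) -> list[ClassifiedCluster]:
    out = []
    for cluster in genome.clusters:
        dom = domains.get(cluster.cluster_id)
        if dom is None:
            out.append(ClassifiedCluster(cluster, None, None))
            continue
        arch = parse_domain_string(dom)
        category = classify_category(arch)
        if category == "NR-PKS" and references:
            seq = genome.gene_sequence(cluster.gene(cluster.core_gene_ids[0]))
            cls = assign_group(seq, references,
                               max_distance=max_distance, arch=arch)
        else:
            from .pks import PKSClassification
            cls = PKSClassification(category=category)
        out.append(ClassifiedCluster(cluster, arch, cls))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full comparison and write all reports; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: inputs ------------------------------------------------------
    try:
        if config.genome_a_dir is None:
            overrides = {k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in config.fixture_overrides.items()}
            fixture = generate_fixture(FixtureConfig(seed=config.seed,
                                                     **overrides))
            genome_a, genome_b = (fixture.genome_physodic,
                                  fixture.genome_olivetoric)
            domains = fixture.domains
            references = fixture.references
            queries = (fixture.hexa_query, fixture.hexb_query)
            if config.simulate_reads:
                reads_a = simulate_reads(genome_a, fixture.counts_physodic,
                                         config.read_length, config.seed)
                reads_b = simulate_reads(genome_b, fixture.counts_olivetoric,
                                         config.read_length, config.seed + 1)
            else:
                reads_a = reads_b = None
        else:
            if config.genome_b_dir is None:
                raise ConfigError("genome_b_dir required with genome_a_dir")
            genome_a, dom_a = load_genome_dir(config.genome_a_dir)
            genome_b, dom_b = load_genome_dir(config.genome_b_dir)
            domains = dom_a | dom_b
            references = (_read_references(config.references_fasta)
                          if config.references_fasta else [])
            queries = None
            reads_a = config.reads_a
            reads_b = config.reads_b
    except ChemotriError:
        raise
    except Exception as e:                      # pragma: no cover - defensive
        raise PipelineStageError("inputs", e) from e
    log.info("inputs: %d + %d clusters", len(genome_a.clusters),
             len(genome_b.clusters))

    # --- stage: homology ----------------------------------------------------
    try:
        matches = reciprocal_best_hit(core_genes_of(genome_a),
                                      core_genes_of(genome_b),
                                      min_identity=config.min_identity)
        comparison = partition_chemotypes(
            genome_a, genome_b, matches, reads_a=reads_a, reads_b=reads_b,
            min_read_identity=config.min_read_identity)
    except Exception as e:
        raise PipelineStageError("homology", e) from e
    log.info("homology: %d pairs, %d/%d specific", len(matches),
             len(comparison.specific_a), len(comparison.specific_b))

    write_report(pd.DataFrame(
        [(m.cluster_a, m.cluster_b, round(m.core_similarity.identity, 4),
          m.core_similarity.score) for m in matches],
        columns=["cluster_a", "cluster_b", "identity", "score"]),
        out / "pairs.tsv", sort_by=["cluster_a"])
    spec_rows = ([(genome_a.genome_id, cid, ev, "specific")
                  for cid, ev in comparison.specific_a]
                 + [(genome_b.genome_id, cid, ev, "specific")
                    for cid, ev in comparison.specific_b]
                 + [(genome_a.genome_id, cid, ev, "ambiguous")
                    for cid, ev in comparison.ambiguous_a]
                 + [(genome_b.genome_id, cid, ev, "ambiguous")
                    for cid, ev in comparison.ambiguous_b])
    write_report(pd.DataFrame(spec_rows, columns=[
        "genome_id", "cluster_id", "absence_evidence", "status"]),
        out / "specific.tsv", sort_by=["genome_id", "cluster_id"])

    # --- stage: classification ---------------------------------------------
    try:
        classified_a = _classify_genome(genome_a, domains, references,
                                        config.group_max_distance)
        classified_b = _classify_genome(genome_b, domains, references,
                                        config.group_max_distance)
    except Exception as e:
        raise PipelineStageError("classification", e) from e

    rows = []
    for cc in classified_a + classified_b:
        if cc.architecture is None:
            continue
        rows.append((cc.cluster.genome_id, cc.cluster.cluster_id,
                     str(cc.architecture), cc.classification.category,
                     cc.classification.group,
                     cc.classification.nearest_reference_id or "",
                     (round(cc.classification.distance, 4)
                      if cc.classification.distance is not None else "")))
    write_report(pd.DataFrame(rows, columns=[
        "genome_id", "cluster_id", "domains", "category", "group",
        "nearest_reference", "distance"]), out / "classifications.tsv",
        sort_by=["genome_id", "cluster_id"])

    nr_a = [cc for cc in classified_a
            if cc.classification and cc.classification.category == "NR-PKS"]
    if len(nr_a) >= 3:
        ids = [cc.cluster.cluster_id for cc in nr_a]
        seqs = {cc.cluster.cluster_id: genome_a.gene_sequence(
            cc.cluster.gene(cc.cluster.core_gene_ids[0])) for cc in nr_a}
        dist = {i: {j: (0.0 if i == j else kmer_distance(seqs[i], seqs[j]))
                    for j in ids} for i in ids}
        (out / "nj_tree.nwk").write_text(nj_tree(dist) + "\n")

    # --- stage: candidate filter -------------------------------------------
    try:
        verdicts = evaluate_candidates(classified_a, comparison)
        atranorin = detect_atranorin_cluster(classified_a, comparison)
        fas_loci = {}
        if queries is not None:
            for genome in (genome_a, genome_b):
                locus = find_divergent_pair(
                    genome, queries[0], queries[1],
                    min_identity=config.min_identity,
                    max_intergenic_bp=config.fas_max_intergenic_bp)
                fas_loci[genome.genome_id] = (
                    dataclasses.asdict(locus) if locus else None)
    except Exception as e:
        raise PipelineStageError("filter", e) from e

    write_report(pd.DataFrame(
        [(v.cluster_id, v.passed, *(v.criteria[k] for k in (
            "in_both_chemotypes", "has_NR_PKS", "has_CytP450", "two_ACPs")),
          ";".join(sorted(v.negative_evidence)), v.narrative)
         for v in verdicts],
        columns=["cluster_id", "passed", "in_both_chemotypes", "has_NR_PKS",
                 "has_CytP450", "two_ACPs", "negative_evidence",
                 "narrative"]), out / "verdicts.tsv")
    candidates = [v.cluster_id for v in verdicts if v.passed]
    log.info("filter: %d candidate(s), atranorin=%s", len(candidates),
             atranorin)

    # --- stage: expression --------------------------------------------------
    try:
        expr_frames = []
        activity = {}
        for genome, reads, classified in ((genome_a, reads_a, classified_a),
                                          (genome_b, reads_b, classified_b)):
            if reads is None:
                continue
            table = map_and_count(reads, genome,
                                  min_read_identity=config.min_read_identity)
            cand = [v.cluster_id for v in verdicts if v.passed]
            cand_cluster = None
            if cand:
                pair = {m.cluster_a: m.cluster_b for m in matches}
                cid = (cand[0] if genome is genome_a
                       else pair.get(cand[0], cand[0]))
                if any(c.cluster_id == cid for c in genome.clusters):
                    cand_cluster = genome.cluster(cid)
            gene_set = []
            if cand_cluster is not None:
                gene_set += [(g.gene_id, g.length_bp)
                             for g in cand_cluster.genes]
            gene_set += [(g.gene_id, g.length_bp) for g in genome.genes
                         if g.canonical_label in {"FAS-A", "FAS-B"}]
            records = expression_table(table, gene_set)
            df = pd.DataFrame(
                [(genome.genome_id, r.gene_id, r.length_bp, r.raw_count,
                  round(r.rpkm, 4)) for r in records],
                columns=["genome_id", "gene_id", "length_bp", "raw_count",
                         "rpkm"])
            expr_frames.append(df)
            if cand_cluster is not None:
                activity[genome.genome_id] = rank_activity(
                    cand_cluster, records,
                    activity_factor=config.activity_factor)
        if expr_frames:
            write_report(pd.concat(expr_frames, ignore_index=True),
                         out / "expression.tsv",
                         sort_by=["genome_id", "gene_id"])
    except Exception as e:
        raise PipelineStageError("expression", e) from e

    # --- stage: synteny for the candidate pair ------------------------------
    if candidates:
        pair = {m.cluster_a: m.cluster_b for m in matches}
        cid_a = candidates[0]
        if cid_a in pair:
            df = synteny_table(genome_a.cluster(cid_a),
                               genome_b.cluster(pair[cid_a]),
                               config.synteny_min_identity_pct,
                               config.synteny_min_length)
            write_report(df, out / "synteny.tsv", sort_by=["gene_a"])

    # --- stage: biosynthesis scheme ----------------------------------------
    olivetoric = assemble_depside(build_ring(6, 4), build_ring(6, 3))
    physodic = depsidonize(olivetoric)
    lecanoric = assemble_depside(build_ring(2, 3), build_ring(2, 3))
    scheme = {"olivetoric_acid": olivetoric.as_dict(),
              "physodic_acid": physodic.as_dict(),
              "lecanoric_acid": lecanoric.as_dict()}
    (out / "scheme.json").write_text(json.dumps(scheme, indent=1,
                                                sort_keys=True) + "\n")

    # --- summary ------------------------------------------------------------
    nr_shared_pairs = [m for m in matches
                       if any(cc.cluster.cluster_id == m.cluster_a
                              and cc.classification
                              and cc.classification.category == "NR-PKS"
                              for cc in classified_a)]
    summary = {
        "n_clusters": {genome_a.genome_id: len(genome_a.clusters),
                       genome_b.genome_id: len(genome_b.clusters)},
        "shared_pairs": len(matches),
        "specific": {genome_a.genome_id: len(comparison.specific_a),
                     genome_b.genome_id: len(comparison.specific_b)},
        "ambiguous": {genome_a.genome_id: len(comparison.ambiguous_a),
                      genome_b.genome_id: len(comparison.ambiguous_b)},
        "nr_pks_shared": len(nr_shared_pairs),
        "n_candidates": len(candidates),
        "candidate_cluster": candidates[0] if candidates else None,
        "atranorin_cluster": atranorin,
        "fas_loci": fas_loci if queries is not None else {},
        "top_active_genes": {
            gid: df.head(3)["gene_id"].tolist()
            for gid, df in activity.items()},
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True) + "\n")
    return summary
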