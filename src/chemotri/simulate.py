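"""Synthetic two-genome fixture mirroring the chemotype comparison.

The generator plants, with known ground truth, everything the downstream
stages must recover: 51 shared clusters whose core genes differ between the
two genomes by a configurable substitution divergence, five physodic-only
and one olivetoric-only cluster with no homolog and no read support in the
other genome, the eight shared NR-PKS clusters with their published domain
strings and companion-gene content (the candidate depside/depsidone cluster
among them with its ten genes at the published lengths), within-genome
paralog decoys that make reciprocal-best-hit matching non-trivial, one
adjacent divergently transcribed HexA/HexB FAS pair per genome, labelled
group-reference PKS sequences, and per-gene read counts at a desk scale
(published transcriptome counts divided by ``count_scale``).

All planted truths are recorded in a JSON-serialisable manifest; downstream
tests read expectations from the manifest, not from literals.  Identical
seeds yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import refdata
from .expression import calibrate_library_size
from .model import (ChemotriError, ClusterRecord, CountTable, GeneRecord,
                    GenomeAnnotation, write_cluster_table)
from .pks import GroupReference

__all__ = ["FixtureConfig", "FixtureResult", "generate_fixture",
           "simulate_reads", "write_fastq", "write_fixture", "ReadLengthError"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Generic reducing-PKS domain string used for R-PKS and hybrid cores.
R_PKS_DOMAINS = "KS-AT-DH-MT-ER-KR-ACP"


class ReadLengthError(ChemotriError):
    """Requested read length exceeds a counted gene's length."""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitutions at the given rate (always to a new base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASES, arr)  # bases are sorted (A<C<G<T)
    mask = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    return _BASES[idx].tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _default_library_sizes() -> tuple[int, int]:
    sizes = []
    for chem in ("physodic", "olivetoric"):
        rows = [(raw, length, p)
                for _, _, length, raw, p in refdata.expression_rows(chem)]
        sizes.append(calibrate_library_size(rows))
    return tuple(sizes)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions the fixture emulates.

    Defaults are the published counts, lengths and cluster layout; the desk
    scale divides transcriptome counts and library sizes by ``count_scale``
    (RPKM is scale-invariant, so normalised values are unchanged).
    """

    seed: int = 7
    n_shared_clusters: int = 51
    specific_physodic: tuple[str, ...] = ("R-PKS", "R-PKS", "hybrid",
                                          "R-PKS", "terpene")
    specific_olivetoric: tuple[str, ...] = ("terpene",)
    shared_core_divergence: float = 0.03
    decoy_paralog_divergence: float = 0.15
    group_reference_divergence: float = 0.02
    indel_rate: float = 0.0          # reserved; substitutions only by default
    core_gene_length_bp: int = 3000
    companion_length_range: tuple[int, int] = (800, 1800)
    n_companions_default: int = 6
    cluster4_gene_lengths: tuple[int, ...] = refdata.CANDIDATE_GENE_LENGTHS
    cluster4_counts_physodic: tuple[int, ...] = (
        refdata.CANDIDATE_RAW_READS["physodic"])
    cluster4_counts_olivetoric: tuple[int, ...] = (
        refdata.CANDIDATE_RAW_READS["olivetoric"])
    fas_lengths: tuple[int, int] = refdata.FAS_GENE_LENGTHS
    fas_orientation: str = "divergent"   # divergent | tandem | convergent
    fas_intergenic_bp: int = 800
    library_sizes: tuple[int, int] | None = None  # None -> calibrated
    count_scale: int = 1000
    intergenic_bp: int = 200
    flank_bp: int = 300
    decoy_every: int = 10
    background_contig_bp: int = 60_000
    read_length: int = 150

    def __post_init__(self) -> None:
        for rate in (self.shared_core_divergence,
                     self.decoy_paralog_divergence,
                     self.group_reference_divergence, self.indel_rate):
            if not 0.0 <= rate < 0.5:
                raise ChemotriError(f"divergence rate {rate} outside [0,0.5)")
        if (min(self.cluster4_counts_physodic
                + self.cluster4_counts_olivetoric) < 0):
            raise ChemotriError("read counts must be non-negative")
        if (min(self.cluster4_gene_lengths) <= 0
                or min(self.fas_lengths) <= 0
                or self.core_gene_length_bp <= 0):
            raise ChemotriError("gene lengths must be positive")
        if self.n_shared_clusters < 0:
            raise ChemotriError("n_shared_clusters must be >= 0")
        if self.fas_orientation not in {"divergent", "tandem", "convergent"}:
            raise ChemotriError(
                f"unknown FAS orientation {self.fas_orientation!r}")

    def resolved_library_sizes(self) -> tuple[int, int]:
        return (self.library_sizes if self.library_sizes is not None
                else _default_library_sizes())


@dataclass
class FixtureResult:
    """Generated fixture: two genomes, counts, references, queries, truth."""

    config: FixtureConfig
    genome_physodic: GenomeAnnotation
    genome_olivetoric: GenomeAnnotation
    counts_physodic: CountTable
    counts_olivetoric: CountTable
    references: list[GroupReference]
    hexa_query: str
    hexb_query: str
    domains: dict[str, str]          # cluster_id -> core domain string
    manifest: dict

    def genome(self, chemotype: str) -> GenomeAnnotation:
        return (self.genome_physodic if chemotype == "physodic"
                else self.genome_olivetoric)

    def counts(self, chemotype: str) -> CountTable:
        return (self.counts_physodic if chemotype == "physodic"
                else self.counts_olivetoric)

    def write(self, outdir: str | Path) -> None:
        write_fixture(self, outdir)


# ---------------------------------------------------------------------------
# Cluster blueprints
# ---------------------------------------------------------------------------


@dataclass
class _GeneSpec:
    label: str
    length: int
    strand: str = "+"
    is_core: bool = False
    role: str | None = None          # e.g. "gene5" for candidate genes


def _nr_cluster_blueprint(spec: refdata.NRPKSClusterSpec,
                          config: FixtureConfig,
                          rng: np.random.Generator) -> list[_GeneSpec]:
    if spec.number == refdata.CANDIDATE_CLUSTER_NUMBER:
        genes = []
        for i, (label, length) in enumerate(zip(
                refdata.CANDIDATE_GENE_LABELS, config.cluster4_gene_lengths)):
            genes.append(_GeneSpec(label=label, length=length,
                                   is_core=(label == "NR-PKS"),
                                   role=f"gene{i + 1}"))
        return genes
    lo, hi = config.companion_length_range
    core_len = config.core_gene_length_bp
    companions = [_GeneSpec(label=lab, length=int(rng.integers(lo, hi + 1)))
                  for lab in spec.companions]
    n_pad = spec.total_genes - 1 - len(companions)
    companions += [_GeneSpec(label="unidentified",
                             length=int(rng.integers(lo, hi + 1)))
                   for _ in range(max(0, n_pad))]
    core = _GeneSpec(label="NR-PKS", length=core_len, is_core=True)
    # cluster 5 carries an R-PKS right next to the NR-PKS, divergently
    # transcribed (the published exclusion argument); put it first on "-".
    genes = companions[:]
    if any(g.label == "red-PKS" for g in genes):
        rpks = next(g for g in genes if g.label == "red-PKS")
        genes.remove(rpks)
        rpks.strand = "-"
        genes = [rpks, core] + genes
    else:
        genes = [genes[0], core] + genes[1:] if genes else [core]
    return genes


def _generic_blueprint(core_type: str, config: FixtureConfig,
                       rng: np.random.Generator) -> list[_GeneSpec]:
    lo, hi = config.companion_length_range
    core_label = {"R-PKS": "R-PKS", "T3-PKS": "T3-PKS", "NRPS": "NRPS",
                  "NRPS-like": "NRPS-like", "terpene": "terpene synthase",
                  "indole": "indole synthase", "hybrid": "R-PKS",
                  }[core_type]
    genes = [_GeneSpec(label=core_label, length=config.core_gene_length_bp,
                       is_core=True)]
    if core_type == "hybrid":
        genes.append(_GeneSpec(label="NRPS",
                               length=int(rng.integers(lo, hi + 1))))
    genes += [_GeneSpec(label="unidentified",
                        length=int(rng.integers(lo, hi + 1)))
              for _ in range(config.n_companions_default - len(genes) + 1)]
    return genes


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _assemble_contig(contig_id: str, genes: list[tuple[str, str, str, str]],
                     config: FixtureConfig, rng: np.random.Generator,
                     intergenic: int | None = None,
                     ) -> tuple[str, list[GeneRecord]]:
    """Lay genes ``(gene_id, label, strand, transcript_seq)`` on one contig."""
    gap = config.intergenic_bp if intergenic is None else intergenic
    parts = [_random_dna(rng, config.flank_bp)]
    pos = config.flank_bp
    records = []
    for i, (gid, label, strand, seq) in enumerate(genes):
        if i:
            parts.append(_random_dna(rng, gap))
            pos += gap
        genomic = _revcomp(seq) if strand == "-" else seq
        start = pos + 1
        end = pos + len(seq)
        parts.append(genomic)
        pos = end
        records.append(GeneRecord(gene_id=gid, contig_id=contig_id,
                                  start=start, end=end, strand=strand,
                                  product_label=label, sequence=seq))
    parts.append(_random_dna(rng, config.flank_bp))
    return "".join(parts), records


def generate_fixture(config: FixtureConfig | None = None) -> FixtureResult:
    """Generate the paper-mirror two-genome fixture with planted truth."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    lib_phys, lib_oliv = config.resolved_library_sizes()

    catalog = {s.number: s for s in refdata.NR_PKS_CATALOG}
    shared_numbers = [n for n in sorted(refdata.SHARED_CORE_TYPES)
                      if n <= config.n_shared_clusters][:config.n_shared_clusters]

    # --- group references -------------------------------------------------
    ref_specs = [
        ("ref_I_a", "I", refdata.CANDIDATE_GENE_LENGTHS[4]),
        ("ref_I_b", "I", config.core_gene_length_bp),
        ("ref_II", "II", config.core_gene_length_bp),
        ("ref_V", "V", config.core_gene_length_bp),
        ("ref_VII", "VII", config.core_gene_length_bp),
        ("ref_IX", "IX", config.core_gene_length_bp),
    ]
    references = [GroupReference(rid, grp, _random_dna(rng, n))
                  for rid, grp, n in ref_specs]
    ref_by_id = {r.reference_id: r for r in references}
    cluster_ref = {1: "ref_VII", 2: "ref_V", 3: "ref_II", 4: "ref_I_a",
                   5: "ref_I_b", 6: "ref_IX", 7: "ref_II", 8: "ref_II"}

    # --- shared clusters in genome A (physodic), mirrored into B ----------
    contigs_a: dict[str, str] = {}
    contigs_b: dict[str, str] = {}
    genes_a: list[GeneRecord] = []
    genes_b: list[GeneRecord] = []
    clusters_a: list[ClusterRecord] = []
    clusters_b: list[ClusterRecord] = []
    domains: dict[str, str] = {}
    manifest_pairs: list[list[str]] = []
    manifest_nr: dict[str, dict] = {}
    decoys: dict[str, str] = {}
    candidate_ids: dict[str, str] = {}
    atranorin_ids: dict[str, str] = {}
    role_genes: dict[str, dict[str, str]] = {"physodic": {},
                                             "olivetoric": {}}

    for n in shared_numbers:
        core_type = refdata.SHARED_CORE_TYPES[n]
        region = refdata.REGION_LABELS.get(n, f"Region {n}.1")
        cid_a, cid_b = f"phys_c{n:02d}", f"oliv_c{n:02d}"
        if n in catalog and core_type == "NR-PKS":
            blueprint = _nr_cluster_blueprint(catalog[n], config, rng)
            domain_string = catalog[n].domains
        else:
            blueprint = _generic_blueprint(core_type, config, rng)
            domain_string = (R_PKS_DOMAINS
                             if core_type in {"R-PKS", "hybrid"} else None)

        # genome A transcript sequences
        seqs_a = []
        for g in blueprint:
            if g.is_core and n in catalog and core_type == "NR-PKS":
                ref = ref_by_id[cluster_ref[n]]
                seq = _mutate(rng, ref.sequence,
                              config.group_reference_divergence)
            else:
                seq = _random_dna(rng, g.length)
            seqs_a.append(seq)
        seqs_b = [_mutate(rng, s, config.shared_core_divergence)
                  for s in seqs_a]

        for cid, gprefix, seqs, contigs, genes, clusters, chem in (
                (cid_a, "phys", seqs_a, contigs_a, genes_a, clusters_a,
                 "physodic"),
                (cid_b, "oliv", seqs_b, contigs_b, genes_b, clusters_b,
                 "olivetoric")):
            laid = []
            gene_ids = []
            cores = []
            for k, (g, seq) in enumerate(zip(blueprint, seqs), start=1):
                gid = f"{cid}_g{k}"
                laid.append((gid, g.label, g.strand, seq))
                gene_ids.append(gid)
                if g.is_core:
                    cores.append(gid)
                if g.role:
                    role_genes[chem][g.role] = gid
            # within-genome paralog decoy on every decoy_every-th cluster
            # (genome A only): an extra diverged copy of the core gene,
            # entered as an additional core so RBH has to defeat it
            if (gprefix == "phys" and config.decoy_every
                    and n % config.decoy_every == 0):
                decoy_seq = _mutate(rng, seqs[[g.is_core
                                               for g in blueprint].index(True)],
                                    config.decoy_paralog_divergence)
                gid = f"{cid}_decoy"
                core_label = blueprint[[g.is_core for g in
                                        blueprint].index(True)].label
                laid.append((gid, core_label, "+", decoy_seq))
                cores.append(gid)
                decoys[cid] = gid
            contig_id = f"{cid}_ctg"
            contig, records = _assemble_contig(contig_id, laid, config, rng)
            contigs[contig_id] = contig
            genes.extend(records)
            clusters.append(ClusterRecord(
                cluster_id=cid, genome_id=chem, region_label=region,
                core_gene_ids=tuple(cores), core_type=core_type,
                genes=tuple(records)))
            if domain_string:
                domains[cid] = domain_string
        manifest_pairs.append([cid_a, cid_b])
        if n in catalog and core_type == "NR-PKS":
            manifest_nr[str(n)] = {
                "physodic": cid_a, "olivetoric": cid_b,
                "domains": domain_string, "group": catalog[n].group,
                "reference_id": cluster_ref[n],
                "total_genes": catalog[n].total_genes,
            }
            if n == refdata.CANDIDATE_CLUSTER_NUMBER:
                candidate_ids = {"physodic": cid_a, "olivetoric": cid_b}
            if n == refdata.ATRANORIN_CLUSTER_NUMBER:
                atranorin_ids = {"physodic": cid_a, "olivetoric": cid_b}

    # --- chemotype-specific clusters ---------------------------------------
    specific_ids: dict[str, list[str]] = {"physodic": [], "olivetoric": []}
    specs = ([("physodic", t) for t in config.specific_physodic]
             + [("olivetoric", t) for t in config.specific_olivetoric])
    for offset, (chem, core_type) in enumerate(specs):
        n = 52 + offset
        cid = f"{'phys' if chem == 'physodic' else 'oliv'}_c{n:02d}"
        region = refdata.REGION_LABELS.get(n, f"Region {n}.1")
        blueprint = _generic_blueprint(core_type, config, rng)
        laid = []
        cores = []
        for k, g in enumerate(blueprint, start=1):
            gid = f"{cid}_g{k}"
            laid.append((gid, g.label, g.strand, _random_dna(rng, g.length)))
            if g.is_core:
                cores.append(gid)
        contig_id = f"{cid}_ctg"
        contigs = contigs_a if chem == "physodic" else contigs_b
        genes = genes_a if chem == "physodic" else genes_b
        clusters = clusters_a if chem == "physodic" else clusters_b
        contig, records = _assemble_contig(contig_id, laid, config, rng)
        contigs[contig_id] = contig
        genes.extend(records)
        clusters.append(ClusterRecord(
            cluster_id=cid, genome_id=chem, region_label=region,
            core_gene_ids=tuple(cores), core_type=core_type,
            genes=tuple(records)))
        if core_type in {"R-PKS", "hybrid"}:
            domains[cid] = R_PKS_DOMAINS
        specific_ids[chem].append(cid)

    # --- HexA/HexB FAS pair -------------------------------------------------
    strands = {"divergent": ("-", "+"), "convergent": ("+", "-"),
               "tandem": ("+", "+")}[config.fas_orientation]
    hexa_a = _random_dna(rng, config.fas_lengths[0])
    hexb_a = _random_dna(rng, config.fas_lengths[1])
    hexa_b = _mutate(rng, hexa_a, config.shared_core_divergence)
    hexb_b = _mutate(rng, hexb_a, config.shared_core_divergence)
    fas_manifest = {}
    for chem, prefix, (ha, hb), contigs, genes in (
            ("physodic", "phys", (hexa_a, hexb_a), contigs_a, genes_a),
            ("olivetoric", "oliv", (hexa_b, hexb_b), contigs_b, genes_b)):
        contig_id = f"{prefix}_fas_ctg"
        laid = [(f"{prefix}_hexA", "FAS alpha subunit (HexA)", strands[0],
                 ha),
                (f"{prefix}_hexB", "FAS beta subunit (HexB)", strands[1],
                 hb)]
        contig, records = _assemble_contig(
            contig_id, laid, config, rng, intergenic=config.fas_intergenic_bp)
        contigs[contig_id] = contig
        genes.extend(records)
        fas_manifest[chem] = {"hexA": records[0].gene_id,
                              "hexB": records[1].gene_id,
                              "contig": contig_id,
                              "orientation": config.fas_orientation,
                              "intergenic_bp": config.fas_intergenic_bp}
        role_genes[chem]["FAS-A"] = records[0].gene_id
        role_genes[chem]["FAS-B"] = records[1].gene_id

    # HexA/HexB search queries: slightly diverged homologs of the physodic
    # copies (synthetic stand-ins for known homologs from another lichen)
    hexa_query = _mutate(rng, hexa_a, 0.05)
    hexb_query = _mutate(rng, hexb_a, 0.05)

    # --- background contigs -------------------------------------------------
    contigs_a["phys_bg"] = _random_dna(rng, config.background_contig_bp)
    contigs_b["oliv_bg"] = _random_dna(rng, config.background_contig_bp)

    genome_a = GenomeAnnotation(genome_id="physodic", contigs=contigs_a,
                                genes=genes_a, clusters=clusters_a)
    genome_b = GenomeAnnotation(genome_id="olivetoric", contigs=contigs_b,
                                genes=genes_b, clusters=clusters_b)

    # --- desk-scale count tables -------------------------------------------
    scale = config.count_scale

    def _scaled(v: int) -> int:
        return int(round(v / scale)) if scale > 1 else int(v)

    counts = {}
    for chem, c4, fas, lib in (
            ("physodic", config.cluster4_counts_physodic,
             refdata.FAS_RAW_READS["physodic"], lib_phys),
            ("olivetoric", config.cluster4_counts_olivetoric,
             refdata.FAS_RAW_READS["olivetoric"], lib_oliv)):
        table: dict[str, int] = {}
        roles = role_genes[chem]
        for i, raw in enumerate(c4):
            gid = roles.get(f"gene{i + 1}")
            if gid is not None and _scaled(raw) > 0:
                table[gid] = _scaled(raw)
        for name, raw in zip(("FAS-A", "FAS-B"), fas):
            if _scaled(raw) > 0:
                table[roles[name]] = _scaled(raw)
        counts[chem] = CountTable(counts=table, library_size=_scaled(lib))

    manifest = {
        "config": dataclasses.asdict(config),
        "library_sizes": {"physodic": lib_phys, "olivetoric": lib_oliv},
        "scaled_library_sizes": {
            "physodic": counts["physodic"].library_size,
            "olivetoric": counts["olivetoric"].library_size},
        "n_clusters": {"physodic": len(clusters_a),
                       "olivetoric": len(clusters_b)},
        "pairs": manifest_pairs,
        "specific": specific_ids,
        "nr_pks_clusters": manifest_nr,
        "candidate": candidate_ids,
        "atranorin": atranorin_ids,
        "fas": fas_manifest,
        "decoys": decoys,
        "role_genes": role_genes,
        "counts": {chem: dict(sorted(counts[chem].counts.items()))
                   for chem in counts},
        "domains": domains,
    }
    return FixtureResult(config=config, genome_physodic=genome_a,
                         genome_olivetoric=genome_b,
                         counts_physodic=counts["physodic"],
                         counts_olivetoric=counts["olivetoric"],
                         references=references, hexa_query=hexa_query,
                         hexb_query=hexb_query, domains=domains,
                         manifest=manifest)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_reads(genome: GenomeAnnotation, table: CountTable,
                   read_length: int = 150, seed: int = 0,
                   ) -> list[tuple[str, str]]:
    """Emit exactly ``raw_count`` error-free reads per counted gene, drawn
    uniformly from the gene body with random strand, plus
    ``library_size − Σcounts`` background reads from gene-free sequence.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for gid in sorted(table.counts):
        count = table.counts[gid]
        gene = genome.gene(gid)
        seq = genome.gene_sequence(gene)
        if read_length > len(seq):
            raise ReadLengthError(
                f"read length {read_length} > gene {gid} length {len(seq)}")
        starts = rng.integers(0, len(seq) - read_length + 1, count)
        flips = rng.random(count) < 0.5
        for i, (s, flip) in enumerate(zip(starts, flips)):
            r = seq[s:s + read_length]
            reads.append((f"{gid}_r{i}", _revcomp(r) if flip else r))

    n_background = table.library_size - sum(table.counts.values())
    if n_background > 0:
        intervals = _genefree_intervals(genome, read_length)
        if not intervals:
            raise ChemotriError("no gene-free sequence for background reads")
        lengths = np.array([e - s - read_length + 1
                            for _, s, e in intervals], dtype=float)
        probs = lengths / lengths.sum()
        choice = rng.choice(len(intervals), n_background, p=probs)
        offsets = rng.random(n_background)
        flips = rng.random(n_background) < 0.5
        for i, (ci, off, flip) in enumerate(zip(choice, offsets, flips)):
            contig_id, s, e = intervals[ci]
            start = s + int(off * (e - s - read_length + 1))
            r = genome.contigs[contig_id][start:start + read_length]
            reads.append((f"bg_r{i}", _revcomp(r) if flip else r))
    return reads


def _genefree_intervals(genome: GenomeAnnotation, min_len: int,
                        ) -> list[tuple[str, int, int]]:
    """0-based half-open gene-free intervals of at least ``min_len`` bp."""
    out = []
    for contig_id in sorted(genome.contigs):
        length = len(genome.contigs[contig_id])
        spans = sorted((g.start - 1, g.end)
                       for g in genome.genes if g.contig_id == contig_id)
        pos = 0
        for s, e in spans:
            if s - pos >= min_len:
                out.append((contig_id, pos, s))
            pos = max(pos, e)
        if length - pos >= min_len:
            out.append((contig_id, pos, length))
    return out


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# On-disk fixture layout
# ---------------------------------------------------------------------------


def write_fixture(result: FixtureResult, outdir: str | Path,
                  with_reads: bool = False) -> None:
    """Write the fixture as FASTA/GFF3/TSV/JSON (optionally FASTQ) files."""
    outdir = Path(outdir)
    for chem in ("physodic", "olivetoric"):
        d = outdir / chem
        d.mkdir(parents=True, exist_ok=True)
        genome = result.genome(chem)
        with open(d / "contigs.fasta", "w") as fh:
            for cid in sorted(genome.contigs):
                fh.write(f">{cid}\n{genome.contigs[cid]}\n")
        with open(d / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(genome.genes,
                            key=lambda g: (g.contig_id, g.start)):
                fh.write(f"{g.contig_id}\tchemotri\tgene\t{g.start}\t"
                         f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id};"
                         f"product={g.product_label}\n")
        write_cluster_table(genome.clusters, d / "clusters.tsv")
        with open(d / "domains.tsv", "w") as fh:
            fh.write("cluster_id\tgene_id\tdomains\n")
            for c in sorted(genome.clusters, key=lambda c: c.cluster_id):
                if c.cluster_id in result.domains:
                    fh.write(f"{c.cluster_id}\t{c.core_gene_ids[0]}\t"
                             f"{result.domains[c.cluster_id]}\n")
        with open(d / "counts.tsv", "w") as fh:
            fh.write("gene_id\traw_count\n")
            for gid in sorted(result.counts(chem).counts):
                fh.write(f"{gid}\t{result.counts(chem).counts[gid]}\n")
        if with_reads:
            reads = simulate_reads(genome, result.counts(chem),
                                   read_length=result.config.read_length,
                                   seed=result.config.seed)
            write_fastq(reads, d / "reads.fastq")
    with open(outdir / "references.fasta", "w") as fh:
        for r in result.references:
            fh.write(f">{r.reference_id} group={r.group}\n{r.sequence}\n")
    with open(outdir / "hex_queries.fasta", "w") as fh:
        fh.write(f">hexA_query\n{result.hexa_query}\n")
        fh.write(f">hexB_query\n{result.hexb_query}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
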