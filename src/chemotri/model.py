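"""Domain types and file IO for annotated genomes and their gene clusters.

Conventions
-----------
Coordinates are 1-based and inclusive at both ends (GFF3 convention)
everywhere in the package; inputs that look 0-based (a start of 0) are
rejected at parse time, never silently shifted.  Gene sequences are stored in
transcript orientation: for a ``-`` strand gene the stored sequence is the
reverse complement of the contig slice.

The cluster table is a 5-column TSV interchange format::

    genome_id  cluster_id  region_label  core_type  genes

where ``genes`` is a comma-separated, coordinate-ordered list of gene ids and
core genes carry a leading ``*``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ChemotriError", "CoordinateError", "DuplicateGeneIdError",
    "UnknownGeneError", "GeneRecord", "ClusterRecord", "GenomeAnnotation",
    "CountTable", "CORE_TYPES", "canonical_product", "read_genome",
    "read_cluster_table", "write_cluster_table", "write_report",
    "read_report",
]


class ChemotriError(Exception):
    """Base class for package errors."""


class CoordinateError(ChemotriError):
    """Gene coordinates violate the 1-based inclusive convention or bounds."""


class DuplicateGeneIdError(ChemotriError):
    """Two gene features share the same ID."""


class UnknownGeneError(ChemotriError):
    """A cluster table references a gene id absent from the annotation."""


#: Closed vocabulary of cluster core types (backbone enzyme classes).
CORE_TYPES = frozenset({
    "NR-PKS", "R-PKS", "T3-PKS", "NRPS", "NRPS-like", "hybrid", "terpene",
    "indole",
})

#: Product labels the rule engine distinguishes; everything else is
#: "unidentified".  Matching is case-insensitive on free-text annotations.
_LABEL_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("NR-PKS", ("nr-pks", "nrpks", "nr pks", "non-reducing pks")),
    ("R-PKS", ("r-pks", "red-pks", "rpks", "reducing pks")),
    ("CytP450", ("cytp450", "p450", "cytochrome")),
    ("OMT", ("o-methyltransferase", "omt", "o-mt")),
    ("monooxygenase", ("monooxygenase",)),
    ("transporter", ("transporter",)),
    ("FAS-A", ("fas-a", "hexa", "fas alpha")),
    ("FAS-B", ("fas-b", "hexb", "fas beta")),
)


def canonical_product(label: str) -> str:
    """Map a free-text product annotation to the closed rule vocabulary.

    Unknown labels map to ``"unidentified"``.  "PKS" alone (without reducing /
    non-reducing qualification) also maps to unidentified: the rule engine
    takes PKS category from the domain architecture, not the text label.
    """
    low = label.strip().lower()
    for canon, needles in _LABEL_RULES:
        if any(n in low for n in needles):
            return canon
    return "unidentified"


@dataclass(frozen=True)
class GeneRecord:
    """A gene model on a contig (1-based inclusive coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product_label: str = "unidentified"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(
                f"{self.gene_id}: start {self.start} < 1 — coordinates must "
                "be 1-based inclusive")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-"}:
            raise CoordinateError(
                f"{self.gene_id}: strand must be '+' or '-', got "
                f"{self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise CoordinateError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"span {self.length_bp}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical_label(self) -> str:
        return canonical_product(self.product_label)


@dataclass(frozen=True)
class ClusterRecord:
    """One biosynthetic gene cluster region with its genes and core gene(s)."""

    cluster_id: str
    genome_id: str
    region_label: str
    core_gene_ids: tuple[str, ...]
    core_type: str
    genes: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ChemotriError(f"{self.cluster_id}: cluster has no genes")
        if self.core_type not in CORE_TYPES:
            raise ChemotriError(
                f"{self.cluster_id}: unknown core type {self.core_type!r}")
        ids = {g.gene_id for g in self.genes}
        missing = set(self.core_gene_ids) - ids
        if missing:
            raise UnknownGeneError(
                f"{self.cluster_id}: core gene(s) {sorted(missing)} not in "
                "cluster")

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise UnknownGeneError(f"{self.cluster_id}: no gene {gene_id}")

    @property
    def core_genes(self) -> tuple[GeneRecord, ...]:
        return tuple(self.gene(i) for i in self.core_gene_ids)


@dataclass
class GenomeAnnotation:
    """An annotated genome: contigs, gene models and cluster regions."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord]
    clusters: list[ClusterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise DuplicateGeneIdError(
                    f"{self.genome_id}: duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise UnknownGeneError(
                    f"{g.gene_id}: contig {g.contig_id} not in genome")
            if g.end > len(self.contigs[g.contig_id]):
                raise CoordinateError(
                    f"{g.gene_id}: end {g.end} beyond contig "
                    f"{g.contig_id} length {len(self.contigs[g.contig_id])}")

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise UnknownGeneError(f"{self.genome_id}: no gene {gene_id}")

    def cluster(self, cluster_id: str) -> ClusterRecord:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise UnknownGeneError(f"{self.genome_id}: no cluster {cluster_id}")

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Gene sequence in transcript orientation (revcomp for ``-``)."""
        if gene.sequence is not None:
            return gene.sequence
        s = self.contigs[gene.contig_id][gene.start - 1:gene.end]
        return str(Seq(s).reverse_complement()) if gene.strand == "-" else s


@dataclass(frozen=True)
class CountTable:
    """Raw read counts per gene plus the total library size.

    ``library_size`` is the total number of reads in the sample (mapped or
    not), so it is always at least the sum of the per-gene counts.
    ``background`` and ``discarded`` (reads matching no gene / reads with
    tied best placements) are bookkeeping from the counting stage; when set,
    ``sum(counts) + background + discarded == library_size``.
    """

    counts: dict[str, int]
    library_size: int
    background: int = 0
    discarded: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ChemotriError("negative raw count")
        if self.library_size < sum(self.counts.values()):
            raise ChemotriError(
                f"library size {self.library_size} smaller than summed "
                f"counts {sum(self.counts.values())}")

    def get(self, gene_id: str) -> int:
        return self.counts.get(gene_id, 0)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _extract_sequences(contigs: dict[str, str],
                       genes: list[GeneRecord]) -> list[GeneRecord]:
    out = []
    for g in genes:
        s = contigs[g.contig_id][g.start - 1:g.end]
        if g.strand == "-":
            s = str(Seq(s).reverse_complement())
        out.append(replace(g, sequence=s))
    return out


def read_genome(fasta_path: str | Path, gff3_path: str | Path,
                cluster_table_path: str | Path | None = None,
                genome_id: str | None = None) -> GenomeAnnotation:
    """Load a genome from FASTA contigs, GFF3 gene models and a cluster TSV.

    Gene features are GFF3 ``gene`` records with an ``ID`` attribute and an
    optional ``product`` attribute.  Gene sequences are extracted from the
    contigs honouring strand.  Raises :class:`CoordinateError`,
    :class:`DuplicateGeneIdError` or :class:`UnknownGeneError` on invalid
    input and :class:`FileNotFoundError` on missing files.
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    for p in (fasta_path, gff3_path):
        if not p.exists():
            raise FileNotFoundError(p)
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(fasta_path), "fasta")}

    db = gffutils.create_db(gff3_path.read_text(), dbfn=":memory:",
                            from_string=True, merge_strategy="error",
                            keep_order=True)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise DuplicateGeneIdError(f"duplicate gene id {gid}")
        seen.add(gid)
        product = feat.attributes.get("product", ["unidentified"])[0]
        genes.append(GeneRecord(gene_id=gid, contig_id=feat.seqid,
                                start=feat.start, end=feat.end,
                                strand=feat.strand, product_label=product))
    genes = _extract_sequences(contigs, genes)

    gid = genome_id or fasta_path.stem
    annotation = GenomeAnnotation(genome_id=gid, contigs=contigs, genes=genes)
    if cluster_table_path is not None:
        annotation.clusters = read_cluster_table(cluster_table_path,
                                                 annotation)
    return annotation


def read_cluster_table(path: str | Path,
                       annotation: GenomeAnnotation) -> list[ClusterRecord]:
    """Read the 5-column cluster TSV against an existing annotation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters = []
    for row in df.itertuples(index=False):
        gene_ids = [g.strip() for g in row.genes.split(",")]
        cores = tuple(g[1:] for g in gene_ids if g.startswith("*"))
        plain = [g.lstrip("*") for g in gene_ids]
        genes = tuple(annotation.gene(g) for g in plain)
        clusters.append(ClusterRecord(
            cluster_id=row.cluster_id, genome_id=row.genome_id,
            region_label=row.region_label, core_gene_ids=cores,
            core_type=row.core_type, genes=genes))
    return clusters


# ---------------------------------------------------------------------------
# Writers (deterministic TSV reports)
# ---------------------------------------------------------------------------

_CLUSTER_COLUMNS = ["genome_id", "cluster_id", "region_label", "core_type",
                    "genes"]


def write_cluster_table(clusters: Iterable[ClusterRecord],
                        path: str | Path) -> None:
    rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        genes = ",".join(("*" if g.gene_id in c.core_gene_ids else "")
                         + g.gene_id
                         for g in sorted(c.genes, key=lambda g: g.start))
        rows.append((c.genome_id, c.cluster_id, c.region_label, c.core_type,
                     genes))
    pd.DataFrame(rows, columns=_CLUSTER_COLUMNS).to_csv(path, sep="\t",
                                                        index=False)


def write_report(df: pd.DataFrame, path: str | Path,
                 sort_by: Sequence[str] | None = None) -> None:
    """Write a tabular report as TSV with deterministic row/column order.

    Rows are sorted by ``sort_by`` (default: any of cluster_id/gene_id that
    are present, in that order).
    """
    if sort_by is None:
        sort_by = [c for c in ("cluster_id", "gene_id") if c in df.columns]
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
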