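"""Transcript quantification: read-to-gene counting and RPKM normalisation.

RPKM (reads per kilobase of gene per million library reads) is

    rpkm = raw_count / (library_size / 10^6) / (length_bp / 1000)

with ``library_size`` the *total* number of reads in the sample, mapped or
not.  Published expression tables print RPKM but never the library size; the
library size is therefore recovered from printed (raw count, length, RPKM)
rows by least squares (:func:`calibrate_library_size`).

Read counting replaces a spliced aligner with exact-seed matching plus
edit-distance verification, which is the appropriate instrument for the
error-free synthetic libraries this package quantifies: a read counts for
the gene holding its best placement at ≥ ``min_read_identity``; multi-mapped
reads with tied best placements are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import ChemotriError, ClusterRecord, CountTable, GenomeAnnotation

__all__ = [
    "ExpressionRecord", "CalibrationError", "rpkm", "calibrate_library_size",
    "map_and_count", "rank_activity", "expression_table", "reads_from_fastq",
]

_SEED_K = 31


class CalibrationError(ChemotriError):
    """Library-size calibration impossible (no row with positive RPKM)."""


@dataclass(frozen=True)
class ExpressionRecord:
    """Raw and RPKM-normalised expression of one gene."""

    gene_id: str
    raw_count: int
    length_bp: int
    library_size: int
    rpkm: float

    def __post_init__(self) -> None:
        if self.raw_count < 0 or self.length_bp <= 0:
            raise ChemotriError(f"{self.gene_id}: invalid count/length")
        expected = rpkm(self.raw_count, self.library_size, self.length_bp)
        if expected and abs(self.rpkm - expected) > 1e-9 * expected:
            raise ChemotriError(
                f"{self.gene_id}: rpkm {self.rpkm} inconsistent with "
                f"formula value {expected}")


def rpkm(raw_count: int, library_size: int, length_bp: int) -> float:
    """Reads per kilobase per million library reads."""
    if library_size <= 0 or length_bp <= 0:
        raise ChemotriError("library_size and length_bp must be positive")
    return raw_count / (library_size / 1e6) / (length_bp / 1e3)


def calibrate_library_size(
        rows: Iterable[tuple[int, int, float]],
        return_details: bool = False):
    """Estimate the (unprinted) library size from printed RPKM rows.

    ``rows`` are ``(raw_count, length_bp, printed_rpkm)``; rows with zero or
    missing RPKM are ignored.  Inverting the RPKM identity gives
    ``rpkm_i = x_i / L`` with ``x_i = raw_i * 10^9 / length_i``; the least
    squares estimate over all usable rows is ``L = Σx_i² / Σx_i·rpkm_i``.
    A single row reduces to exact inversion.  With ``return_details`` the
    per-row residuals (printed − refitted RPKM) are also returned.
    """
    usable = [(r, l, p) for r, l, p in rows if p and p > 0]
    if not usable:
        raise CalibrationError("no row with positive printed RPKM")
    x = np.array([r * 1e9 / l for r, l, _ in usable])
    p = np.array([v for *_, v in usable])
    lib = int(round((x @ x) / (x @ p)))
    if not return_details:
        return lib
    residuals = p - x / lib
    return lib, residuals


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------


def reads_from_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fastq")]


def _seed_index(genome: GenomeAnnotation) -> dict[str, set[str]]:
    """k-mer index over both strands of every gene sequence."""
    index: dict[str, set[str]] = {}
    for g in genome.genes:
        seq = genome.gene_sequence(g)
        for s in (seq, str(Seq(seq).reverse_complement())):
            for i in range(0, len(s) - _SEED_K + 1):
                index.setdefault(s[i:i + _SEED_K], set()).add(g.gene_id)
    return index


def map_and_count(reads, genome: GenomeAnnotation,
                  min_read_identity: float = 0.95) -> CountTable:
    """Count reads per gene by best placement.

    ``reads`` is an iterable of ``(read_id, sequence)`` or a FASTQ path.  A
    read counts for gene *g* iff its best placement (fewest edits, either
    strand, infix alignment) lies in *g* at identity ≥ the threshold; reads
    whose best placement is tied between distinct genes are discarded, and
    reads matching no gene count only toward the library size.  Conservation:
    ``sum(counts) + background + discarded == library_size``.
    """
    if isinstance(reads, (str, Path)):
        reads = reads_from_fastq(reads)
    reads = list(reads)
    if not reads:
        return CountTable(counts={}, library_size=0)

    index = _seed_index(genome)
    seqs = {g.gene_id: genome.gene_sequence(g) for g in genome.genes}
    rcs = {gid: str(Seq(s).reverse_complement()) for gid, s in seqs.items()}

    counts: dict[str, int] = {}
    background = discarded = 0
    for _rid, seq in reads:
        n = len(seq)
        candidates: set[str] = set()
        positions = {0, max(0, (n - _SEED_K) // 2), max(0, n - _SEED_K)}
        for pos in positions:
            candidates |= index.get(seq[pos:pos + _SEED_K], set())
        max_edits = int(np.floor((1.0 - min_read_identity) * n))
        best: dict[str, int] = {}
        for gid in candidates:
            dists = []
            for target in (seqs[gid], rcs[gid]):
                r = edlib.align(seq, target, mode="HW", task="distance",
                                k=max_edits)
                if r["editDistance"] >= 0:
                    dists.append(r["editDistance"])
            if dists:
                best[gid] = min(dists)
        if not best:
            background += 1
            continue
        top = min(best.values())
        winners = [gid for gid, d in best.items() if d == top]
        if len(winners) > 1:
            discarded += 1
        else:
            counts[winners[0]] = counts.get(winners[0], 0) + 1
    return CountTable(counts=counts, library_size=len(reads),
                      background=background, discarded=discarded)


# ---------------------------------------------------------------------------
# Expression tables and activity ranking
# ---------------------------------------------------------------------------


def expression_table(table: CountTable,
                     genes: Iterable[tuple[str, int]],
                     ) -> list[ExpressionRecord]:
    """Build per-gene expression records from a count table.

    ``genes`` are ``(gene_id, length_bp)``; genes absent from the count
    table get zero counts.
    """
    records = []
    for gid, length in genes:
        raw = table.get(gid)
        records.append(ExpressionRecord(
            gene_id=gid, raw_count=raw, length_bp=length,
            library_size=table.library_size,
            rpkm=rpkm(raw, table.library_size, length)
            if table.library_size > 0 else 0.0))
    return records


def rank_activity(cluster: ClusterRecord | Sequence[str],
                  records: Iterable[ExpressionRecord] |
                  Mapping[str, ExpressionRecord],
                  activity_factor: float = 10.0) -> pd.DataFrame:
    """Rank a cluster's genes by RPKM and flag transcriptionally active ones.

    Genes are sorted by RPKM descending (ties by gene id); a gene is flagged
    active when its RPKM is positive and at least ``activity_factor`` times
    the within-cluster median RPKM.  The rank order is threshold-free; the
    flag depends on ``activity_factor``.
    """
    if isinstance(cluster, ClusterRecord):
        gene_ids = [g.gene_id for g in cluster.genes]
    else:
        gene_ids = list(cluster)
    if not isinstance(records, Mapping):
        records = {r.gene_id: r for r in records}
    rows = []
    for gid in gene_ids:
        r = records.get(gid)
        rows.append((gid, r.raw_count if r else 0,
                     r.length_bp if r else 0, r.rpkm if r else 0.0))
    df = pd.DataFrame(rows, columns=["gene_id", "raw_count", "length_bp",
                                     "rpkm"])
    df = df.sort_values(["rpkm", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    threshold = activity_factor * float(df["rpkm"].median())
    df["active"] = (df["rpkm"] > 0) & (df["rpkm"] >= threshold)
    return df
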