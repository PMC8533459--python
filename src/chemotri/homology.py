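"""Cross-genome cluster homology: alignment scoring, reciprocal best hits,
shared/specific partition with raw-read absence evidence, synteny tables.

Orthology between the two chemotypes is called at the level of cluster core
genes with the classical reciprocal-best-hit (RBH) criterion: clusters A and
B are homologous iff B's core is A's core's unique best-scoring match and
vice versa, at a minimum identity.  RBH rather than one-way best hit is used
precisely to defeat within-genome paralogy.

Alignment scoring is global (Needleman-Wunsch with affine gaps): match +1,
mismatch −1, −2 for the first position of a gap and −1 for each further
position.  Pairs sharing essentially no k-mers are skipped as no-hits
(seeding, as any database search tool does); this cannot change best hits
between full-length homologs, which share most of their k-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .model import ClusterRecord, GenomeAnnotation, ChemotriError
from .pks import kmer_set

log = logging.getLogger(__name__)

__all__ = [
    "CoreGene", "SimilarityScore", "HomologyMatch", "ChemotypeComparison",
    "score_pair", "reciprocal_best_hit", "partition_chemotypes",
    "synteny_table", "core_genes_of",
]

#: Alignment scoring used everywhere a similarity is computed.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1

#: Pairs whose k-mer Jaccard distance exceeds this are treated as no-hit.
SEED_MAX_DISTANCE = 0.9


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_ALIGNER = _aligner()


@dataclass(frozen=True)
class CoreGene:
    """A cluster core gene entered into the RBH comparison."""

    cluster_id: str
    gene_id: str
    sequence: str


@dataclass(frozen=True)
class SimilarityScore:
    query_id: str
    subject_id: str
    identity: float   # fraction of identical alignment columns, in [0, 1]
    aligned_length: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ChemotriError(f"identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class HomologyMatch:
    cluster_a: str
    cluster_b: str
    core_similarity: SimilarityScore
    reciprocal: bool = True


@dataclass
class ChemotypeComparison:
    """Partition of both genomes' clusters into shared / specific / ambiguous.

    ``specific_a``/``specific_b`` hold ``(cluster_id, absence_evidence)``
    where absence evidence is the maximum RPKM-normalised coverage of the
    cluster's core gene(s) in the *other* chemotype's raw reads (``None``
    when no reads were supplied).  A cluster is called specific only with
    zero cross-coverage; nonzero cross-coverage flags it ambiguous.
    """

    shared_pairs: list[HomologyMatch]
    specific_a: list[tuple[str, float | None]]
    specific_b: list[tuple[str, float | None]]
    ambiguous_a: list[tuple[str, float]]
    ambiguous_b: list[tuple[str, float]]


def score_pair(seq_a: str, seq_b: str, query_id: str = "a",
               subject_id: str = "b") -> SimilarityScore:
    """Global alignment of two nucleotide sequences under the stated scoring.

    Identity is the fraction of identical columns over all alignment columns
    (gap columns included).  Symmetric: ``score_pair(a, b)`` and
    ``score_pair(b, a)`` have equal score and identity.
    """
    if not seq_a or not seq_b:
        raise ChemotriError("cannot align an empty sequence")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = aln.length
    return SimilarityScore(query_id=query_id, subject_id=subject_id,
                           identity=counts.identities / length,
                           aligned_length=length, score=aln.score)


def core_genes_of(genome: GenomeAnnotation) -> list[CoreGene]:
    """All cluster core genes of a genome, as RBH input."""
    cores = []
    for c in genome.clusters:
        for g in c.core_genes:
            cores.append(CoreGene(c.cluster_id, g.gene_id,
                                  genome.gene_sequence(g)))
    return cores


def reciprocal_best_hit(cores_a: Sequence[CoreGene],
                        cores_b: Sequence[CoreGene],
                        min_identity: float = 0.7,
                        seed_max_distance: float | None = SEED_MAX_DISTANCE,
                        ) -> list[HomologyMatch]:
    """Reciprocal-best-hit matching between two sets of core genes.

    A pair is reported iff each member is the other's unique best hit (best
    alignment score; ties broken by higher identity, then lexicographic
    gene id) and the pair's identity is at least ``min_identity``.  Each
    cluster appears in at most one reported pair (best-scoring kept).
    Invariant under swapping the two sides (pairs transpose).
    """
    if not cores_a or not cores_b:
        return []
    sets_a = [kmer_set(c.sequence) for c in cores_a]
    sets_b = [kmer_set(c.sequence) for c in cores_b]

    # score[i][j]: alignment score or None for no-hit (failed seeding)
    scores: list[list[float | None]] = [[None] * len(cores_b)
                                        for _ in cores_a]
    sims: dict[tuple[int, int], SimilarityScore] = {}
    for i, ca in enumerate(cores_a):
        for j, cb in enumerate(cores_b):
            if seed_max_distance is not None:
                union = len(sets_a[i] | sets_b[j])
                jac = (len(sets_a[i] & sets_b[j]) / union) if union else 0.0
                if 1.0 - jac > seed_max_distance:
                    continue
            scores[i][j] = _ALIGNER.score(ca.sequence, cb.sequence)

    def _sim(i: int, j: int) -> SimilarityScore:
        if (i, j) not in sims:
            sims[(i, j)] = score_pair(cores_a[i].sequence,
                                      cores_b[j].sequence,
                                      cores_a[i].gene_id, cores_b[j].gene_id)
        return sims[(i, j)]

    def _best(row: Iterable[tuple[int, float | None]],
              identity_of, name_of) -> int | None:
        cands = [(j, s) for j, s in row if s is not None]
        if not cands:
            return None
        top = max(s for _, s in cands)
        tied = [j for j, s in cands if s == top]
        if len(tied) > 1:
            tied.sort(key=lambda j: (-identity_of(j), name_of(j)))
        return tied[0]

    best_a = [_best(enumerate(scores[i]),
                    lambda j, i=i: _sim(i, j).identity,
                    lambda j: cores_b[j].gene_id)
              for i in range(len(cores_a))]
    best_b = [_best(((i, scores[i][j]) for i in range(len(cores_a))),
                    lambda i, j=j: _sim(i, j).identity,
                    lambda i: cores_a[i].gene_id)
              for j in range(len(cores_b))]

    mutual = [(i, j) for i, j in enumerate(best_a)
              if j is not None and best_b[j] == i]

    matches: list[HomologyMatch] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    # deterministic greedy: best score first, then ids
    mutual.sort(key=lambda ij: (-scores[ij[0]][ij[1]],
                                cores_a[ij[0]].gene_id,
                                cores_b[ij[1]].gene_id))
    for i, j in mutual:
        ca, cb = cores_a[i].cluster_id, cores_b[j].cluster_id
        if ca in used_a or cb in used_b:
            continue
        sim = _sim(i, j)
        if sim.identity < min_identity:
            log.info("RBH pair %s/%s rejected: identity %.3f < %.3f",
                     ca, cb, sim.identity, min_identity)
            continue
        used_a.add(ca)
        used_b.add(cb)
        matches.append(HomologyMatch(ca, cb, sim))
    matches.sort(key=lambda m: (m.cluster_a, m.cluster_b))
    return matches


def partition_chemotypes(genome_a: GenomeAnnotation,
                         genome_b: GenomeAnnotation,
                         matches: Sequence[HomologyMatch],
                         reads_a=None, reads_b=None,
                         min_read_identity: float = 0.95,
                         ) -> ChemotypeComparison:
    """Partition clusters into shared pairs and chemotype-specific sets.

    For every unmatched cluster the *other* chemotype's reads (``reads_b``
    for genome A's clusters and vice versa; iterables of ``(read_id, seq)``)
    are mapped onto that genome's genes and the cluster is called specific
    only when its core genes attract zero coverage; otherwise it is flagged
    ambiguous with its normalised cross-coverage.
    """
    from .expression import map_and_count, rpkm  # late import, avoids cycle

    matched_a = {m.cluster_a for m in matches}
    matched_b = {m.cluster_b for m in matches}

    def _one_side(genome: GenomeAnnotation, matched: set[str], cross_reads):
        table = None
        if cross_reads is not None:
            table = map_and_count(cross_reads, genome,
                                  min_read_identity=min_read_identity)
        specific, ambiguous = [], []
        for c in genome.clusters:
            if c.cluster_id in matched:
                continue
            if table is None or table.library_size == 0:
                specific.append((c.cluster_id, None))
                continue
            evidence = max(
                rpkm(table.get(g.gene_id), table.library_size, g.length_bp)
                for g in c.core_genes)
            if evidence == 0.0:
                specific.append((c.cluster_id, 0.0))
            else:
                log.warning("cluster %s unmatched but has cross-coverage "
                            "%.3g — flagged ambiguous", c.cluster_id,
                            evidence)
                ambiguous.append((c.cluster_id, evidence))
        return specific, ambiguous

    specific_a, ambiguous_a = _one_side(genome_a, matched_a, reads_b)
    specific_b, ambiguous_b = _one_side(genome_b, matched_b, reads_a)
    return ChemotypeComparison(shared_pairs=list(matches),
                               specific_a=specific_a, specific_b=specific_b,
                               ambiguous_a=ambiguous_a,
                               ambiguous_b=ambiguous_b)


def synteny_table(cluster_a: ClusterRecord, cluster_b: ClusterRecord,
                  min_identity_pct: float = 90.0, min_length: int = 50,
                  ) -> pd.DataFrame:
    """Per-gene-pair identity table between two homologous clusters.

    Clusters are oriented so their (first) core genes point the same way; if
    not, cluster B's genes are reverse-complemented (recorded in
    ``df.attrs["flipped_b"]``).  All gene pairs are aligned and rows kept
    where identity ≥ ``min_identity_pct`` and aligned length ≥
    ``min_length`` — a tabular stand-in for a synteny figure.
    """
    def _seqs(cluster: ClusterRecord) -> list[tuple[str, str]]:
        out = []
        for g in sorted(cluster.genes, key=lambda g: g.start):
            if g.sequence is None:
                raise ChemotriError(
                    f"{g.gene_id}: gene sequence required for synteny")
            out.append((g.gene_id, g.sequence))
        return out

    flip = (cluster_a.core_genes[0].strand != cluster_b.core_genes[0].strand)
    seqs_a, seqs_b = _seqs(cluster_a), _seqs(cluster_b)
    if flip:
        from Bio.Seq import Seq
        seqs_b = [(gid, str(Seq(s).reverse_complement()))
                  for gid, s in reversed(seqs_b)]

    rows = []
    for ga, sa in seqs_a:
        ka = kmer_set(sa)
        for gb, sb in seqs_b:
            kb = kmer_set(sb)
            union = len(ka | kb)
            if not union or 1.0 - len(ka & kb) / union > SEED_MAX_DISTANCE:
                continue
            sim = score_pair(sa, sb, ga, gb)
            if (sim.identity * 100.0 >= min_identity_pct
                    and sim.aligned_length >= min_length):
                rows.append((ga, gb, round(sim.identity * 100.0, 2),
                             sim.aligned_length))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity_pct",
                                     "aligned_length"])
    df.attrs["flipped_b"] = flip
    return df
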