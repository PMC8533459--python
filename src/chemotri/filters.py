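"""Candidate triage for the depside/depsidone cluster, the atranorin-cluster
rule, and detection of the divergently transcribed HexA/HexB FAS pair.

The depside/depsidone candidate filter applies four hard criteria to every
NR-PKS-bearing cluster: (1) homologous and present in both chemotypes,
(2) the cluster contains an NR-PKS, (3) the cluster contains a CytP450 (the
enzyme adding the depsidone ether bond), and (4) the PKS carries two ACP
domains (the two-ring depside signature).  Additional exclusion arguments —
a cMT domain, a missing TE, an O-methyltransferase in the cluster, an
adjacent divergently transcribed R-PKS, a phylogenetic group other than I
(orcinol-compound PKSs) — are recorded as negative evidence, not as extra
hard criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .homology import ChemotypeComparison, score_pair
from .model import ChemotriError, ClusterRecord, GeneRecord, GenomeAnnotation
from .pks import DomainArchitecture, PKSClassification, kmer_set

log = logging.getLogger(__name__)

__all__ = [
    "AmbiguousClusterError", "ClassifiedCluster", "CandidateVerdict",
    "FASLocus", "PairLocation", "evaluate_candidates",
    "detect_atranorin_cluster", "find_divergent_pair", "locate_pair",
]

#: Maximum intergenic distance (bp) for two genes to count as "adjacent".
MAX_ADJACENT_BP = 5000


class AmbiguousClusterError(ChemotriError):
    """More than one cluster satisfies a rule meant to be unique."""


@dataclass(frozen=True)
class ClassifiedCluster:
    """A cluster together with its core-PKS architecture and classification
    (architecture/classification are None for clusters without a PKS)."""

    cluster: ClusterRecord
    architecture: DomainArchitecture | None
    classification: PKSClassification | None


@dataclass(frozen=True)
class CandidateVerdict:
    cluster_id: str
    passed: bool
    criteria: dict[str, bool]
    negative_evidence: frozenset[str]
    narrative: str


@dataclass(frozen=True)
class FASLocus:
    """An adjacent, divergently transcribed gene pair (FAS alpha/beta)."""

    gene_a_id: str
    gene_b_id: str
    orientation: str          # divergent | convergent | tandem
    intergenic_bp: int

    def __post_init__(self) -> None:
        if self.intergenic_bp < 0:
            raise ChemotriError("overlapping genes cannot form a FAS locus")


@dataclass(frozen=True)
class PairLocation:
    """Where two query hits landed relative to each other."""

    gene_a: GeneRecord
    gene_b: GeneRecord
    same_contig: bool
    adjacent: bool
    orientation: str | None   # None when on different contigs
    intergenic_bp: int | None


def _cluster_labels(cluster: ClusterRecord) -> set[str]:
    return {g.canonical_label for g in cluster.genes}


def _has_divergent_rpks_neighbor(cluster: ClusterRecord,
                                 core_id: str) -> bool:
    """True if an R-PKS gene sits right next to the core NR-PKS, the two
    being divergently transcribed (− gene before + gene)."""
    genes = sorted(cluster.genes, key=lambda g: g.start)
    idx = next((i for i, g in enumerate(genes) if g.gene_id == core_id), None)
    if idx is None:
        return False
    for j in (idx - 1, idx + 1):
        if not 0 <= j < len(genes):
            continue
        other = genes[j]
        if other.canonical_label != "R-PKS":
            continue
        first, second = (genes[j], genes[idx]) if j < idx else (genes[idx],
                                                                genes[j])
        if first.strand == "-" and second.strand == "+":
            return True
    return False


def evaluate_candidates(classified: Sequence[ClassifiedCluster],
                        comparison: ChemotypeComparison,
                        ) -> list[CandidateVerdict]:
    """Apply the four-criterion filter to every NR-PKS-bearing cluster.

    Returns one verdict per cluster whose PKS classifies as non-reducing;
    clusters without any PKS are skipped with a logged notice.  ``passed``
    is true iff all four criteria hold; negative evidence is recorded for
    failing clusters and as warnings on passing ones.
    """
    shared = ({m.cluster_a for m in comparison.shared_pairs}
              | {m.cluster_b for m in comparison.shared_pairs})
    verdicts = []
    for cc in classified:
        if cc.architecture is None or cc.classification is None:
            log.info("cluster %s has no PKS — skipped by candidate filter",
                     cc.cluster.cluster_id)
            continue
        if cc.classification.category != "NR-PKS":
            continue
        cluster, arch = cc.cluster, cc.architecture
        labels = _cluster_labels(cluster)
        criteria = {
            "in_both_chemotypes": cluster.cluster_id in shared,
            "has_NR_PKS": cc.classification.category == "NR-PKS",
            "has_CytP450": "CytP450" in labels,
            "two_ACPs": arch.acp_count >= 2,
        }
        evidence = set()
        if arch.has_cMT:
            evidence.add("has_cMT")
        if not arch.has_TE:
            evidence.add("lacks_TE")
        if "OMT" in labels:
            evidence.add("has_OMT_in_cluster")
        if cc.classification.group != "I":
            evidence.add("group_mismatch")
        if any(_has_divergent_rpks_neighbor(cluster, core)
               for core in cluster.core_gene_ids):
            evidence.add("divergent_R_PKS_neighbor")
        passed = all(criteria.values())
        if passed:
            failed = []
        else:
            failed = sorted(k for k, v in criteria.items() if not v)
        narrative = ("meets all four criteria" if passed else
                     "fails " + ", ".join(failed))
        if evidence:
            narrative += " [evidence: " + ", ".join(sorted(evidence)) + "]"
        verdicts.append(CandidateVerdict(
            cluster_id=cluster.cluster_id, passed=passed, criteria=criteria,
            negative_evidence=frozenset(evidence), narrative=narrative))
    return verdicts


def detect_atranorin_cluster(classified: Sequence[ClassifiedCluster],
                             comparison: ChemotypeComparison | None = None,
                             ) -> str | None:
    """Find the putative atranorin cluster, or None.

    Rule: the PKS carries SAT, KS, AT, PT, ACP and cMT (TE optional — the
    canonical atranorin PKS architecture ends in TE but the domain call may
    miss it), places in group IX, and the cluster contains a CytP450, an
    OMT and a transporter (atr1-like gene content).  More than one match
    raises :class:`AmbiguousClusterError`.
    """
    shared = None
    if comparison is not None:
        shared = ({m.cluster_a for m in comparison.shared_pairs}
                  | {m.cluster_b for m in comparison.shared_pairs})
    hits = []
    for cc in classified:
        if cc.architecture is None or cc.classification is None:
            continue
        if shared is not None and cc.cluster.cluster_id not in shared:
            continue
        arch, cls = cc.architecture, cc.classification
        if not {"SAT", "KS", "AT", "PT", "ACP", "cMT"} <= set(arch.tokens):
            continue
        if cls.group != "IX":
            continue
        labels = _cluster_labels(cc.cluster)
        if {"CytP450", "OMT", "transporter"} <= labels:
            hits.append(cc.cluster.cluster_id)
    if len(hits) > 1:
        raise AmbiguousClusterError(
            f"multiple atranorin-like clusters: {sorted(hits)}")
    return hits[0] if hits else None


def _best_gene_hit(genome: GenomeAnnotation, query: str,
                   min_identity: float) -> GeneRecord | None:
    qset = kmer_set(query)
    best, best_score = None, None
    for g in sorted(genome.genes, key=lambda g: g.gene_id):
        seq = genome.gene_sequence(g)
        gset = kmer_set(seq)
        union = len(qset | gset)
        if not union or 1.0 - len(qset & gset) / union > 0.9:
            continue
        sim = score_pair(query, seq)
        if sim.identity < min_identity:
            continue
        if best_score is None or sim.score > best_score:
            best, best_score = g, sim.score
    return best


def locate_pair(genome: GenomeAnnotation, query_a_seq: str,
                query_b_seq: str, min_identity: float = 0.7,
                max_intergenic_bp: int = MAX_ADJACENT_BP,
                ) -> PairLocation | None:
    """Locate the best gene hits of two queries and their relative geometry.

    Returns None when either query has no gene hit at ``min_identity``.
    Adjacency means: same contig, no intervening gene on either strand, and
    intergenic distance at most ``max_intergenic_bp``.
    """
    if not query_a_seq or not query_b_seq:
        raise ChemotriError("empty query sequence")
    hit_a = _best_gene_hit(genome, query_a_seq, min_identity)
    hit_b = _best_gene_hit(genome, query_b_seq, min_identity)
    if hit_a is None or hit_b is None or hit_a.gene_id == hit_b.gene_id:
        log.info("FAS query without a distinct gene hit at identity >= %.2f",
                 min_identity)
        return None
    if hit_a.contig_id != hit_b.contig_id:
        return PairLocation(hit_a, hit_b, same_contig=False, adjacent=False,
                            orientation=None, intergenic_bp=None)
    first, second = sorted((hit_a, hit_b), key=lambda g: g.start)
    contig_genes = sorted((g for g in genome.genes
                           if g.contig_id == hit_a.contig_id),
                          key=lambda g: g.start)
    i1 = contig_genes.index(first)
    i2 = contig_genes.index(second)
    intergenic = max(0, second.start - first.end - 1)
    if first.strand == second.strand:
        orientation = "tandem"
    elif first.strand == "-" and second.strand == "+":
        orientation = "divergent"
    else:
        orientation = "convergent"
    adjacent = (i2 == i1 + 1) and intergenic <= max_intergenic_bp
    return PairLocation(hit_a, hit_b, same_contig=True, adjacent=adjacent,
                        orientation=orientation, intergenic_bp=intergenic)


def find_divergent_pair(genome: GenomeAnnotation, query_a_seq: str,
                        query_b_seq: str, min_identity: float = 0.7,
                        max_intergenic_bp: int = MAX_ADJACENT_BP,
                        ) -> FASLocus | None:
    """Locate an adjacent, divergently transcribed homolog pair.

    The two queries (e.g. known HexA and HexB homologs) are matched to their
    best gene hits; a :class:`FASLocus` is returned iff the hits are
    adjacent and divergent.  Otherwise the geometry is logged and None
    returned.
    """
    loc = locate_pair(genome, query_a_seq, query_b_seq, min_identity,
                      max_intergenic_bp)
    if loc is None or not loc.same_contig:
        return None
    if not (loc.adjacent and loc.orientation == "divergent"):
        log.info("query pair found but %s%s — not a divergent locus",
                 loc.orientation,
                 "" if loc.adjacent else " and not adjacent")
        return None
    return FASLocus(gene_a_id=loc.gene_a.gene_id,
                    gene_b_id=loc.gene_b.gene_id,
                    orientation="divergent",
                    intergenic_bp=loc.intergenic_bp)
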