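"""Published reference tables for the *Pseudevernia furfuracea* chemotype study.

These constants describe the two sequenced chemotypes of the lichen-forming
fungus *P. furfuracea* — one producing the depside olivetoric acid, the other
the corresponding depsidone physodic acid.  They are the inputs that the
synthetic fixture generator mirrors and that the worked expression examples
use: the catalog of the eight NR-PKS clusters shared by both chemotypes (PKS
domain architectures, phylogenetic groups and companion genes), the clusters
found in only one chemotype, and the transcriptome read counts over the
ten-gene candidate depside/depsidone cluster and the HexA/HexB fatty-acid
synthase pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# NR-PKS cluster catalog (clusters shared by both chemotypes)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NRPKSClusterSpec:
    """One shared NR-PKS cluster: domain string, group placement, companions.

    ``domains`` keeps the mixed "-"/space separators as published; the parser
    accepts both.  ``companions`` are the identified non-core genes of the
    cluster; padding to ``total_genes`` is unidentified.
    """

    number: int
    domains: str
    group: str
    group_compound: str
    total_genes: int
    companions: tuple[str, ...]


NR_PKS_CATALOG: tuple[NRPKSClusterSpec, ...] = (
    NRPKSClusterSpec(1, "SAT-KS-AT-ACP cMT-TD", "VII",
                     "azaphilones, monascorubrin", 12,
                     ("regulatory gene",)),
    NRPKSClusterSpec(2, "SAT-KS-AT-PT-ACP", "V", "anthraquinones", 16,
                     ("metallo-beta-lactamase family protein", "halogenase")),
    NRPKSClusterSpec(3, "SAT-KS-AT-PT-ACP ACP-TE", "II", "melanins", 11,
                     ("dehydrogenase/reductase (KR)",)),
    NRPKSClusterSpec(4, "SAT-KS-AT-ACP ACP-TE", "I",
                     "zearalenone, orsellinic acid", 10,
                     ("CytP450", "monooxygenase")),
    NRPKSClusterSpec(5, "SAT-KS-AT-PT-ACP-TE", "I",
                     "zearalenone, orsellinic acid", 13,
                     ("O-methyltransferase", "CytP450",
                      "crotonyl-CoA reductase/alcohol dehydrogenase",
                      "red-PKS", "GATase_7")),
    # Cluster 6 is the putative atranorin cluster: its gene composition
    # includes a CytP450, an OMT and a transporter (atr1-like content).
    NRPKSClusterSpec(6, "SAT-KS-AT-PT-ACP cMT", "IX", "mitorubin, atranorin",
                     11,
                     ("alkyl hydroperoxide reductase", "CytP450",
                      "drug resistance transporter", "O-methyltransferase")),
    NRPKSClusterSpec(7, "SAT-KS-AT-PT-ACP-ACP-TE", "II", "melanins", 13,
                     ("serine/threonine protein kinase",
                      "drug resistance transporter",
                      "monooxygenase FAD-binding",
                      "short-chain dehydrogenase/reductase SDR",
                      "O-methyltransferase", "transcription regulator")),
    NRPKSClusterSpec(8, "SAT-KS-AT-PT-ACP-ACP-TE", "II", "melanins", 9,
                     ("drug resistance transporter", "O-methyltransferase",
                      "halogenase", "monooxygenase FAD-binding",
                      "adh_short (DH-KR)", "monooxygenase FAD-binding")),
)

#: Cluster number of the candidate depside/depsidone cluster (two ACPs +
#: CytP450; group I, orsellinic-acid-type PKSs).
CANDIDATE_CLUSTER_NUMBER = 4

#: Cluster number of the putative atranorin cluster (group IX, cMT-bearing).
ATRANORIN_CLUSTER_NUMBER = 6

# ---------------------------------------------------------------------------
# Shared / chemotype-specific cluster layout
# ---------------------------------------------------------------------------

#: Core types of the 51 clusters shared by both chemotypes, by cluster number.
#: Composition: 8 NR-PKS, 14 R-PKS, 1 T3-PKS, 7 hybrid, 14 NRPS/NRPS-like,
#: 5 terpene, 2 indole.
SHARED_CORE_TYPES: dict[int, str] = (
    {n: "NR-PKS" for n in range(1, 9)}
    | {n: "R-PKS" for n in range(9, 23)}
    | {23: "T3-PKS"}
    | {n: "hybrid" for n in range(24, 31)}
    | {n: "NRPS" for n in range(31, 38)}
    | {n: "NRPS-like" for n in range(38, 44)}
    | {n: "terpene" for n in range(44, 49)}
    | {49: "indole", 50: "indole", 51: "NRPS"}
)

#: Chemotype-specific clusters: number -> (chemotype, core_type).
SPECIFIC_CLUSTERS: dict[int, tuple[str, str]] = {
    52: ("physodic", "R-PKS"),
    53: ("physodic", "R-PKS"),
    54: ("physodic", "hybrid"),
    55: ("physodic", "R-PKS"),
    56: ("physodic", "terpene"),
    57: ("olivetoric", "terpene"),
}

#: antiSMASH-style region labels where published.
REGION_LABELS: dict[int, str] = {
    1: "Region 12.3", 2: "Region 18.1", 3: "Region 44.1", 4: "Region 33.1",
    5: "Region 2.2", 6: "Region 9.3", 9: "Region 10.1", 11: "Region 16.1",
    12: "Region 2.4", 15: "Region 9.2", 44: "Region 38.1", 45: "Region 33.2",
    46: "Region 2.3", 47: "Region 12.2", 48: "Region 60.1", 52: "Region 7.2",
    53: "Region 25.1", 54: "Region 60.2", 55: "Region 65.1",
    56: "Region 27.1", 57: "Region 10.1",
}

# ---------------------------------------------------------------------------
# Candidate-cluster and FAS expression (transcriptome read counts)
# ---------------------------------------------------------------------------

#: Gene order is gene1..gene10 of the candidate cluster.
CANDIDATE_GENE_LABELS: tuple[str, ...] = (
    "unidentified", "unidentified", "unidentified", "CytP450", "NR-PKS",
    "unidentified", "unidentified", "unidentified", "unidentified",
    "monooxygenase",
)

CANDIDATE_GENE_LENGTHS: tuple[int, ...] = (
    3822, 306, 2685, 2139, 6294, 2550, 3284, 2191, 492, 1851,
)

#: Raw transcriptome reads aligned per gene ("no hits" recorded as 0).
CANDIDATE_RAW_READS: dict[str, tuple[int, ...]] = {
    "physodic": (38, 0, 0, 8677, 111226, 13690, 1035, 936, 0, 46),
    "olivetoric": (0, 1, 19, 1222, 1265, 6304, 118, 205, 12, 19),
}

#: Published RPKM values per gene (None where no reads aligned / not reported).
CANDIDATE_RPKM: dict[str, tuple[float | None, ...]] = {
    "physodic": (0.0, None, None, 117.29, 511.0, 155.25, 9.11, 12.35, None,
                 0.71),
    "olivetoric": (None, 0.0, 0.0, 17.4, 6.33, 75.38, 1.125, 1.98, 0.73,
                   0.307),
}

#: HexA (FAS alpha subunit) and HexB (beta subunit) homologs: adjacent,
#: divergently transcribed, not linked to the candidate cluster.
FAS_GENE_LENGTHS: tuple[int, int] = (5619, 6285)
FAS_RAW_READS: dict[str, tuple[int, int]] = {
    "physodic": (3143, 1971),
    "olivetoric": (944, 911),
}
FAS_RPKM: dict[str, tuple[float, float]] = {
    "physodic": (16.17, 9.06),
    "olivetoric": (5.12, 4.42),
}


def expression_rows(chemotype: str) -> list[tuple[str, str, int, int, float | None]]:
    """Published expression table for one chemotype.

    Returns rows ``(gene, label, length_bp, raw_count, rpkm)`` for the ten
    candidate-cluster genes followed by FAS-A and FAS-B.
    """
    rows = []
    for i in range(10):
        rows.append((f"gene{i + 1}", CANDIDATE_GENE_LABELS[i],
                     CANDIDATE_GENE_LENGTHS[i],
                     CANDIDATE_RAW_READS[chemotype][i],
                     CANDIDATE_RPKM[chemotype][i]))
    for j, name in enumerate(("FAS-A", "FAS-B")):
        rows.append((name, name, FAS_GENE_LENGTHS[j],
                     FAS_RAW_READS[chemotype][j], FAS_RPKM[chemotype][j]))
    return rows
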