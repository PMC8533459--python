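"""PKS domain-architecture parsing and phylogenetic group placement.

Fungal iterative type I PKSs are classified from their domain string:
reducing PKSs (R-PKS) carry any of the KR/DH/ER reducing domains,
non-reducing PKSs (NR-PKS) lack them and carry at least KS, AT and ACP.
NR-PKSs are further placed into the established phylogenetic groups
(I, II, V, VII, IX here) by distance to labelled reference sequences — an
alignment-free k-mer Jaccard distance to the nearest reference stands in
for a full maximum-likelihood phylogeny, whose output the downstream filter
only consumes as a group label anyway.  A neighbor-joining tree over the
same distances is emitted for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .model import ChemotriError

__all__ = [
    "DOMAIN_VOCABULARY", "REDUCING_DOMAINS", "UnknownDomainError",
    "DomainArchitecture", "PKSClassification", "GroupReference",
    "parse_domain_string", "classify_category", "kmer_set", "kmer_distance",
    "assign_group", "nj_tree",
]

#: Recognised PKS domain tokens.  TD is a reductive release domain distinct
#: from TE; neither counts as a reducing (KR/DH/ER) domain.
DOMAIN_VOCABULARY = frozenset({
    "SAT", "KS", "AT", "PT", "ACP", "cMT", "TE", "TD", "KR", "DH", "ER",
    "MT",
})

REDUCING_DOMAINS = frozenset({"KR", "DH", "ER"})

PKS_GROUPS = ("I", "II", "V", "VII", "IX")


class UnknownDomainError(ChemotriError):
    """A domain string contained a token outside the vocabulary."""


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered PKS domain tokens with derived feature flags."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ChemotriError("empty domain architecture")
        bad = [t for t in self.tokens if t not in DOMAIN_VOCABULARY]
        if bad:
            raise UnknownDomainError(f"unknown domain token(s): {bad}")

    @property
    def acp_count(self) -> int:
        return sum(t == "ACP" for t in self.tokens)

    @property
    def has_cMT(self) -> bool:
        return "cMT" in self.tokens

    @property
    def has_PT(self) -> bool:
        return "PT" in self.tokens

    @property
    def has_TE(self) -> bool:
        return "TE" in self.tokens

    @property
    def has_SAT(self) -> bool:
        return "SAT" in self.tokens

    @property
    def has_reducing(self) -> bool:
        return any(t in REDUCING_DOMAINS for t in self.tokens)

    def __str__(self) -> str:
        return "-".join(self.tokens)


@dataclass(frozen=True)
class PKSClassification:
    """Category plus (for NR-PKSs) phylogenetic group placement."""

    category: str                      # NR-PKS | R-PKS | other
    group: str = "unknown"             # I | II | V | VII | IX | unknown
    nearest_reference_id: str | None = None
    distance: float | None = None

    def __post_init__(self) -> None:
        if self.group != "unknown" and self.category != "NR-PKS":
            raise ChemotriError(
                "group placement only defined for NR-PKSs")


@dataclass(frozen=True)
class GroupReference:
    """A labelled reference PKS sequence anchoring one phylogenetic group."""

    reference_id: str
    group: str
    sequence: str
    alphabet: str = "nucleotide"       # or "protein"


def parse_domain_string(text: str) -> DomainArchitecture:
    """Parse a domain string with "-" and/or whitespace separators.

    Published tables mix the two separators within one string
    (e.g. ``"SAT-KS-AT-ACP ACP-TE"``); both split token boundaries.
    Tokens are matched case-sensitively against the vocabulary.
    """
    if not text or not text.strip():
        raise ChemotriError("empty domain string")
    tokens = tuple(t for chunk in text.split() for t in chunk.split("-") if t)
    return DomainArchitecture(tokens=tokens)


def classify_category(arch: DomainArchitecture) -> str:
    """R-PKS iff any reducing domain; NR-PKS iff KS+AT+ACP and none; else
    other."""
    if arch.has_reducing:
        return "R-PKS"
    needed = {"KS", "AT", "ACP"}
    if needed <= set(arch.tokens):
        return "NR-PKS"
    return "other"


def kmer_set(seq: str, k: int = 8) -> frozenset[str]:
    """The set of k-mers of a sequence (empty if shorter than k)."""
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_distance(seq_a: str, seq_b: str, k: int = 8) -> float:
    """1 − Jaccard similarity of the two k-mer sets; in [0, 1].

    Symmetric, zero for identical sequences, one for sequences sharing no
    k-mer.  Sequences must be longer than k.
    """
    if len(seq_a) <= k or len(seq_b) <= k:
        raise ChemotriError(f"sequences must be longer than k={k}")
    a, b = kmer_set(seq_a, k), kmer_set(seq_b, k)
    return 1.0 - len(a & b) / len(a | b)


def assign_group(pks_seq: str, references: Sequence[GroupReference],
                 max_distance: float = 0.6,
                 arch: DomainArchitecture | None = None,
                 ) -> PKSClassification:
    """Place an NR-PKS into a phylogenetic group by nearest reference.

    The group of the closest labelled reference is assigned when its k-mer
    distance is at most ``max_distance``; otherwise the group is unknown.
    ``k`` adapts to the reference alphabet (8 for nucleotide, 4 for amino
    acids).  If ``arch`` is given and is not non-reducing, no group is
    assigned.
    """
    if not references:
        raise ChemotriError("at least one labelled reference required")
    category = "NR-PKS" if arch is None else classify_category(arch)
    if category != "NR-PKS":
        return PKSClassification(category=category)
    best_ref, best_d = None, None
    for ref in sorted(references, key=lambda r: r.reference_id):
        k = 4 if ref.alphabet == "protein" else 8
        d = kmer_distance(pks_seq, ref.sequence, k=k)
        if best_d is None or d < best_d:
            best_ref, best_d = ref, d
    if best_d is not None and best_d <= max_distance:
        return PKSClassification(category="NR-PKS", group=best_ref.group,
                                 nearest_reference_id=best_ref.reference_id,
                                 distance=best_d)
    return PKSClassification(category="NR-PKS", group="unknown",
                             nearest_reference_id=(best_ref.reference_id
                                                   if best_ref else None),
                             distance=best_d)


def nj_tree(distances: Mapping[str, Mapping[str, float]] | np.ndarray,
            ids: Sequence[str] | None = None) -> str:
    """Neighbor-joining tree (newick) from a symmetric distance matrix.

    Accepts either a nested mapping ``{id: {id: d}}`` or a square array plus
    ``ids``.  Deterministic for a given input order.
    """
    if isinstance(distances, Mapping):
        ids = sorted(distances)
        mat = np.array([[float(distances[i][j]) for j in ids] for i in ids])
    else:
        mat = np.asarray(distances, dtype=float)
        if ids is None:
            raise ChemotriError("ids required with an array distance matrix")
    dm = DistanceMatrix(mat, ids=list(ids))
    tree = _skbio_nj(dm)
    return str(tree).strip()
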