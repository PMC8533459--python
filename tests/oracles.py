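"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available
(quadratic dynamic programming, exhaustive enumeration, set arithmetic) and
share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

NEG_INF = float("-inf")

# affine gap convention: first gap position -2, each further position -1
MATCH, MISMATCH, OPEN, EXTEND = 1, -1, 2, 1


def gotoh_score(a: str, b: str) -> float:
    """Global affine-gap alignment score by explicit three-state DP."""
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(OPEN + (i - 1) * EXTEND)
    for j in range(1, m + 1):
        Iy[0][j] = -(OPEN + (j - 1) * EXTEND)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - OPEN, Ix[i - 1][j] - EXTEND,
                           Iy[i - 1][j] - OPEN)
            Iy[i][j] = max(M[i][j - 1] - OPEN, Iy[i][j - 1] - EXTEND,
                           Ix[i][j - 1] - OPEN)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def brute_mutual_best(score: dict[tuple[str, str], float],
                      ids_a: list[str], ids_b: list[str],
                      ) -> set[tuple[str, str]]:
    """All (a, b) that are each other's unique best-scoring partner.

    The enumerations used in tests avoid exact score ties, so score order
    alone decides uniqueness.
    """
    pairs = set()
    for a, b in itertools.product(ids_a, ids_b):
        top_a = max(score[(a, x)] for x in ids_b)
        argmax_a = [x for x in ids_b if score[(a, x)] == top_a]
        top_b = max(score[(x, b)] for x in ids_a)
        argmax_b = [x for x in ids_a if score[(x, b)] == top_b]
        if argmax_a == [b] and argmax_b == [a]:
            pairs.add((a, b))
    return pairs


def jaccard_kmer_distance(a: str, b: str, k: int) -> float:
    """Set-arithmetic k-mer distance, written independently."""
    sa = {a[i:i + k] for i in range(len(a) - k + 1)}
    sb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(sa & sb) / len(sa | sb)


def additive_distance_matrix(tree: dict[str, tuple[str, float]],
                             leaves: list[str]) -> dict[str, dict[str, float]]:
    """Pairwise path-length distances on a tree given as child->(parent, len)."""
    def path_to_root(x: str) -> list[tuple[str, float]]:
        out = []
        while x in tree:
            parent, length = tree[x]
            out.append((x, length))
            x = parent
        out.append((x, 0.0))
        return out

    def dist(u: str, v: str) -> float:
        pu = path_to_root(u)
        pv = path_to_root(v)
        anc_u: dict[str, float] = {}
        acc = 0.0
        for name, length in pu:
            anc_u[name] = acc
            acc += length
        acc = 0.0
        for name, length in pv:
            if name in anc_u:
                return acc + anc_u[name]
            acc += length
        raise ValueError("no common ancestor")

    return {u: {v: (0.0 if u == v else dist(u, v)) for v in leaves}
            for u in leaves}
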