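"""Independent brute-force oracles used by the test suite.

These deliberately re-derive alignment scores, edit distances and global
identities with plain dynamic programming (quadratic space, explicit state
machines) so the package's aligner-backed implementations are checked
against an unrelated code path.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def blosum(a: str, b: str) -> float:
    return float(_BLOSUM[a][b])


def sw_affine_score(q: str, r: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps; a gap of length k costs
    gap_open + (k-1)*gap_extend. Returns the optimal local score (floor 0)."""
    n, m = len(q), len(r)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q (consumes r)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in r (consumes q)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + blosum(q[i - 1], r[j - 1]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_dna_identity(a: str, b: str, match=1.0, mismatch=-1.0,
                        gap_open=4.0, gap_extend=1.0) -> tuple[float, float]:
    """Needleman-Wunsch with affine gaps (gap of length k costs
    gap_open + (k-1)*gap_extend); returns (score, percent identity of one
    optimal alignment, gaps counted as columns)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        Y[i][0] = -(gap_open + (i - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_extend,
                          Y[i][j - 1] - gap_open)
            Y[i][j] = max(M[i - 1][j] - gap_open, Y[i - 1][j] - gap_extend,
                          X[i - 1][j] - gap_open)
    score = max(M[n][m], X[n][m], Y[n][m])
    # traceback one optimal path, counting matches and columns
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i][j])
    matches = columns = 0
    while i > 0 or j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            matches += a[i - 1] == b[j - 1]
            columns += 1
            prev = max(("M", "X", "Y"),
                       key=lambda st: {"M": M, "X": X, "Y": Y}[st][i - 1][j - 1])
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            columns += 1
            for prev, cost in (("M", gap_open), ("X", gap_extend), ("Y", gap_open)):
                if abs({"M": M, "X": X, "Y": Y}[prev][i][j - 1] - cost - X[i][j]) < 1e-9:
                    break
            j -= 1
            state = prev
        else:
            columns += 1
            for prev, cost in (("M", gap_open), ("Y", gap_extend), ("X", gap_open)):
                if abs({"M": M, "X": X, "Y": Y}[prev][i - 1][j] - cost - Y[i][j]) < 1e-9:
                    break
            i -= 1
            state = prev
        if i == 0 and j == 0:
            break
        if i == 0:
            columns += j
            break
        if j == 0:
            columns += i
            break
    return score, 100.0 * matches / columns


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def fuzzy_edit_oracle(query: str, ref: str) -> tuple[int, int]:
    """Exhaustive (substitutions, indels) for aligning two equal-length
    windows with at most one indel and free trailing overhang, minimising
    total differences then indels.

    Enumerates the complete constrained alignment space: either no indel
    (plain Hamming) or exactly one deletion/insertion at each possible
    position with the overhanging terminal base free.
    """
    assert len(query) == len(ref)
    best = (hamming(query, ref), 0)

    def better(c):
        nonlocal best
        if (c[0] + c[1], c[1]) < (best[0] + best[1], best[1]):
            best = c

    L = len(query)
    for i in range(L):  # deletion: query base i unaligned, trailing ref base free
        q = query[:i] + query[i + 1 :]
        better((hamming(q, ref[: L - 1]), 1))
    for j in range(L):  # insertion: ref base j skipped, trailing query base free
        r = ref[:j] + ref[j + 1 :]
        better((hamming(query[: L - 1], r), 1))
    return best
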