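"""Independent brute-force global affine-gap aligner (Gotoh) used as a
test oracle.  Deliberately separate from the package implementation:
plain dynamic programming with traceback, no shared code paths.

Scoring mirrors the package's placement aligner: match +1, mismatch -1,
a gap of length L costs 5 + (L - 1).
"""
from __future__ import annotations

NEG = float("-inf")

MATCH = 1
MISMATCH = -1
GAP_OPEN = -5  # score of the first gap column
GAP_EXTEND = -1


def gotoh_align(a: str, b: str) -> tuple[int, list[tuple[int, int]]]:
    """Optimal global alignment score and one optimal per-base map.

    Returns (score, pairs) where pairs are 0-based (i, j) aligned
    columns (matches and mismatches).
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a advances)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b advances)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + s
            Xi[j] = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND, Yi1[j] + GAP_OPEN)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND, Xi[j - 1] + GAP_OPEN)
    score = max(M[n][m], X[n][m], Y[n][m])

    # traceback one optimal path
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    state = max(((M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y")))[1]
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            prev = M[i][j] - s
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == X[i - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            if i > 1 or j > 0:
                if X[i][j] == M[i - 1][j] + GAP_OPEN:
                    state = "M"
                elif X[i][j] == X[i - 1][j] + GAP_EXTEND:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            if j > 1 or i > 0:
                if Y[i][j] == M[i][j - 1] + GAP_OPEN:
                    state = "M"
                elif Y[i][j] == Y[i][j - 1] + GAP_EXTEND:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
    pairs.reverse()
    return int(score), pairs


def placement_score(alt: str, parent: str, blocks: list[tuple[int, int, int, int]]) -> int:
    """Score of the global alignment a placement's blocks describe.

    Used to verify the implementation's blocks are an *optimal*
    alignment: their implied score must equal the Gotoh optimum.
    """

    def gap_cost(length: int) -> int:
        return 0 if length <= 0 else GAP_OPEN + (length - 1) * GAP_EXTEND

    score = 0
    prev_a, prev_p = 0, 0
    for a1, a2, p1, p2 in blocks:
        score += gap_cost(a1 - prev_a - 1) + gap_cost(p1 - prev_p - 1)
        for off in range(a2 - a1 + 1):
            score += MATCH if alt[a1 - 1 + off] == parent[p1 - 1 + off] else MISMATCH
        prev_a, prev_p = a2, p2
    score += gap_cost(len(alt) - prev_a) + gap_cost(len(parent) - prev_p)
    return score
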