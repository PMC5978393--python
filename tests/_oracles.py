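"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately plain-Python and slow; these functions are
reference re-implementations, not imports from the package under test.
"""

from __future__ import annotations

MATCH, MISMATCH, GAP = 1, -1, -2


def _sub_score(x: str, y: str) -> int:
    if x == y or x == "N" or y == "N":
        return MATCH
    return MISMATCH


def nw_oracle(a: str, b: str) -> tuple[int, int, int, int, int]:
    """Plain-Python global alignment with the package's scoring.

    Traceback prefers diagonal, then up (gap in b), then left (gap in a).
    Returns (score, matches, mismatches, gap_columns, columns).
    """
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        score[0][j] = GAP * j
    for i in range(1, n + 1):
        score[i][0] = GAP * i
        for j in range(1, m + 1):
            score[i][j] = max(
                score[i - 1][j - 1] + _sub_score(a[i - 1], b[j - 1]),
                score[i - 1][j] + GAP,
                score[i][j - 1] + GAP,
            )
    i, j = n, m
    matches = mismatches = gaps = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if i > 0 and j > 0:
            s = _sub_score(a[i - 1], b[j - 1])
            if score[i][j] == score[i - 1][j - 1] + s:
                if s == MATCH:
                    matches += 1
                else:
                    mismatches += 1
                i, j = i - 1, j - 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + GAP:
            gaps += 1
            i -= 1
            continue
        gaps += 1
        j -= 1
    return score[n][m], matches, mismatches, gaps, cols


def identity_oracle(a: str, b: str) -> float:
    if b < a:
        a, b = b, a
    _, matches, _, _, cols = nw_oracle(a, b)
    return matches / cols


def semiglobal_oracle(primer: str, read: str) -> tuple[int, int]:
    """Best (edits, leftmost start) of primer aligned end-to-end inside read."""
    p, r = len(primer), len(read)
    best_edits, best_start = 10**9, -1
    for start in range(r + 1):
        prev = list(range(p + 1))
        if prev[p] < best_edits:
            best_edits, best_start = prev[p], start
        for j in range(start, r):
            cur = [j - start + 1] + [0] * p
            for i in range(1, p + 1):
                cur[i] = min(
                    prev[i] + 1,
                    cur[i - 1] + 1,
                    prev[i - 1] + (primer[i - 1] != read[j]),
                )
            prev = cur
            if prev[p] < best_edits:
                best_edits, best_start = prev[p], start
    return best_edits, best_start


def homopolymer_oracle(seq: str, min_len: int) -> list[tuple[str, int, int]]:
    """All maximal runs >= min_len via an O(n^2)-style re-scan."""
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            out.append((seq[i], i, j - i))
        i = j
    return out


def lca_oracle(ranks_a: tuple, ranks_b: tuple) -> tuple:
    """Longest common prefix of two 7-rank tuples (None-padded)."""
    out = []
    for ra, rb in zip(ranks_a, ranks_b):
        if ra is None or ra != rb:
            break
        out.append(ra)
    return tuple(out) + (None,) * (7 - len(out))


def expected_errors_oracle(quals) -> float:
    total = 0.0
    for q in quals:
        total += 10.0 ** (-q / 10.0)
    return total
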