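"""Needleman-Wunsch global alignment kernel.

Scoring is fixed package-wide: match +1, mismatch -1, gap -2 (linear), with
terminal gaps penalized like any other gap.  Identity is defined as
matches / alignment columns, so terminal overhangs of a short sequence
against a long one count against identity — the behaviour greedy
centroid clustering expects for variable-length amplicons.

The DP and traceback are jitted with numba; traceback ties are broken
deterministically (diagonal, then gap-in-second, then gap-in-first) so the
reported identity is reproducible.  ``N`` is a wildcard that matches any
base, so N-padded sequences align cleanly onto each other — required for
the padding pre-processing mode, where reads and centroids both carry 3'
N-tails.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nw_stats", "global_identity"]

MATCH = 1
MISMATCH = -1
GAP = -2

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i  # code 4 == N / unknown


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _nw_kernel(a, b):  # pragma: no cover - exercised via nw_stats
    n = a.shape[0]
    m = b.shape[0]
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    for j in range(m + 1):
        score[0, j] = GAP * j
    for i in range(1, n + 1):
        score[i, 0] = GAP * i
        ai = a[i - 1]
        row = score[i]
        prev = score[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            if ai == bj or ai == 4 or bj == 4:
                diag = prev[j - 1] + MATCH
            else:
                diag = prev[j - 1] + MISMATCH
            up = prev[j] + GAP
            left = row[j - 1] + GAP
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            row[j] = best
    # traceback: prefer diagonal, then up (gap in b), then left (gap in a)
    i = n
    j = m
    matches = 0
    mismatches = 0
    gaps = 0
    cols = 0
    while i > 0 or j > 0:
        cols += 1
        if i > 0 and j > 0:
            ai = a[i - 1]
            bj = b[j - 1]
            if ai == bj or ai == 4 or bj == 4:
                sub = MATCH
            else:
                sub = MISMATCH
            if score[i, j] == score[i - 1, j - 1] + sub:
                if sub == MATCH:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + GAP:
            gaps += 1
            i -= 1
            continue
        gaps += 1
        j -= 1
    return score[n, m], matches, mismatches, gaps, cols


def nw_stats(a: str, b: str) -> tuple[int, int, int, int, int]:
    """Global alignment of two sequences.

    Returns ``(score, matches, mismatches, gap_columns, columns)`` for one
    optimal alignment chosen by the deterministic traceback.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return tuple(int(x) for x in _nw_kernel(_encode(a), _encode(b)))


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the global alignment of *a* and *b*.

    Symmetric; 1.0 iff the sequences are equal up to N wildcards.
    """
    # canonical argument order: with tied optimal paths the traceback could
    # otherwise pick alignments with different match counts for (a,b) vs (b,a)
    if b < a:
        a, b = b, a
    _, matches, _, _, cols = nw_stats(a, b)
    return matches / cols
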