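"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's alignment path (biopython): the
optimal affine-gap alignment score is computed by direct recursion over the
alignment definition, memoized on (i, j, previous-move) states.
"""

from __future__ import annotations

from functools import lru_cache


def best_affine_score(a: str, b: str, match: int, mismatch: int,
                      gap_open: int, gap_extend: int) -> float:
    """Optimal global alignment score under affine gap costs.

    Recursion over the last move (diagonal / gap-in-a / gap-in-b); the
    first base of a gap scores ``gap_open`` and every further base
    ``gap_extend`` (the convention used by the package's aligner).
    """
    neg = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = neg
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            best = max(best, cost + rec(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            best = max(best, cost + rec(i, j + 1, "B"))
        return best

    result = rec(0, 0, "M")
    rec.cache_clear()
    return result


def score_of_alignment(ref_row: str, query_row: str, match: int, mismatch: int,
                       gap_open: int, gap_extend: int) -> float:
    """Score a gapped alignment (two rows with '-') column by column."""
    score = 0.0
    prev_gap = None  # 'ref' | 'query'
    for r, q in zip(ref_row, query_row):
        if r == "-" or q == "-":
            side = "ref" if r == "-" else "query"
            score += gap_extend if prev_gap == side else gap_open
            prev_gap = side
        else:
            score += match if r == q else mismatch
            prev_gap = None
    return score
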