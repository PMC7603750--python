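"""Independent brute-force oracles used by the tests.

These deliberately re-derive alignment scores by memoized top-down
recursion over explicit affine states — a formulation independent of
the production bottom-up matrices — and alignment-set scores by direct
column accounting.
"""

from __future__ import annotations

from functools import lru_cache


def brute_local_score(q: str, s: str, score, gap_open: int, gap_extend: int) -> int:
    """Optimal Smith-Waterman score by exhaustive recursion.

    best(i, j, state) = best score of any alignment ENDING exactly at
    (i, j) in `state` (M = last column aligned pair, E = last column gap
    in query, F = last column gap in subject).  The global optimum is
    the max over all end cells, floored at zero.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if state == "M":
            if i == 0 or j == 0:
                return float("-inf")
            prev = max(0.0, best(i - 1, j - 1, "M"), best(i - 1, j - 1, "E"),
                       best(i - 1, j - 1, "F"))
            return prev + score(q[i - 1], s[j - 1])
        if state == "E":  # gap in query, consumes s[j-1]
            if j == 0:
                return float("-inf")
            return max(max(best(i, j - 1, "M"), best(i, j - 1, "F")) - gap_open,
                       best(i, j - 1, "E") - gap_extend)
        if i == 0:  # F: gap in subject, consumes q[i-1]
            return float("-inf")
        return max(max(best(i - 1, j, "M"), best(i - 1, j, "E")) - gap_open,
                   best(i - 1, j, "F") - gap_extend)

    out = 0.0
    for i in range(len(q) + 1):
        for j in range(len(s) + 1):
            for st in ("M", "E", "F"):
                out = max(out, best(i, j, st))
    return int(out)


def brute_global_score(q: str, s: str, score, gap_open: int, gap_extend: int) -> int:
    """Optimal global (end-to-end, affine) alignment score, same
    recursion style, terminal gaps penalized."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else float("-inf")
        if state == "M":
            if i == 0 or j == 0:
                return float("-inf")
            return max(best(i - 1, j - 1, "M"), best(i - 1, j - 1, "E"),
                       best(i - 1, j - 1, "F")) + score(q[i - 1], s[j - 1])
        if state == "E":
            if j == 0:
                return float("-inf")
            start = 0.0 if (i == 0 and j == 1) else float("-inf")
            return max(max(best(i, j - 1, "M"), best(i, j - 1, "F"), start) - gap_open,
                       best(i, j - 1, "E") - gap_extend)
        if i == 0:
            return float("-inf")
        start = 0.0 if (i == 1 and j == 0) else float("-inf")
        return max(max(best(i - 1, j, "M"), best(i - 1, j, "E"), start) - gap_open,
                   best(i - 1, j, "F") - gap_extend)

    return int(max(best(len(q), len(s), st) for st in ("M", "E", "F")))


def pairwise_alignment_score(row_a: str, row_b: str, score,
                             gap_open: int, gap_extend: int) -> int:
    """Score an already-aligned pair of gapped rows: substitution score
    on residue-residue columns, affine penalty per gap run (terminal
    included); gap-gap columns score nothing."""
    total = 0
    in_gap_a = in_gap_b = False
    for a, b in zip(row_a, row_b):
        if a == "-" and b == "-":
            continue
        if a == "-":
            total -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif b == "-":
            total -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += score(a, b)
            in_gap_a = in_gap_b = False
    return total
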