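"""Independent brute-force oracles used to cross-check the library."""

from __future__ import annotations

import re
from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

_CANONICAL_RE = re.compile(r"D.[DNS].[DNST]G..[TDSNGEQ]..[ED]")
_RELAXED_RE = re.compile(r"D.[DNS].[DNST]G.....[ED]")


def scan_oracle(seq: str, strictness: str = "canonical") -> list[int]:
    """Left-to-right regex scan with skip-past-loop overlap resolution."""
    pattern = _CANONICAL_RE if strictness == "canonical" else _RELAXED_RE
    starts = []
    i = 0
    while i + 12 <= len(seq):
        if pattern.fullmatch(seq[i : i + 12]):
            starts.append(i)
            i += 12
        else:
            i += 1
    return starts


def gotoh_score(a: str, b: str, gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    """Optimal global alignment score by memoized recursion (affine gaps).

    Follows the convention where the first residue of a gap costs
    ``gap_open`` and each subsequent one ``gap_extend``; terminal gaps are
    penalized like internal ones.
    """

    @lru_cache(maxsize=None)
    def f(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i]][b[j]] + f(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            best = max(best, cost + f(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            best = max(best, cost + f(i, j + 1, "B"))
        return best

    return f(0, 0, "start")


def max_adjacent_pairing(gaps: list[int], lo: int, hi: int) -> int:
    """Maximum number of disjoint adjacent-loop pairs by exhaustive search.

    ``gaps[i]`` is the linker between loops i and i+1; a pair (i, i+1) is
    allowed when lo <= gaps[i] <= hi.
    """
    n = len(gaps) + 1

    def best(i: int) -> int:
        if i >= n - 1:
            return 0
        take = 0
        if lo <= gaps[i] <= hi:
            take = 1 + best(i + 2)
        return max(take, best(i + 1))

    return best(0)


def bipartitions(tree, anchor: str) -> set[frozenset]:
    """Non-trivial splits of a tree, each canonicalized as the side
    not containing ``anchor``."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = all_tips - below if anchor in below else below
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(side)
    return splits
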