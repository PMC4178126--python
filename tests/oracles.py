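"""Independent oracles used by the test suite.

These deliberately avoid the package's DP kernel: alignment optima are
recomputed by exhaustive path enumeration (and by a separate memoised
recursion for larger cases), and affine gap costs are re-scored from the
gapped strings themselves.
"""

from __future__ import annotations

from functools import lru_cache

from demarcate.pairalign import AlignParams, pair_score


def score_gapped_pair(row_a: str, row_b: str, params: AlignParams) -> float:
    """Score a finished alignment: pair scores plus affine gap costs.

    A gap run of length L costs gap_open + (L-1)*gap_extend; runs in
    different rows are separate runs even when adjacent.
    """
    total = 0.0
    prev = None  # which row the previous column's gap was in, if any
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            row = 0 if x == "-" else 1
            total -= params.gap_extend if prev == row else params.gap_open
            prev = row
        else:
            total += pair_score(x, y, params)
            prev = None
    return total


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b).

    No column may be gap in both rows, so each column consumes a character
    of a, of b, or both.
    """
    def rec(i: int, j: int, row_a: list, row_b: list):
        if i == len(a) and j == len(b):
            yield "".join(row_a), "".join(row_b)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, row_a + [a[i]], row_b + [b[j]])
        if i < len(a):
            yield from rec(i + 1, j, row_a + [a[i]], row_b + ["-"])
        if j < len(b):
            yield from rec(i, j + 1, row_a + ["-"], row_b + [b[j]])

    yield from rec(0, 0, [], [])


def brute_force_best(a: str, b: str, params: AlignParams) -> float:
    """Optimal global score by scoring every possible alignment."""
    return max(score_gapped_pair(ra, rb, params)
               for ra, rb in enumerate_alignments(a, b))


def recursive_best(a: str, b: str, params: AlignParams) -> float:
    """Optimal global score by memoised recursion over suffixes.

    Independent of the package's iterative kernel: pure-Python recursion
    keyed on (i, j, row of the previous column's gap).
    """
    go, ge = params.gap_open, params.gap_extend
    neg = float("-inf")

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev_gap: int) -> float:
        # prev_gap: -1 no gap in previous column, 0 gap in row a, 1 in row b
        if i == len(a) and j == len(b):
            return 0.0
        options = [neg]
        if i < len(a) and j < len(b):
            options.append(pair_score(a[i], b[j], params) + best(i + 1, j + 1, -1))
        if i < len(a):  # gap in row b
            cost = ge if prev_gap == 1 else go
            options.append(-cost + best(i + 1, j, 1))
        if j < len(b):  # gap in row a
            cost = ge if prev_gap == 0 else go
            options.append(-cost + best(i, j + 1, 0))
        return max(options)

    result = best(0, 0, -1)
    best.cache_clear()
    return result


def connected_components_oracle(ids, edges):
    """Connected components via networkx, for partition cross-checks."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    return [sorted(c) for c in nx.connected_components(g)]
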