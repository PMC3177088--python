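"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and vectorized
code paths: alignments are scored by exhaustive enumeration of operation
strings, proximity by all-pairs scans, and the binomial p-value by direct
summation of the probability mass function.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from cysmap.homology_map import substitution_score


def enumerate_alignment_score(
    q: str,
    t: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    semiglobal: bool = True,
) -> float:
    """Optimal alignment score by exhaustive enumeration (lengths <= ~7).

    Operations: M consumes one residue of each sequence, X consumes only
    the query, Y consumes only the target.  A maximal gap run of length k
    costs gap_open + k*gap_extend, except the first and last runs of the
    alignment when ``semiglobal`` (free end gaps).
    """

    def score_ops(ops: str) -> float:
        runs: list[tuple[str, int]] = []
        for op in ops:
            kind = "G" if op in "XY" else "M"
            key = op if kind == "G" else "M"
            if runs and runs[-1][0] == key:
                runs[-1] = (key, runs[-1][1] + 1)
            else:
                runs.append((key, 1))
        total = 0.0
        i = j = 0
        pos = 0
        for ridx, (key, length) in enumerate(runs):
            if key == "M":
                for _ in range(length):
                    total += substitution_score(q[i], t[j])
                    i += 1
                    j += 1
            else:
                is_end_run = ridx == 0 or ridx == len(runs) - 1
                if not (semiglobal and is_end_run):
                    total -= gap_open + gap_extend * length
                if key == "X":
                    i += length
                else:
                    j += length
            pos += length
        return total

    best = -math.inf
    stack = [(0, 0, "")]
    while stack:
        i, j, ops = stack.pop()
        if i == len(q) and j == len(t):
            best = max(best, score_ops(ops))
            continue
        if i < len(q):
            stack.append((i + 1, j, ops + "X"))
        if j < len(t):
            stack.append((i, j + 1, ops + "Y"))
        if i < len(q) and j < len(t):
            stack.append((i + 1, j + 1, ops + "M"))
    return best


def brute_force_hits(points: np.ndarray, cutoff: float) -> tuple[int, int]:
    """All-pairs neighbour count with the count-once rule.

    Returns (number of points with at least one other point at distance
    < cutoff, number of pairs below cutoff).
    """
    n = len(points)
    hit = [False] * n
    n_pairs = 0
    for a, b in combinations(range(n), 2):
        if np.linalg.norm(points[a] - points[b]) < cutoff:
            hit[a] = hit[b] = True
            n_pairs += 1
    return sum(hit), n_pairs


def brute_force_mask(positions: list[int], spacing: int) -> list[int]:
    """All-pairs version of the clustered-cysteine mask."""
    drop = set()
    for a, b in combinations(positions, 2):
        if abs(a - b) <= spacing:
            drop.add(a)
            drop.add(b)
    return [p for p in positions if p not in drop]


def exact_binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value by direct PMF summation: sum the
    probabilities of all outcomes no more likely than the observed one."""
    pmf = [math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(n + 1)]
    observed = pmf[k]
    return min(1.0, sum(v for v in pmf if v <= observed * (1 + 1e-9)))
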