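"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the alignment
oracle is a direct recursion over the definition of a gapped local
alignment, the BH oracle is the textbook step-up formula, and the
hypergeometric oracle sums exact rational probabilities.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _col_score(mb: str, tb: str, weight: float, params) -> float:
    if (mb, tb) in _WC:
        return params.match * weight
    if (mb, tb) in _WOBBLE:
        return params.wobble * weight
    return params.mismatch * weight


def best_local_score(mir: str, target: str, params) -> float:
    """Maximum score over all gapped local alignments, by recursion.

    An alignment is a sequence of columns consuming the reversed miRNA
    and/or the target; affine gaps cost ``gap_open`` for the first
    column of a run and ``gap_extend`` for each further one.  The score
    of the best alignment continuing from (i, j) in a given gap state is
    defined recursively; the empty alignment scores 0.
    """
    a = mir[::-1]
    b = target
    n, m = len(a), len(b)
    weights = [params.seed_weight
               if params.seed_start <= (n - i) <= params.seed_end else 1.0
               for i in range(n)]

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int, prev: str) -> float:
        # best score achievable by any (possibly empty) continuation
        options = [0.0]
        if i < n and j < m:
            options.append(_col_score(a[i], b[j], weights[i], params)
                           + best_from(i + 1, j + 1, "M"))
        if j < m:  # gap in the miRNA, consume a target base
            cost = params.gap_extend if prev == "X" else params.gap_open
            options.append(cost + best_from(i, j + 1, "X"))
        if i < n:  # gap in the target, consume a miRNA base
            cost = params.gap_extend if prev == "Y" else params.gap_open
            options.append(cost + best_from(i + 1, j, "Y"))
        return max(options)

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, best_from(i, j, "M"))
    return best


def enumerate_local_score(mir: str, target: str, params) -> float:
    """Plain exhaustive DFS over every alignment path (tiny inputs only).

    Validates :func:`best_local_score` itself on instances small enough
    to enumerate without memoisation.
    """
    a = mir[::-1]
    b = target
    n, m = len(a), len(b)
    weights = [params.seed_weight
               if params.seed_start <= (n - i) <= params.seed_end else 1.0
               for i in range(n)]
    best = 0.0

    def walk(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        best = max(best, score)
        if i < n and j < m:
            walk(i + 1, j + 1, "M",
                 score + _col_score(a[i], b[j], weights[i], params))
        if j < m:
            walk(i, j + 1, "X",
                 score + (params.gap_extend if prev == "X" else params.gap_open))
        if i < n:
            walk(i + 1, j, "Y",
                 score + (params.gap_extend if prev == "Y" else params.gap_open))

    for i in range(n):
        for j in range(m):
            walk(i, j, "start", 0.0)
    return best


def bh_stepup(pvals: list[float]) -> list[float]:
    """Textbook BH: adj_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via direct summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def stacking_energy_resum(mir_aligned: str, target_aligned: str,
                          table: dict[str, float]) -> float:
    """Left-to-right re-summation of stack energies over paired runs."""
    def paired(mb: str, tb: str) -> bool:
        return (mb, tb) in _WC or (mb, tb) in _WOBBLE

    total = 0.0
    cols = list(zip(mir_aligned, target_aligned))
    for (m1, t1), (m2, t2) in zip(cols, cols[1:]):
        if "-" not in (m1, t1, m2, t2) and paired(m1, t1) and paired(m2, t2):
            total += table[t1 + t2]
    return total
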