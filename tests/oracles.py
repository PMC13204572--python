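"""Independent brute-force oracles used by the test suite.

These are written against the method definitions only — integer/rational
arithmetic, direct enumeration — and share no code with the package, so
they can arbitrate the package's log-space implementations.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from fractions import Fraction
from itertools import product

#: Same relative tie tolerance as the implementation's exact test, expressed
#: as the exact rational (10^7 + 1) / 10^7 so the comparison stays integral.
TIE_NUM, TIE_DEN = 10**7 + 1, 10**7


def _weight(first_row: tuple[int, ...], cols: tuple[int, ...]) -> int:
    """Integer N!/prod(cells!) — proportional to the table's probability
    within its margin class."""
    w = 1
    remaining = sum(cols)
    for a, c in zip(first_row, cols):
        w *= math.comb(remaining, a)
        remaining -= a
    remaining = sum(cols) - sum(first_row)
    for a, c in zip(first_row, cols):
        w *= math.comb(remaining, c - a)
        remaining -= c - a
    return w


def margin_class(row0: int, cols: tuple[int, ...]):
    """All first rows consistent with margins (row0; cols), with weights."""
    ranges = [range(min(row0, c) + 1) for c in cols[:-1]]
    rows = []
    for head in product(*ranges):
        last = row0 - sum(head)
        if 0 <= last <= cols[-1]:
            rows.append(head + (last,))
    return rows


def fisher_p_exact(table) -> Fraction:
    """Exact two-sided homogeneity p-value for a 2xc table as a Fraction.

    Sums the multivariate hypergeometric probability of every
    margin-consistent table whose probability is at most (1 + 1e-7) times
    the observed table's, evaluated with exact integer weights.
    """
    first = tuple(int(x) for x in table[0])
    second = tuple(int(x) for x in table[1])
    cols = tuple(a + b for a, b in zip(first, second))
    row0 = sum(first)
    w_obs = _weight(first, cols)
    cutoff = (w_obs * TIE_NUM) // TIE_DEN
    total = tail = 0
    for fr in margin_class(row0, cols):
        w = _weight(fr, cols)
        total += w
        if w <= cutoff:
            tail += w
    return Fraction(tail, total)


def margin_class_pvalues(row0: int, cols: tuple[int, ...]) -> dict[tuple[int, ...], Fraction]:
    """Exact p-value of every table in one margin class, computed once."""
    rows = margin_class(row0, cols)
    weights = [_weight(fr, cols) for fr in rows]
    order = sorted(range(len(rows)), key=weights.__getitem__)
    ws = [weights[i] for i in order]
    prefix = []
    acc = 0
    for w in ws:
        acc += w
        prefix.append(acc)
    total = acc
    out = {}
    for i, fr in enumerate(rows):
        cutoff = (weights[i] * TIE_NUM) // TIE_DEN
        idx = bisect_right(ws, cutoff)
        out[fr] = Fraction(prefix[idx - 1], total)
    return out


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = math.comb(N, n)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, denom)


def bh_stepup(pvalues, m=None):
    """Literal BH step-up on Fractions/floats, mapped back to input order."""
    n = len(pvalues)
    if m is None:
        m = n
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = min(1.0, running)
    return q
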