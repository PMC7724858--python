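"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths (and scipy's test
functions): probabilities come from math.comb, distributions from explicit
enumeration, and graph distances from a hand-written Floyd-Warshall.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_pmf(x: int, N: int, K: int, n: int) -> Fraction:
    """P(X = x) drawing n from N with K successes, as an exact fraction."""
    if x < 0 or x > n or x > K or n - x > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))


def fisher_one_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """P(top-left cell >= a) over all tables with the observed margins."""
    N, row1, col1 = a + b + c + d, a + b, a + c
    total = Fraction(0)
    for x in range(a, min(row1, col1) + 1):
        total += hypergeom_pmf(x, N, row1, col1)
    return total


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    N, row1, col1 = a + b + c + d, a + b, a + c
    p_obs = hypergeom_pmf(a, N, row1, col1)
    total = Fraction(0)
    for x in range(0, min(row1, col1) + 1):
        p = hypergeom_pmf(x, N, row1, col1)
        if p <= p_obs:
            total += p
    return total


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    return sum(
        (hypergeom_pmf(x, N, K, n) for x in range(k, min(K, n) + 1)),
        Fraction(0),
    )


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        r = (i + j + 1) / 2.0  # mean of ranks i+1..j
        for idx in order[i:j]:
            ranks[idx] = r
        i = j
    return ranks


def mwu_enumeration(x, y, two_sided: bool = True) -> tuple[float, Fraction]:
    """Exact Mann-Whitney p by enumerating every assignment of the pooled
    values to the two groups (mid-ranks for ties)."""
    pooled = list(x) + list(y)
    nx, ny = len(x), len(y)
    ranks = midranks(pooled)

    def u_of(idx_set):
        r = sum(ranks[i] for i in idx_set)
        ux = r - nx * (nx + 1) / 2.0
        return min(ux, nx * ny - ux)

    u_obs = u_of(range(nx))
    hits = 0
    total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        total += 1
        if two_sided:
            if u_of(combo) <= u_obs + 1e-9:
                hits += 1
        else:
            r = sum(ranks[i] for i in combo)
            ux = r - nx * (nx + 1) / 2.0
            if ux <= u_obs + 1e-9:
                hits += 1
    return u_obs, Fraction(hits, total)


def ks_statistic_brute(x, y) -> float:
    """sup |ECDF_x - ECDF_y| evaluated at every pooled sample point."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def floyd_warshall(n_nodes: int, edges) -> list[list[float]]:
    inf = float("inf")
    d = [[inf] * n_nodes for _ in range(n_nodes)]
    for i in range(n_nodes):
        d[i][i] = 0
    for u, v in edges:
        d[u][v] = d[v][u] = 1
    for k in range(n_nodes):
        dk = d[k]
        for i in range(n_nodes):
            dik = d[i][k]
            if dik == inf:
                continue
            row = d[i]
            for j in range(n_nodes):
                alt = dik + dk[j]
                if alt < row[j]:
                    row[j] = alt
    return d
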