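"""Exact and asymptotic statistics used throughout the pipeline.

Fisher's exact test and the hypergeometric tail are computed from the
hypergeometric pmf directly (fixed-margin enumeration); the Mann-Whitney U
null distribution is built exactly by a rank-sum counting recursion for
small samples.  The Woolf odds-ratio interval uses a fixed z = 1.96 so that
reported intervals match 2-decimal epidemiological tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import special
from scipy.stats import hypergeom, rankdata

from .errors import ArgumentError

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-status counts: rows exposed/unexposed, columns case/control."""

    exposed_cases: int
    exposed_controls: int
    unexposed_cases: int
    unexposed_controls: int

    def __post_init__(self) -> None:
        cells = self.cells()
        if any(c < 0 for c in cells):
            raise ArgumentError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ArgumentError("contingency table needs at least one non-zero margin")

    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.exposed_cases,
            self.exposed_controls,
            self.unexposed_cases,
            self.unexposed_controls,
        )


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


class MWUResult(NamedTuple):
    statistic: float
    pvalue: float
    exact: bool


def fisher_exact(
    table: Sequence[Sequence[int]],
    alternative: Literal["one_sided", "two_sided"] = "two_sided",
) -> float:
    """Exact p-value for a 2x2 table by fixed-margin hypergeometric enumeration.

    ``one_sided`` tests for enrichment of the top-left cell (P(X >= a));
    ``two_sided`` sums the probabilities of all tables with the given margins
    that are no more probable than the observed one.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ArgumentError("table cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    if alternative == "one_sided":
        if a <= lo:
            return 1.0  # whole support; avoid float summation drift
        p = float(pmf[support >= a].sum())
    elif alternative == "two_sided":
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    else:
        raise ArgumentError(f"unknown alternative {alternative!r}")
    return min(1.0, p)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) drawing n from a population N with K successes."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ArgumentError("need 0 <= K, n <= N")
    if k > min(K, n):
        raise ArgumentError("k cannot exceed min(K, n)")
    if k <= 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample KS statistic D = sup |ECDF_x - ECDF_y| with the asymptotic
    Kolmogorov p-value at effective size n_x*n_y/(n_x+n_y).

    The exact small-sample distribution is not implemented; the asymptotic
    form is adequate for the pooled per-node samples this package compares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ArgumentError("both samples must be non-empty")
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    d = float(np.abs(cdf_x - cdf_y).max())
    n_eff = xs.size * ys.size / (xs.size + ys.size)
    p = float(special.kolmogorov(math.sqrt(n_eff) * d))
    return KSResult(d, min(1.0, p))


def _rank_sum_counts(doubled_ranks: Sequence[int], m: int) -> dict[int, int]:
    """Number of size-m subsets of ``doubled_ranks`` per doubled rank sum."""
    layers: list[dict[int, int]] = [{0: 1}] + [dict() for _ in range(m)]
    for r in doubled_ranks:
        for j in range(min(m, len(layers)) - 1, -1, -1):
            if j + 1 > m:
                continue
            for s, c in layers[j].items():
                layers[j + 1][s + r] = layers[j + 1].get(s + r, 0) + c
    return layers[m]


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    two_sided: bool = True,
    exact_limit: int = 25,
) -> MWUResult:
    """Mann-Whitney U with U = min(U_x, U_y).

    For n_x + n_y <= ``exact_limit`` the null distribution of the rank sum is
    enumerated exactly (mid-ranks for ties); beyond that a tie-corrected
    normal approximation is used and flagged via ``exact=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ArgumentError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = float(ranks[:nx].sum())
    u_x = r_x - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x
    u = min(u_x, u_y)

    if nx + ny <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _rank_sum_counts(doubled.tolist(), nx)
        total = math.comb(nx + ny, nx)
        # doubled U_x for each achievable rank sum
        du_obs = round(2 * u)
        du_max = 2 * nx * ny
        hits = 0
        for s, c in counts.items():
            du = s - nx * (nx + 1)
            low = du <= du_obs
            high = du >= du_max - du_obs
            if two_sided:
                if low or high:
                    hits += c
            else:
                if low:
                    hits += c
        return MWUResult(u, min(1.0, hits / total), True)

    # normal approximation with tie correction
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MWUResult(u, 1.0, False)
    z = (u + 0.5 - mu) / math.sqrt(var)
    p_one = float(special.ndtr(z))
    p = min(1.0, 2 * p_one) if two_sided else p_one
    return MWUResult(u, p, False)


def woolf_or(table: ContingencyTable2x2, z: float = Z_95) -> ORResult:
    """Crude odds ratio with a Woolf (log-normal) confidence interval.

    A Haldane-Anscombe correction (+0.5 to every cell) is applied when any
    cell is zero; the result is flagged via ``corrected``.
    """
    a, b, c, d = (float(v) for v in table.cells())
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oratio)
    return ORResult(
        odds_ratio=oratio,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        corrected=corrected,
    )
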