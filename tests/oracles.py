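"""Independent oracles used by the test suite.

Deliberately naive implementations (pure-Python scans, exact enumeration)
kept free of any code path they are used to check.
"""

from __future__ import annotations

import itertools
from collections import Counter


def brute_force_runs(seq: str) -> dict[str, Counter]:
    """Maximal monomer runs per base by a character-by-character scan."""
    counts: dict[str, Counter] = {b: Counter() for b in "ACGT"}
    i = 0
    while i < len(seq):
        b = seq[i]
        j = i
        while j < len(seq) and seq[j] == b:
            j += 1
        if b in counts:
            counts[b][j - i] += 1
        i = j
    return counts


def brute_force_cpg_runs(seq: str) -> Counter:
    """Maximal (CG)_k tandem repeats, counted in repeat units."""
    counts: Counter = Counter()
    i = 0
    while i + 1 < len(seq):
        if seq[i : i + 2] == "CG":
            k = 0
            while seq[i + 2 * k : i + 2 * k + 2] == "CG":
                k += 1
            counts[k] += 1
            i += 2 * k
        else:
            i += 1
    return counts


def brute_force_callable(line_track, pool_track, dp_min, dp_max,
                         require_pool=True) -> int:
    """Per-position depth scan over expanded tracks."""
    line_depth: dict[tuple[str, int], int] = {}
    for sc, s, e, d in line_track:
        for p in range(s, e):
            line_depth[(sc, p)] = d
    pool_depth: dict[tuple[str, int], int] = {}
    for sc, s, e, d in pool_track:
        for p in range(s, e):
            pool_depth[(sc, p)] = d
    n = 0
    for key, d in line_depth.items():
        if not dp_min <= d <= dp_max:
            continue
        if require_pool and pool_depth.get(key, 0) < dp_min:
            continue
        n += 1
    return n


def chi2_equal_manual(n1: int, n2: int) -> float:
    """Textbook goodness-of-fit statistic against equal expectation."""
    e = (n1 + n2) / 2
    return (n1 - e) ** 2 / e + (n2 - e) ** 2 / e


def _offspring_dist(a: int, b: int) -> dict[int, float]:
    """Genotype distribution of one offspring of parents carrying a and b
    copies of the mutant allele (Mendelian, one locus)."""
    dist: dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    pa = a / 2.0
    pb = b / 2.0
    for x, px in ((0, 1 - pa), (1, pa)):
        for y, py in ((0, 1 - pb), (1, pb)):
            dist[x + y] += px * py
    return dist


def exact_sibchain_probs(G: int, g: int) -> tuple[float, float, float]:
    """Exact (P_present, P_het, P_hom) for the sequenced generation-G
    individual, for a mutation arising heterozygously in one member of the
    generation-g breeding pair, by dynamic programming over the ordered
    pair-genotype distribution of the full-sib chain.
    """
    if g == G:
        return 1.0, 1.0, 0.0
    # distribution over ordered parent-pair genotypes, start (1, 0)
    pair: dict[tuple[int, int], float] = {(1, 0): 1.0}
    for step in range(g, G - 1):
        nxt: dict[tuple[int, int], float] = {}
        for (a, b), p in pair.items():
            od = _offspring_dist(a, b)
            for c1, p1 in od.items():
                for c2, p2 in od.items():
                    if p1 * p2:
                        nxt[(c1, c2)] = nxt.get((c1, c2), 0.0) + p * p1 * p2
        pair = nxt
    final = {0: 0.0, 1: 0.0, 2: 0.0}
    for (a, b), p in pair.items():
        for c, pc in _offspring_dist(a, b).items():
            final[c] += p * pc
    present = final[1] + final[2]
    if present == 0:
        return 0.0, 0.0, 0.0
    return present, final[1] / present, final[2] / present


def garwood_bounds_reference(m: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson CI bounds on the count scale via the gamma relation,
    computed with mpmath-free bisection on the Poisson CDF (independent of
    scipy.stats.chi2.ppf used by the implementation)."""
    from scipy.stats import poisson

    def upper(target):
        lo, hi = 0.0, max(10.0, 5.0 * m + 20)
        for _ in range(200):
            mid = (lo + hi) / 2
            # P(X <= m) under mean mid
            if poisson.cdf(m, mid) > target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    def lower(target):
        if m == 0:
            return 0.0
        lo, hi = 0.0, max(10.0, 5.0 * m + 20)
        for _ in range(200):
            mid = (lo + hi) / 2
            # P(X >= m) under mean mid
            if 1 - poisson.cdf(m - 1, mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    return lower(alpha / 2), upper(alpha / 2)
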