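"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (exact rational
hypergeometric enumeration, exhaustive graph enumeration) so it can stand
against the package's scipy/numba-backed implementations.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hypergeom_pmf_exact(k: int, n_total: int, n_success: int, n_draw: int) -> Fraction:
    if k < 0 or k > n_draw or k > n_success or n_draw - k > n_total - n_success:
        return Fraction(0)
    return Fraction(
        comb(n_success, k) * comb(n_total - n_success, n_draw - k),
        comb(n_total, n_draw),
    )


def fisher_two_sided_exact(x: int, n_total: int, n_success: int, n_draw: int) -> float:
    """Two-sided Fisher p: total mass of outcomes no more probable than x.

    Uses exact rationals with the customary (1 + 1e-7) relative slack for
    "no more probable", matching the convention of standard software.
    """
    obs = hypergeom_pmf_exact(x, n_total, n_success, n_draw)
    slack = obs * Fraction(10_000_001, 10_000_000)
    lo = max(0, n_draw - (n_total - n_success))
    hi = min(n_success, n_draw)
    return float(
        sum(
            p
            for k in range(lo, hi + 1)
            if (p := hypergeom_pmf_exact(k, n_total, n_success, n_draw)) <= slack
        )
    )


def hypergeom_upper_tail_exact(x: int, n_total: int, n_success: int, n_draw: int) -> float:
    """P(X >= x) by exact enumeration."""
    hi = min(n_success, n_draw)
    return float(sum(hypergeom_pmf_exact(k, n_total, n_success, n_draw) for k in range(x, hi + 1)))


def hypergeom_lower_tail_exact(x: int, n_total: int, n_success: int, n_draw: int) -> float:
    """P(X <= x) by exact enumeration."""
    return float(sum(hypergeom_pmf_exact(k, n_total, n_success, n_draw) for k in range(0, x + 1)))


def enumerate_bipartite_graphs(row_deg: list[int], col_deg: list[int]) -> list[frozenset]:
    """All simple bipartite edge sets with the given degree sequences.

    Brute force over subsets of the complete bipartite edge set; feasible
    only for tiny graphs. Edges are (row, col) index pairs.
    """
    n_edges = sum(row_deg)
    assert n_edges == sum(col_deg)
    cells = [(i, j) for i in range(len(row_deg)) for j in range(len(col_deg))]
    out = []
    for subset in combinations(cells, n_edges):
        rd = [0] * len(row_deg)
        cd = [0] * len(col_deg)
        for i, j in subset:
            rd[i] += 1
            cd[j] += 1
        if rd == list(row_deg) and cd == list(col_deg):
            out.append(frozenset(subset))
    return out


def rd_of_edge_set(edges, row_dir, col_dir) -> float:
    c = sum(1 for i, j in edges if row_dir[i] != col_dir[j])
    e = len(edges)
    return (2 * c - e) / e


def re_score_brute(values: np.ndarray, target_mask: np.ndarray) -> float:
    """Rank-based regulatory-effect score by direct definition."""
    order = np.argsort(np.argsort(values, kind="stable"))
    ranks = np.empty(len(values))
    # average ranks on ties
    vals = np.asarray(values, dtype=float)
    for v in np.unique(vals):
        idx = vals == v
        first = np.sort(order[idx]) + 1
        ranks[idx] = first.mean()
    t = ranks[target_mask].mean()
    nt = ranks[~target_mask].mean()
    return (nt - t) / len(values)
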