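"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (enumeration, direct formulas) and shares
no code with the package path it checks.
"""

from itertools import combinations

import numpy as np
import pandas as pd


def bh_stepup_bruteforce(p):
    """q_i = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def spearman_bruteforce(x, y):
    """Average ranks computed by hand, then a textbook Pearson correlation."""

    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j + 2) / 2.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return float("nan") if den == 0 else num / den


def hypergeom_bruteforce(overlap, universe, set_size, list_size):
    """P(X >= overlap) by counting draws explicitly."""
    from math import comb

    total = comb(universe, list_size)
    count = 0
    for k in range(overlap, min(set_size, list_size) + 1):
        count += comb(set_size, k) * comb(universe - set_size, list_size - k)
    return count / total


def dmr_bruteforce(probes: pd.DataFrame, max_gap: int, min_probes: int,
                   min_delta: float):
    """Enumerate every candidate probe run and keep the maximal valid ones.

    A valid run is a set of consecutive (by position) significant probes on
    one chromosome with one shared direction, |delta_beta| > min_delta,
    every consecutive gap <= max_gap, and at least min_probes members; a
    run is kept only when it cannot be extended on either side.
    """
    keep = probes[probes["delta_beta"].abs() > min_delta]
    rows = sorted(keep.itertuples(index=False),
                  key=lambda r: (r.chrom, r.pos))
    out = []
    n = len(rows)
    for i in range(n):
        for j in range(i + min_probes - 1, n):
            run = rows[i:j + 1]
            if len({r.chrom for r in run}) != 1:
                continue
            if len({r.direction for r in run}) != 1:
                continue
            if any(run[k + 1].pos - run[k].pos > max_gap
                   for k in range(len(run) - 1)):
                continue
            # maximality on both sides
            if (i > 0 and rows[i - 1].chrom == run[0].chrom
                    and rows[i - 1].direction == run[0].direction
                    and run[0].pos - rows[i - 1].pos <= max_gap):
                continue
            if (j + 1 < n and rows[j + 1].chrom == run[0].chrom
                    and rows[j + 1].direction == run[0].direction
                    and rows[j + 1].pos - run[-1].pos <= max_gap):
                continue
            out.append(
                (run[0].chrom, run[0].pos, run[-1].pos, len(run),
                 run[0].direction)
            )
    return sorted(set(out))


def overlap_counts_bruteforce(sets):
    """All pairwise and triple intersections of three gene sets."""
    a, b, c = (set(s) for s in sets)
    return {
        "ab": len(a & b),
        "ac": len(a & c),
        "bc": len(b & c),
        "abc": len(a & b & c),
    }
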