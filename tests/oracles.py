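"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — O(n^2) pairwise definitions,
union-find, exhaustive enumeration — and shares no code with the package
paths it checks.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def gini_pairwise(values):
    """Gini as the pairwise mean absolute difference over twice the mean."""
    x = np.asarray(values, dtype=float)
    n = x.size
    total = np.abs(x[:, None] - x[None, :]).sum()
    return total / (2 * n * n * x.mean())


def brute_force_clone_partition(records):
    """Single-linkage clone partition by all-pairs comparison + union-find."""
    keys = sorted({(r.v_gene, r.j_gene, r.cdr3_nt) for r in records})
    parent = list(range(len(keys)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i, j in combinations(range(len(keys)), 2):
        vi, ji, si = keys[i]
        vj, jj, sj = keys[j]
        if vi != vj or ji != jj or len(si) != len(sj):
            continue
        matches = sum(a == b for a, b in zip(si, sj))
        if Fraction(matches, len(si)) >= Fraction(9, 10):
            union(i, j)

    groups = {}
    for i, key in enumerate(keys):
        groups.setdefault(find(i), set()).add(key)
    return {frozenset(g) for g in groups.values()}


def km_product_limit(times, events):
    """Kaplan-Meier estimate at each distinct event time (naive product)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


def ranksum_exact_p(a, b):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[: a.size].sum()
    ws = np.array(
        [ranks[list(c)].sum() for c in combinations(range(pooled.size), a.size)]
    )
    p = 2 * min((ws <= obs).mean(), (ws >= obs).mean())
    return min(1.0, p)


def bh_definition(p_values):
    """BH adjusted values straight from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)
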