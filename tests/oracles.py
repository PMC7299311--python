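"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit loops, exhaustive
enumeration, closed-form combinatorics.  Nothing imports the code paths it
checks.
"""

from itertools import combinations

import numpy as np


def agreement_loop(a, b, w=None):
    """Entrywise agreement count between two binary matrices, explicit loops."""
    total = 0.0
    for v in range(a.shape[0]):
        for t in range(a.shape[1]):
            if a[v, t] == b[v, t]:
                total += 1.0 if w is None else w[v, t]
    return total


def similarity_loop(stack, w=None):
    """All-pairs agreement matrix by double loop, zero diagonal."""
    n = stack.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                p[i, j] = agreement_loop(stack[i], stack[j], w)
    return p


def modularity_formula(adj, labels):
    """Newman-Girvan modularity from its definition, explicit double sum."""
    two_w = adj.sum()
    q = 0.0
    n = adj.shape[0]
    strength = adj.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] / two_w - strength[i] * strength[j] / two_w**2
    return q


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield part + [[first]]


def best_partition_exhaustive(adj):
    """Maximum-modularity partition by enumerating every partition."""
    n = adj.shape[0]
    best_q, best_labels = -np.inf, None
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        q = modularity_formula(adj, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def mwu_exact_enum(a, b):
    """Exact two-sided Mann-Whitney p-value by enumerating group assignments.

    Assumes no ties.  Two-sided p = 2 * min(P(U <= u), P(U >= u)), capped
    at 1, where U is the count of (a, b) pairs with a > b.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(n), na):
        ga = pooled[list(idx)]
        gb = pooled[[i for i in range(n) if i not in idx]]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    p_lo = (us <= u_obs).mean()
    p_hi = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_lo, p_hi))


def fisher_exact_enum(table):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):  # table [[k, r1-k], [c1-k, r2-(c1-k)]]
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))
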