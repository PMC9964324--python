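"""Independent brute-force reference implementations used only by tests.

Each oracle favours transparency over speed: explicit loops, no
vectorization, no reuse of the package's code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ssgsea_es_bruteforce(values, gene_ids, set_genes, alpha):
    """Position-by-position running-sum ES for one sample.

    Sorts genes by descending expression (gene id breaks ties), walks the
    ranked list once, and accumulates the in-set weighted CDF minus the
    out-of-set uniform CDF.
    """
    pairs = sorted(zip(values, gene_ids), key=lambda t: (-t[0], t[1]))
    n = len(pairs)
    ranks = {g: n - i for i, (_, g) in enumerate(pairs)}  # top gene gets N
    members = [g for _, g in pairs if g in set_genes]
    m = len(members)
    assert 0 < m < n
    denom_in = 0.0
    for g in members:
        denom_in += ranks[g] ** alpha
    es = 0.0
    run_in = 0.0
    run_out = 0
    for _, g in pairs:
        if g in set_genes:
            run_in += ranks[g] ** alpha
        else:
            run_out += 1
        es += run_in / denom_in - run_out / (n - m)
    return es


def bh_bruteforce(p_values):
    """BH adjusted p via the definition: min over tail of p_(j)*m/j."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        tail = []
        for j in range(rank_pos, m + 1):
            tail.append(p[order[j - 1]] * m / j)
        adjusted[idx] = min(1.0, min(tail))
    return adjusted


def tom_bruteforce(adjacency):
    """Triple-loop topological overlap; diagonal 1."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    tom = np.ones((n, n))
    for i in range(n):
        k_i = sum(a[i, u] for u in range(n) if u != i)
        for j in range(n):
            if i == j:
                continue
            k_j = sum(a[j, u] for u in range(n) if u != j)
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return tom


def ranksum_exact_p_bruteforce(a, b):
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(pooled)
    assert len(set(pooled)) == n, "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    observed = sum(ranks[v] for v in a)
    n_a = len(a)
    mean_w = n_a * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(1, n + 1), n_a):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(observed - mean_w) - 1e-12:
            count += 1
    return count / total


def km_empirical_survival(times, t):
    """Empirical survival P(T > t) for uncensored samples."""
    times = list(times)
    return sum(1 for x in times if x > t) / len(times)
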