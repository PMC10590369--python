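"""Independent brute-force oracles, written separately from the library.

These deliberately use plain Python loops and ``math`` so they share no
code path with the vectorized/scipy implementations they check.
"""

import math


def js_distance_oracle(p, q, base=2.0):
    """sqrt of 0.5*KL(p||m) + 0.5*KL(q||m), m = (p+q)/2, logs in ``base``."""

    def kl(a, b):
        total = 0.0
        for ai, bi in zip(a, b):
            if ai > 0:
                total += ai * math.log(ai / bi, base)
        return total

    m = [(pi + qi) / 2.0 for pi, qi in zip(p, q)]
    div = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return math.sqrt(max(div, 0.0))


def eq1_dissimilarity_oracle(P_i, P_j, C_i, C_j, base=2.0):
    """Nested-loop evaluation of d_ij = sum_t w_ij(t) JS(P_i(t)||P_j(t))."""
    T = len(C_i)
    denom = sum(C_i[t] * C_j[t] for t in range(T))
    if denom <= 0:
        return None
    d = 0.0
    for t in range(T):
        w = C_i[t] * C_j[t] / denom
        if w > 0:
            d += w * js_distance_oracle(P_i[t], P_j[t], base=base)
    return d


def complete_linkage_oracle(D):
    """Naive O(n^3) complete-linkage agglomerator.

    Clusters are frozensets of leaf indices; ids follow the same scheme as
    the implementation (leaves 0..n-1, merge m creates id n+m) and ties are
    broken by the lexicographically smallest id pair.  Returns the merge
    list [(id_a, id_b, height)].
    """
    n = len(D)
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for x, a in enumerate(ids):
            for b in ids[x + 1 :]:
                h = max(D[i][j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0] or (h == best[0] and (a, b) < best[1:]):
                    best = (h, a, b)
        h, a, b = best
        merges.append((a, b, h))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges
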