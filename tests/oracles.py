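"""Independent brute-force oracles used to cross-check the implementations.

These are deliberately naive: literal step-up for BH, exact rational
enumeration for the hypergeometric tail, O(n^3) UPGMA with explicit
tie-breaking, and mid-rank Spearman from first principles.  They share
no code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q[order[i]] = running
    return np.minimum(q, 1.0)


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact P(X >= k) by rational enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return float(acc)


def upgma_oracle(d: np.ndarray) -> list[tuple[frozenset, float]]:
    """Naive UPGMA: merge the closest pair (lowest-index tie-break).

    Returns the merge list as (leaf set of the new cluster, height).
    Inter-cluster distance is the unweighted mean over all cross pairs
    of the *original* dissimilarities.
    """
    n = d.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((merged, float(dist)))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def spearman_midrank_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks (ties averaged)."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
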