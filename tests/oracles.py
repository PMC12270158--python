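"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: binning via
transitive closure of the pairwise-distance graph, Kendall statistics via
O(n^2) pair counting plus the closed-form tie-corrected variance, nearest
genes via all-pairs minimisation, and the rank-sum test via exhaustive
enumeration of group assignments.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_bins(positions: np.ndarray, max_gap: int = 65) -> list[list[int]]:
    """Cluster positions by transitive closure over all pairs with distance < max_gap."""
    positions = np.asarray(positions, dtype=np.int64)
    n = positions.size
    if n == 0:
        return []
    adj = np.abs(positions[:, None] - positions[None, :]) < max_gap
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append(int(positions[i]))
    clusters = [sorted(c) for c in clusters]
    return sorted(clusters)


def kendall_pair_counts(x, y) -> tuple[int, int, int, int, int]:
    """(concordant, discordant, x-tie pairs, y-tie pairs, total pairs) by enumeration."""
    x = list(map(float, x))
    y = list(map(float, y))
    C = D = tx = ty = n0 = 0
    for i, j in combinations(range(len(x)), 2):
        n0 += 1
        dx = x[j] - x[i]
        dy = y[j] - y[i]
        if dx == 0:
            tx += 1
        if dy == 0:
            ty += 1
        if dx == 0 or dy == 0:
            continue
        if dx * dy > 0:
            C += 1
        else:
            D += 1
    return C, D, tx, ty, n0


def kendall_tau_b_oracle(x, y) -> float:
    C, D, tx, ty, n0 = kendall_pair_counts(x, y)
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        raise ZeroDivisionError("tau-b undefined")
    return (C - D) / denom


def kendall_p_oracle(x, y) -> float:
    """Two-sided asymptotic p with the tie-corrected variance of C - D."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    C, D, _, _, _ = kendall_pair_counts(x, y)
    s = C - D
    t = np.unique(x, return_counts=True)[1].astype(float)
    u = np.unique(y, return_counts=True)[1].astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(t * (t - 1) * (2 * t + 5))
    vu = np.sum(u * (u - 1) * (2 * u + 5))
    v1 = np.sum(t * (t - 1)) * np.sum(u * (u - 1)) / (2.0 * n * (n - 1))
    v2 = (
        np.sum(t * (t - 1) * (t - 2))
        * np.sum(u * (u - 1) * (u - 2))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        raise ZeroDivisionError("degenerate variance")
    z = s / math.sqrt(var)
    return math.erfc(abs(z) / math.sqrt(2.0))


def nearest_gene_oracle(
    bin_start: int, bin_end: int, genes: list[tuple[str, int, int]]
) -> tuple[str, int]:
    """All-pairs minimum gap distance; ties by |distance| then symbol."""
    best = None
    for name, gs, ge in genes:
        gap = max(gs - bin_end, bin_start - ge, 0)
        signed = gap if gs >= bin_end else (-gap if gap > 0 else 0)
        if gs < bin_end and bin_start < ge:
            signed = 0
        key = (gap, name)
        if best is None or key < best[0]:
            best = (key, name, signed)
    return best[1], best[2]


def wilcoxon_exact_oracle(a, b) -> float:
    """Two-sided rank-sum p by enumerating all C(n, n1) group assignments.

    Requires no ties. p = P(|W - mean| >= |w_obs - mean|) under the uniform
    null over assignments, where W is the rank sum of the first group.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    n = len(pooled)
    w_obs = sum(ranks[v] for v in a)
    mean = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mean)
    count = 0
    total = 0
    for idx in combinations(range(1, n + 1), n1):
        total += 1
        if abs(sum(idx) - mean) >= dev - 1e-9:
            count += 1
    return count / total
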