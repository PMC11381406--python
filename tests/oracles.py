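"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results through different algorithms than the
package (cyclic Jacobi rotations instead of LAPACK eigh; exhaustive greedy
Ward agglomeration instead of scipy linkage; bisection binning instead of
vectorised floor arithmetic) so agreement is a genuine cross-check.
"""

from __future__ import annotations

import bisect
import math

import numpy as np


def jacobi_eigenvalues(a: np.ndarray, sweeps: int = 100, tol: float = 1e-13) -> np.ndarray:
    """Eigenvalues of a symmetric matrix by cyclic Jacobi rotations, descending."""
    a = np.array(a, dtype=float)
    n = a.shape[0]
    for _ in range(sweeps):
        off = math.sqrt(sum(a[i, j] ** 2 for i in range(n) for j in range(n) if i != j))
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < 1e-16:
                    continue
                phi = 0.5 * math.atan2(2.0 * a[p, q], a[p, p] - a[q, q])
                c, s = math.cos(phi), math.sin(phi)
                g = np.eye(n)
                g[p, p] = c
                g[q, q] = c
                g[p, q] = -s
                g[q, p] = s
                a = g.T @ a @ g
    return np.sort(np.diag(a))[::-1]


def greedy_ward_merges(points: np.ndarray) -> list[frozenset]:
    """Exhaustive greedy Ward agglomeration: the merged member-set at each step.

    At every step the pair of clusters with the minimal increase in total
    within-cluster sum of squares, dESS = |A||B|/(|A|+|B|) * ||cA - cB||^2,
    is merged.
    """
    points = np.asarray(points, dtype=float)
    clusters: list[tuple[frozenset, np.ndarray, int]] = [
        (frozenset([i]), points[i].copy(), 1) for i in range(len(points))
    ]
    merges: list[frozenset] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                mi, ci, ni = clusters[i]
                mj, cj, nj = clusters[j]
                d = ni * nj / (ni + nj) * float(((ci - cj) ** 2).sum())
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        mi, ci, ni = clusters[i]
        mj, cj, nj = clusters[j]
        merged = (mi | mj, (ni * ci + nj * cj) / (ni + nj), ni + nj)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        merges.append(merged[0])
    return merges


def scipy_merge_sets(z: np.ndarray, n: int) -> list[frozenset]:
    """Member-sets merged at each row of a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row, (a, b, _, _) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + row] = merged
        out.append(merged)
    return out


def bin_level(v: float) -> int:
    """Direct binning oracle for the 5-level unit-interval grade."""
    if not (0.0 <= v <= 1.0):
        raise ValueError(v)
    return bisect.bisect_right([0.2, 0.4, 0.6, 0.8], v) + 1 if v < 1.0 else 5
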