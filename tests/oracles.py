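"""Independent reference implementations used only to check the package.

Each oracle is deliberately written along a different path from the code it
checks: UPGMA recomputes cluster distances from the original matrix as flat
means over member leaf pairs; the NNLS oracle searches a nonnegative grid;
quantiles are computed by explicit order-statistic interpolation.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_upgma(ids, dist):
    """O(n^3) UPGMA from first principles.

    Cluster distance = unweighted mean of all member-pair distances in the
    *original* matrix (mathematically identical to the size-weighted update);
    ties broken by lexicographically smallest (creation-index) pair.
    Returns a list of (left_index, right_index, height) merges using the same
    indexing convention as ClusterTree (leaves 0..n-1, then merges).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_index = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = float(
                np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            )
            key = (d, i, j)
            if best is None or key < best:
                best = key
        d, i, j = best
        merges.append((i, j, d / 2.0))
        clusters[next_index] = clusters.pop(i) + clusters.pop(j)
        next_index += 1
    return merges


def grid_nnls_objective(design, target, step=0.01, upper=None, sweeps=60):
    """Best objective ||Ax-b||^2 over the nonnegative grid {0, step, 2*step, ...}.

    Exhaustive for k <= 2; cyclic coordinate descent over the grid otherwise
    (the objective is convex, so the sweep converges to the grid optimum
    along each axis).
    """
    A = np.asarray(design, dtype=float)
    b = np.asarray(target, dtype=float)
    k = A.shape[1]
    if upper is None:
        col_norms = np.linalg.norm(A, axis=0)
        upper = 2.0 * np.linalg.norm(b) / col_norms.min()
    axis = np.arange(0.0, upper + step, step)
    if k <= 2:
        if k == 1:
            objs = np.sum((np.outer(axis, A[:, 0]) - b) ** 2, axis=1)
            return float(objs.min())
        best = np.inf
        for x0 in axis:
            r0 = b - x0 * A[:, 0]
            objs = np.sum((np.outer(axis, A[:, 1]) - r0) ** 2, axis=1)
            best = min(best, float(objs.min()))
        return best
    x = np.zeros(k)
    for _ in range(sweeps):
        changed = False
        for j in range(k):
            r = b - A @ x + x[j] * A[:, j]
            objs = np.sum((np.outer(axis, A[:, j]) - r) ** 2, axis=1)
            best = axis[int(np.argmin(objs))]
            if best != x[j]:
                x[j] = best
                changed = True
        if not changed:
            break
    r = b - A @ x
    return float(r @ r)


def kkt_violation(design, target, x):
    """Max violation of the NNLS KKT conditions at x (0 if optimal)."""
    A = np.asarray(design, dtype=float)
    b = np.asarray(target, dtype=float)
    w = A.T @ (b - A @ x)  # negative gradient / 2
    scale = max(1.0, float(np.abs(A.T @ b).max()))
    viol = 0.0
    for j in range(len(x)):
        if x[j] > 0:
            viol = max(viol, abs(w[j]) / scale)  # stationarity on the support
        else:
            viol = max(viol, max(w[j], 0.0) / scale)  # dual feasibility
    return viol


def quantile_by_sorting(values, q):
    """Linear-interpolation quantile computed from explicit order statistics."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return float(v[0])
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
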