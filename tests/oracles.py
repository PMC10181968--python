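"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain loops / exhaustive
enumeration, independent of the package's implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_density(values, mask, spacing) -> dict:
    """Per-voxel counting implementation of the density panel."""
    vals = []
    n_em = n_ggo = n_fib = 0
    nz, ny, nx = values.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                v = float(values[z, y, x])
                vals.append(v)
                if v < -950:
                    n_em += 1
                if -800 <= v < -700:
                    n_ggo += 1
                if v >= -700:
                    n_fib += 1
    n = len(vals)
    vals.sort()
    # linear-interpolation percentile
    h = 0.15 * (n - 1)
    lo = math.floor(h)
    perc15 = vals[lo] + (h - lo) * (vals[min(lo + 1, n - 1)] - vals[lo])
    return {
        "voxel_count": n,
        "volume_ml": n * spacing[0] * spacing[1] * spacing[2] / 1000.0,
        "mld_hu": sum(vals) / n,
        "ei_pct": 100.0 * n_em / n,
        "ggoi_pct": 100.0 * n_ggo / n,
        "fibi_pct": 100.0 * n_fib / n,
        "perc15_hu": perc15,
    }


def flood_fill_clusters(emph: np.ndarray) -> list[int]:
    """26-connected cluster voxel counts via breadth-first flood fill."""
    emph = np.asarray(emph, dtype=bool)
    seen = np.zeros_like(emph)
    shape = emph.shape
    neigh = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    sizes = []
    for start in zip(*np.nonzero(emph)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        count = 0
        while stack:
            z, y, x = stack.pop()
            count += 1
            for dz, dy, dx in neigh:
                q = (z + dz, y + dy, x + dx)
                if (
                    0 <= q[0] < shape[0]
                    and 0 <= q[1] < shape[1]
                    and 0 <= q[2] < shape[2]
                    and emph[q]
                    and not seen[q]
                ):
                    seen[q] = True
                    stack.append(q)
        sizes.append(count)
    return sorted(sizes)


def brute_distance_to_outside(mask: np.ndarray, spacing) -> np.ndarray:
    """Exact Euclidean distance of each mask voxel to the nearest non-mask
    voxel, by exhaustive pairwise search. Only for tiny masks."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape)
    bg = np.argwhere(~mask).astype(float) * np.asarray(spacing)
    for idx in np.argwhere(mask):
        p = idx.astype(float) * np.asarray(spacing)
        out[tuple(idx)] = np.sqrt(((bg - p) ** 2).sum(axis=1)).min()
    return out


def wilcoxon_exact_two_sided(diffs) -> float:
    """Exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = _rank(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = 2**n
    mean = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / total


def mannwhitney_exact_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(idx: tuple) -> float:
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = u_stat(tuple(range(n)))
    mean = n * m / 2.0
    us = [u_stat(c) for c in itertools.combinations(range(n + m), n)]
    count = sum(1 for u in us if abs(u - mean) >= abs(u_obs - mean) - 1e-12)
    return count / len(us)


def _rank(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a))
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j < len(a) and sorted_a[j] == sorted_a[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def logistic_mle_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct likelihood maximization with a generic optimizer."""
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def nll(beta):
        eta = X @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
    return res.x
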