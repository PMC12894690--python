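"""Slow, transparent reference implementations used for cross-validation.

Each function here recomputes a quantity by the most literal route available
(explicit loops, dense graph search, rank-then-Pearson) so that the optimised
pipeline can be checked against an independent computation.  None of these is
used by the pipeline itself.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

__all__ = [
    "dijkstra_arrival",
    "dot_product_loop",
    "rank_then_pearson",
    "kl_closed_form",
]


def dijkstra_arrival(
    speed: np.ndarray,
    seeds,
    spacing=(1.0, 1.0, 1.0),
    speed_floor: float | None = 1e-3,
) -> np.ndarray:
    """Dijkstra shortest-path arrival times on the dense 26-neighbourhood.

    Edge cost between adjacent voxels u, v is the Euclidean step length times
    the mean slowness ``(1/F_u + 1/F_v) / 2``.  With a dense neighbourhood
    this graph distance approximates the continuous geodesic the eikonal
    solver discretises, providing an independent oracle.
    """
    speed = np.asarray(speed, dtype=np.float64)
    if speed_floor is not None:
        speed = np.maximum(speed, float(speed_floor))
    spacing = np.asarray(spacing, dtype=np.float64)
    shape = speed.shape
    inv_f = 1.0 / speed
    offsets = [
        np.array(o)
        for o in itertools.product((-1, 0, 1), repeat=3)
        if any(o)
    ]
    steps = [np.linalg.norm(np.asarray(o) * spacing) for o in offsets]

    dist = np.full(shape, np.inf)
    heap = []
    for s in np.atleast_2d(np.asarray(seeds, dtype=np.intp)):
        dist[tuple(s)] = 0.0
        heapq.heappush(heap, (0.0, tuple(int(x) for x in s)))
    done = np.zeros(shape, dtype=bool)
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for off, length in zip(offsets, steps):
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if not all(0 <= v[a] < shape[a] for a in range(3)):
                continue
            if done[v]:
                continue
            nd = d + length * 0.5 * (inv_f[u] + inv_f[v])
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def dot_product_loop(substrate: np.ndarray, cpm: np.ndarray) -> float:
    """Explicit voxel-by-voxel dot product (triple loop)."""
    if substrate.shape != cpm.shape:
        raise ValueError("grid mismatch")
    total = 0.0
    for i in range(substrate.shape[0]):
        for j in range(substrate.shape[1]):
            for k in range(substrate.shape[2]):
                total += float(substrate[i, j, k]) * float(cpm[i, j, k])
    return total


def rank_then_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman's rho computed literally: mid-rank both vectors, Pearson."""
    from scipy.stats import rankdata

    ra = rankdata(a, method="average")
    rb = rankdata(b, method="average")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float((ra * rb).sum() / denom)


def kl_closed_form(mean: np.ndarray, sd: np.ndarray) -> float:
    """KL( N(mean, sd^2) || N(0, I) ) = 1/2 sum(mu^2 + sd^2 - 1 - ln sd^2)."""
    mean = np.asarray(mean, dtype=np.float64)
    sd = np.asarray(sd, dtype=np.float64)
    return float(0.5 * np.sum(mean**2 + sd**2 - 1.0 - np.log(sd**2)))
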