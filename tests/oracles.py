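"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (loops,
prefix sums, exhaustive search) and never calls the implementation under
test.
"""

from __future__ import annotations

import numpy as np


def exhaustive_otsu3(values: np.ndarray, nbins: int = 256):
    """Exhaustive search over all (t1 < t2) bin pairs maximizing the
    between-class variance of a three-way split of a ``nbins``-bin
    histogram.  Returns (best objective, (t1, t2) bin-centre thresholds).

    Maximizing sum_k w_k mu_k^2 is equivalent to maximizing the
    between-class variance since the total mean is fixed.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist / hist.sum()
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * centers)])
    best = (-np.inf, None)
    for t1 in range(nbins - 2):
        w0 = cw[t1 + 1]
        if w0 == 0:
            continue
        m0 = cwx[t1 + 1] / w0
        t2 = np.arange(t1 + 1, nbins - 1)
        w1 = cw[t2 + 1] - cw[t1 + 1]
        w2 = cw[-1] - cw[t2 + 1]
        ok = (w1 > 0) & (w2 > 0)
        if not ok.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            m1 = (cwx[t2 + 1] - cwx[t1 + 1]) / w1
            m2 = (cwx[-1] - cwx[t2 + 1]) / w2
        obj = np.where(ok, w0 * m0 ** 2 + w1 * m1 ** 2 + w2 * m2 ** 2, -np.inf)
        j = int(np.argmax(obj))
        if obj[j] > best[0]:
            best = (float(obj[j]), (centers[t1], centers[t2[j]]))
    return best


def otsu3_objective(values: np.ndarray, thresholds, nbins: int = 256) -> float:
    """sum_k w_k mu_k^2 attained by a given threshold pair on the same histogram."""
    values = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist / hist.sum()
    t1, t2 = thresholds
    obj = 0.0
    for m in (centers <= t1, (centers > t1) & (centers <= t2), centers > t2):
        wk = w[m].sum()
        if wk == 0:
            return -np.inf
        mk = (w[m] * centers[m]).sum() / wk
        obj += wk * mk ** 2
    return float(obj)


def bfs_steps(n_vertices: int, edges, source: int) -> np.ndarray:
    """Plain queue-based BFS hop counts; -1 for unreachable vertices."""
    adj = [[] for _ in range(n_vertices)]
    for a, b in edges:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    dist = np.full(n_vertices, -1, dtype=np.int64)
    dist[source] = 0
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    return dist


def point_segment_distance(p, a, b) -> float:
    """Distance from a point to one segment, scalar arithmetic only."""
    p, a, b = (np.asarray(x, dtype=np.float64) for x in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = min(max(float((p - a) @ ab) / denom, 0.0), 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def mean_min_segment_distance(points, seg_a, seg_b) -> float:
    """Double loop over samples x segments: mean of per-point min distances."""
    out = []
    for p in points:
        out.append(min(point_segment_distance(p, a, b)
                       for a, b in zip(seg_a, seg_b)))
    return float(np.mean(out))
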