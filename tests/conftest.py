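"""Shared fixtures and independent reference (oracle) implementations.

The oracles here deliberately use naive, per-definition computations so the
package's vectorised implementations are checked against an independent
route: dense arc-length resampling for Sholl counts, explicit O(n^3)
agglomeration for Ward clustering, exhaustive enumeration for k-means/PAM,
and per-definition cluster validation indices.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from astromorph import make_skeleton
from astromorph.skeleton import AstrocyteSkeleton


# ---------------------------------------------------------------------------
# skeleton builders
# ---------------------------------------------------------------------------

def build_skeleton(nodes, cell_id="test"):
    """Build a skeleton from rows (id, type, x, y, z, radius, parent)."""
    arr = np.asarray(nodes, dtype=float)
    return make_skeleton(
        cell_id=cell_id,
        ids=arr[:, 0].astype(int),
        type_code=arr[:, 1].astype(int),
        xyz=arr[:, 2:5],
        radius=arr[:, 5],
        parent_ids=arr[:, 6].astype(int),
    )


@pytest.fixture
def star5():
    """Five straight 20-um arms from the soma, no bifurcations."""
    dirs = [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
    ]
    rows = [(1, 1, 0, 0, 0, 2.0, -1)]
    nid = 2
    for dx, dy, dz in dirs:
        parent = 1
        for seg in range(1, 21):
            rows.append((nid, 3, dx * seg, dy * seg, dz * seg, 0.5, parent))
            parent = nid
            nid += 1
    return build_skeleton(rows, "star5")


@pytest.fixture
def y_tree():
    """One 5-um stem bifurcating once into two daughters."""
    rows = [(1, 1, 0, 0, 0, 2.0, -1)]
    parent = 1
    nid = 2
    for seg in range(1, 6):  # stem along +x to (5,0,0)
        rows.append((nid, 3, seg, 0, 0, 0.5, parent))
        parent = nid
        nid += 1
    fork = parent
    for sign in (1, -1):
        parent = fork
        for seg in range(1, 6):
            rows.append(
                (nid, 3, 5 + seg * 0.8, sign * seg * 0.6, 0, 0.4, parent)
            )
            parent = nid
            nid += 1
    return build_skeleton(rows, "ytree")


@pytest.fixture
def four_bifurcating():
    """Four primaries, each bifurcating once at 5 um into arms to 15 um."""
    dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]
    rows = [(1, 1, 0, 0, 0, 2.0, -1)]
    nid = 2
    for dx, dy, dz in dirs:
        parent = 1
        for seg in range(1, 6):
            rows.append((nid, 3, dx * seg, dy * seg, dz * seg, 0.5, parent))
            parent = nid
            nid += 1
        fork = parent
        # orthogonal offsets so the two arms diverge
        ox, oy = (-dy, dx)
        for s in (1.0, -1.0):
            parent = fork
            for seg in range(1, 11):
                x = dx * (5 + seg * 0.9) + ox * s * seg * 0.43
                y = dy * (5 + seg * 0.9) + oy * s * seg * 0.43
                rows.append((nid, 3, x, y, dz * (5 + seg), 0.4, parent))
                parent = nid
                nid += 1
    return build_skeleton(rows, "four_bif")


# ---------------------------------------------------------------------------
# Sholl oracle: dense arc-length resampling
# ---------------------------------------------------------------------------

def sholl_dense_oracle(
    skeleton: AstrocyteSkeleton, step: float = 1.0, ds: float = 0.001
) -> np.ndarray:
    """Sholl counts by resampling every process edge at ``ds`` arc-length.

    Each edge polyline is sampled densely; crossings of the sphere of radius
    k*step are counted per micro-segment with the half-open rule
    min(d) < r <= max(d).  Returns counts for radii step..R_max*step.
    """
    from astromorph.morphometry import _process_edges

    edges = _process_edges(skeleton)
    if len(edges) == 0:
        return np.zeros(0, dtype=int)
    centre = skeleton.xyz[skeleton.root_index]
    diff = np.zeros(1, dtype=np.int64)
    for child, parent in edges:
        p = skeleton.xyz[parent] - centre
        q = skeleton.xyz[child] - centre
        length = float(np.linalg.norm(q - p))
        n = max(int(np.ceil(length / ds)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        d = np.linalg.norm(p[None, :] + t[:, None] * (q - p)[None, :], axis=1)
        lo = np.minimum(d[:-1], d[1:])
        hi = np.maximum(d[:-1], d[1:])
        k_lo = np.floor(lo / step).astype(np.int64) + 1
        k_hi = np.floor(hi / step).astype(np.int64)
        keep = k_hi >= k_lo
        k_lo, k_hi = k_lo[keep], k_hi[keep]
        if len(k_lo) == 0:
            continue
        need = int(k_hi.max()) + 2
        if need > len(diff):
            diff = np.concatenate([diff, np.zeros(need - len(diff), np.int64)])
        np.add.at(diff, k_lo, 1)
        np.add.at(diff, k_hi + 1, -1)
    counts = np.cumsum(diff)[1:]
    nz = np.flatnonzero(counts)
    return counts[: nz[-1] + 1] if len(nz) else np.zeros(0, dtype=int)


# ---------------------------------------------------------------------------
# clustering oracles
# ---------------------------------------------------------------------------

def ward_naive(points: np.ndarray, k: int) -> np.ndarray:
    """O(n^3) Ward agglomeration by the Lance-Williams update, labels 1..k."""
    points = np.asarray(points, float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    centroids = {i: points[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}

    def merge_cost(a, b):
        na, nb = sizes[a], sizes[b]
        d2 = float(((centroids[a] - centroids[b]) ** 2).sum())
        return na * nb / (na + nb) * d2

    heights = []
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            c = merge_cost(a, b)
            if best is None or c < best[0] - 1e-12:
                best = (c, a, b)
        c, a, b = best
        heights.append(c)
        na, nb = sizes[a], sizes[b]
        centroids[a] = (na * centroids[a] + nb * centroids[b]) / (na + nb)
        clusters[a] = clusters[a] + clusters[b]
        sizes[a] = na + nb
        del clusters[b], centroids[b], sizes[b]
    labels = np.empty(n, dtype=int)
    for new_id, key in enumerate(sorted(clusters), start=1):
        labels[np.asarray(clusters[key])] = new_id
    return labels


def best_partition_wss(points: np.ndarray, k: int = 2):
    """Exhaustive minimum within-cluster sum of squares over all k-partitions."""
    points = np.asarray(points, float)
    n = len(points)
    best = (np.inf, None)
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        lab = np.asarray(assignment)
        wss = 0.0
        for c in range(k):
            sub = points[lab == c]
            wss += ((sub - sub.mean(axis=0)) ** 2).sum()
        if wss < best[0]:
            best = (wss, lab + 1)
    return best


def best_medoids(points: np.ndarray, k: int):
    """Exhaustive minimum PAM cost over all medoid subsets of size k."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(np.asarray(points, float)))
    best = (np.inf, None)
    for subset in itertools.combinations(range(len(points)), k):
        cost = D[:, subset].min(axis=1).sum()
        if cost < best[0]:
            best = (cost, subset)
    return best


def indices_reference(points: np.ndarray, labels: np.ndarray, L: int = 10):
    """Per-definition connectivity, Dunn and silhouette (naive loops)."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    n = len(points)
    D = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    # connectivity
    conn = 0.0
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i), key=lambda j: (D[i, j], j)
        )[: min(L, n - 1)]
        for rank, j in enumerate(order, start=1):
            if labels[j] != labels[i]:
                conn += 1.0 / rank
    # dunn
    uniq = sorted(set(labels.tolist()))
    diam = max(
        (
            D[i, j]
            for c in uniq
            for i in range(n)
            for j in range(n)
            if labels[i] == c and labels[j] == c
        ),
        default=0.0,
    )
    inter = min(
        (
            D[i, j]
            for i in range(n)
            for j in range(n)
            if labels[i] != labels[j]
        ),
        default=np.inf,
    )
    dunn = 0.0 if diam == 0 else inter / diam
    # silhouette
    sil = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            sil.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in uniq
            if c != labels[i]
        )
        sil.append((b - a) / max(a, b))
    return conn, dunn, float(np.mean(sil))
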