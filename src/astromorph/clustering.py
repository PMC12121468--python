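"""Morphotype clustering in retained principal-component space.

Four algorithms are compared — agglomerative hierarchical clustering,
k-means, partitioning around medoids (PAM) and a one-dimensional
self-organizing map (SOM) — scored with internal validation indices
(connectivity, Dunn index, mean silhouette width).  The number of clusters
is chosen by majority vote of a panel of eight internal indices, ties
broken toward the smaller k.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("hierarchical", "kmeans", "pam", "som")

DEFAULT_PANEL = (
    "calinski_harabasz",
    "silhouette",
    "dunn",
    "davies_bouldin",
    "gap",
    "hartigan",
    "c_index",
    "krzanowski_lai",
)


@dataclass
class ClusterSolution:
    """A partition of cells into k non-empty clusters labelled 1..k."""

    algorithm: str
    k: int
    labels: np.ndarray
    centers: np.ndarray | None = None  # centroids, medoids or SOM units
    linkage_matrix: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels).tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must cover exactly 1..{self.k}, got {sorted(present)}"
            )


@dataclass
class ValidationReport:
    """Index values per (algorithm, k), the k vote, and the chosen solution."""

    index_table: pd.DataFrame
    votes: dict[str, int] = field(default_factory=dict)
    vote_counts: dict[int, int] = field(default_factory=dict)
    chosen_k: int | None = None
    chosen_algorithm: str | None = None


# ---------------------------------------------------------------------------
# algorithms
# ---------------------------------------------------------------------------

def hcluster(
    points: np.ndarray, k: int, linkage_method: str = "ward"
) -> ClusterSolution:
    """Agglomerative clustering on Euclidean distances, cut at k clusters."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    Z = linkage(points, method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterSolution(
        algorithm="hierarchical",
        k=k,
        labels=_canonical_labels(labels),
        linkage_matrix=Z,
    )


def kmeans_fit(
    points: np.ndarray, k: int, n_restarts: int = 25, seed: int | None = None
) -> ClusterSolution:
    """Best-of-restarts Lloyd k-means (within-cluster sum of squares)."""
    points = np.asarray(points, dtype=float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(points) + 1
    return ClusterSolution(
        algorithm="kmeans",
        k=k,
        labels=_canonical_labels(labels),
        centers=km.cluster_centers_,
        seed=seed,
    )


def pam_fit(points: np.ndarray, k: int, seed: int | None = None) -> ClusterSolution:
    """Partitioning around medoids: greedy BUILD then SWAP to a local optimum.

    Medoids are data points; the objective is the total Euclidean distance of
    every point to its closest medoid.  SWAP examines every (medoid,
    non-medoid) exchange and applies the best strictly improving one until
    none remains, which is deterministic, so ``seed`` is recorded but unused.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    D = squareform(pdist(points))
    # BUILD: first medoid minimises total distance, then greedy additions
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    # SWAP
    improved = True
    while improved:
        improved = False
        best_cost = D[:, medoids_arr].min(axis=1).sum()
        best_swap = None
        for mi, m in enumerate(medoids_arr):
            others = np.delete(medoids_arr, mi)
            for h in range(n):
                if h in medoids_arr:
                    continue
                cand = np.append(others, h)
                cost = D[:, cand].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_swap = (mi, h)
        if best_swap is not None:
            medoids_arr[best_swap[0]] = best_swap[1]
            medoids_arr = np.sort(medoids_arr)
            improved = True
    labels = np.argmin(D[:, medoids_arr], axis=1) + 1
    return ClusterSolution(
        algorithm="pam",
        k=k,
        labels=_canonical_labels(labels),
        centers=points[medoids_arr],
        seed=seed,
    )


def som_fit(
    points: np.ndarray,
    k: int,
    epochs: int = 50,
    seed: int | None = None,
    lr: tuple[float, float] = (0.5, 0.01),
    radius: tuple[float, float] | None = None,
) -> ClusterSolution:
    """Online self-organizing map on a k x 1 grid.

    Learning rate and (Gaussian) neighbourhood radius decay linearly over
    epochs; cells are labelled by their best-matching unit.  With the
    neighbourhood radius forced to 0 the update rule reduces to online
    k-means.  Deterministic for a fixed seed.
    """
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    n, d = points.shape
    if radius is None:
        radius = (max(k / 2.0, 1.0), 0.0)
    # init units on the first principal axis of the data
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    qs = np.quantile(proj, np.linspace(0.1, 0.9, k))
    units = points.mean(axis=0) + np.outer(qs, vt[0])
    grid = np.arange(k, dtype=float)
    total_steps = epochs * n
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / max(total_steps - 1, 1)
            eta = lr[0] + (lr[1] - lr[0]) * frac
            sigma = radius[0] + (radius[1] - radius[0]) * frac
            x = points[i]
            bmu = int(np.argmin(((units - x) ** 2).sum(axis=1)))
            if sigma <= 1e-12:
                h = (grid == grid[bmu]).astype(float)
            else:
                h = np.exp(-((grid - grid[bmu]) ** 2) / (2 * sigma**2))
            units += eta * h[:, None] * (x - units)
            step += 1
    bmus = np.argmin(
        ((points[:, None, :] - units[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    occupied = np.unique(bmus)
    if len(occupied) < k:
        logger.warning(
            "SOM: %d of %d units empty; relabelling over occupied units",
            k - len(occupied),
            k,
        )
        remap = {u: j for j, u in enumerate(occupied)}
        bmus = np.array([remap[b] for b in bmus])
        units = units[occupied]
    labels = bmus + 1
    return ClusterSolution(
        algorithm="som",
        k=len(np.unique(labels)),
        labels=_canonical_labels(labels),
        centers=units,
        seed=seed,
    )


def fit_algorithm(
    points: np.ndarray,
    algorithm: str,
    k: int,
    seed: int | None = None,
    linkage_method: str = "ward",
) -> ClusterSolution:
    """Dispatch to one of the four clustering algorithms."""
    if algorithm == "hierarchical":
        return hcluster(points, k, linkage_method=linkage_method)
    if algorithm == "kmeans":
        return kmeans_fit(points, k, seed=seed)
    if algorithm == "pam":
        return pam_fit(points, k, seed=seed)
    if algorithm == "som":
        return som_fit(points, k, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (stable canonical form)."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# internal validation indices
# ---------------------------------------------------------------------------

def connectivity_index(
    points: np.ndarray, labels: np.ndarray, n_neighbors: int = 10
) -> float:
    """Connectivity (lower is better): sum over points and neighbour ranks j
    of 1/j whenever the j-th nearest neighbour lies in another cluster."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    L = min(n_neighbors, n - 1)
    D = squareform(pdist(points))
    np.fill_diagonal(D, np.inf)
    total = 0.0
    for i in range(n):
        order = np.argsort(D[i], kind="stable")[:L]
        for j, nb in enumerate(order, start=1):
            if labels[nb] != labels[i]:
                total += 1.0 / j
    return total


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min inter-cluster point distance / max intra diameter.

    Degenerate partitions with zero maximum diameter return 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    D = squareform(pdist(points))
    uniq = np.unique(labels)
    max_diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, D[np.ix_(idx, idx)].max())
    if max_diam == 0.0:
        logger.warning("Dunn index degenerate: zero intra-cluster diameter")
        return 0.0
    min_inter = np.inf
    for a in range(len(uniq)):
        ia = np.flatnonzero(labels == uniq[a])
        for b in range(a + 1, len(uniq)):
            ib = np.flatnonzero(labels == uniq[b])
            min_inter = min(min_inter, D[np.ix_(ia, ib)].min())
    return float(min_inter / max_diam)


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton-cluster points contribute 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    return float(silhouette_samples(np.asarray(points, float), labels).mean())


def validation_indices(
    points: np.ndarray, solution: ClusterSolution, n_neighbors: int = 10
) -> tuple[float, float, float]:
    """(connectivity, dunn, silhouette) for one clustering solution."""
    return (
        connectivity_index(points, solution.labels, n_neighbors=n_neighbors),
        dunn_index(points, solution.labels),
        mean_silhouette(points, solution.labels),
    )


# ---------------------------------------------------------------------------
# k selection: eight-index panel with majority vote
# ---------------------------------------------------------------------------

def _wss(points: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to centroids."""
    total = 0.0
    for c in np.unique(labels):
        sub = points[labels == c]
        total += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(total)


def _gap_statistic(
    points: np.ndarray,
    labels_by_k: dict[int, np.ndarray],
    n_ref: int,
    rng: np.random.Generator,
    algorithm: str,
    linkage_method: str,
) -> int:
    """Gap statistic with uniform (feature-range box) reference sets.

    Chooses the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}; falls back to
    the k with the largest gap when the inequality never holds.
    """
    ks = sorted(labels_by_k)
    log_w = {k: np.log(_wss(points, labels_by_k[k])) for k in ks}
    lo, hi = points.min(axis=0), points.max(axis=0)
    ref_log_w = {k: np.empty(n_ref) for k in ks}
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=points.shape)
        for k in ks:
            sol = fit_algorithm(
                ref, algorithm, k,
                seed=int(rng.integers(2**31)), linkage_method=linkage_method,
            )
            ref_log_w[k][b] = np.log(_wss(ref, sol.labels))
    gap = {k: ref_log_w[k].mean() - log_w[k] for k in ks}
    s = {
        k: ref_log_w[k].std(ddof=0) * np.sqrt(1 + 1 / n_ref) for k in ks
    }
    for k in ks[:-1]:
        if gap[k] >= gap[k + 1] - s[k + 1]:
            return k
    return max(gap, key=lambda k: gap[k])


def select_k(
    points: np.ndarray,
    k_range: range | tuple[int, int] = (2, 8),
    panel: tuple[str, ...] = DEFAULT_PANEL,
    algorithm: str = "hierarchical",
    linkage_method: str = "ward",
    seed: int | None = None,
    n_ref: int = 50,
) -> ValidationReport:
    """Choose the number of clusters by majority vote of an index panel.

    Each index in the panel votes for its optimal k within ``k_range``
    (labels produced by ``algorithm`` at each k); the winning k is the mode,
    ties broken toward smaller k.  A pathological all-way tie falls back to
    the silhouette's k with a warning.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if isinstance(k_range, range):
        ks = list(k_range)
    else:
        ks = list(range(k_range[0], k_range[1] + 1))
    if not ks or ks[0] < 2 or ks[-1] >= n:
        raise ValueError(f"k_range must lie within [2, n-1], got {ks}")
    rng = np.random.default_rng(seed)

    # labels at every k in the range, plus flanking ks for Hartigan / KL
    extended = sorted(set(ks) | {ks[-1] + 1} | ({ks[0] - 1} - {0, 1}))
    labels_by_k: dict[int, np.ndarray] = {}
    for k in extended:
        if k >= n:
            continue
        sol = fit_algorithm(
            points, algorithm, k,
            seed=None if seed is None else seed + k,
            linkage_method=linkage_method,
        )
        labels_by_k[k] = sol.labels
    wss = {k: _wss(points, lab) for k, lab in labels_by_k.items()}
    wss[1] = float(((points - points.mean(axis=0)) ** 2).sum())

    rows = []
    for k in ks:
        lab = labels_by_k[k]
        rows.append(
            {
                "k": k,
                "calinski_harabasz": calinski_harabasz_score(points, lab),
                "silhouette": mean_silhouette(points, lab),
                "dunn": dunn_index(points, lab),
                "davies_bouldin": davies_bouldin_score(points, lab),
            }
        )
    table = pd.DataFrame(rows).set_index("k")

    votes: dict[str, int] = {}
    if "calinski_harabasz" in panel:
        votes["calinski_harabasz"] = int(table["calinski_harabasz"].idxmax())
    if "silhouette" in panel:
        votes["silhouette"] = int(table["silhouette"].idxmax())
    if "dunn" in panel:
        votes["dunn"] = int(table["dunn"].idxmax())
    if "davies_bouldin" in panel:
        votes["davies_bouldin"] = int(table["davies_bouldin"].idxmin())
    if "gap" in panel:
        votes["gap"] = _gap_statistic(
            points, {k: labels_by_k[k] for k in ks}, n_ref, rng,
            algorithm, linkage_method,
        )
    if "hartigan" in panel:
        votes["hartigan"] = _hartigan_rule(wss, ks, n)
    if "c_index" in panel:
        votes["c_index"] = _c_index_vote(points, labels_by_k, ks)
    if "krzanowski_lai" in panel:
        votes["krzanowski_lai"] = _krzanowski_lai(wss, ks, d)

    counts = Counter(votes.values())
    top = max(counts.values())
    winners = sorted(k for k, c in counts.items() if c == top)
    if len(winners) == len(counts) and len(counts) > 1:
        logger.warning("k vote is an all-way tie; falling back to silhouette")
        chosen = votes.get("silhouette", winners[0])
    else:
        chosen = winners[0]
    report = ValidationReport(
        index_table=table,
        votes=votes,
        vote_counts=dict(counts),
        chosen_k=int(chosen),
        chosen_algorithm=algorithm,
    )
    logger.info("k-selection votes %s -> chosen k=%d", votes, chosen)
    return report


def _hartigan_rule(wss: dict[int, float], ks: list[int], n: int) -> int:
    """Smallest k with Hartigan statistic <= 10 (else the largest k tried)."""
    for k in ks:
        w_next = wss.get(k + 1)
        if w_next is None or w_next <= 0:
            continue
        h = (wss[k] / w_next - 1.0) * (n - k - 1)
        if h <= 10.0:
            return k
    return ks[-1]


def _c_index_vote(
    points: np.ndarray, labels_by_k: dict[int, np.ndarray], ks: list[int]
) -> int:
    """k minimising the C-index (within-cluster distance sum, range-scaled)."""
    dists = np.sort(pdist(points))
    cumulative = np.concatenate([[0.0], np.cumsum(dists)])
    best_k, best_c = ks[0], np.inf
    for k in ks:
        labels = labels_by_k[k]
        D = squareform(pdist(points))
        s_w, n_w = 0.0, 0
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if len(idx) > 1:
                sub = D[np.ix_(idx, idx)]
                s_w += sub[np.triu_indices(len(idx), 1)].sum()
                n_w += len(idx) * (len(idx) - 1) // 2
        if n_w == 0:
            continue
        s_min = cumulative[n_w]
        s_max = cumulative[-1] - cumulative[len(dists) - n_w]
        denom = s_max - s_min
        c_val = (s_w - s_min) / denom if denom > 0 else 0.0
        if c_val < best_c:
            best_c, best_k = c_val, k
    return best_k


def _krzanowski_lai(wss: dict[int, float], ks: list[int], d: int) -> int:
    """k maximising the Krzanowski-Lai ratio |DIFF(k)/DIFF(k+1)|."""

    def diff(k: int) -> float | None:
        if (k - 1) not in wss or k not in wss:
            return None
        return (k - 1) ** (2.0 / d) * wss[k - 1] - k ** (2.0 / d) * wss[k]

    best_k, best_kl = ks[0], -np.inf
    for k in ks:
        d_k, d_k1 = diff(k), diff(k + 1)
        if d_k is None or d_k1 is None or abs(d_k1) < 1e-300:
            continue
        kl = abs(d_k / d_k1)
        if kl > best_kl:
            best_kl, best_k = kl, k
    return best_k


# ---------------------------------------------------------------------------
# algorithm selection
# ---------------------------------------------------------------------------

def select_algorithm(
    points: np.ndarray,
    k: int,
    candidates: tuple[str, ...] = ALGORITHMS,
    seed: int | None = None,
    linkage_method: str = "ward",
) -> tuple[ClusterSolution, ValidationReport]:
    """Fit each candidate at k and rank by internal validation indices.

    Each of connectivity (negated: lower is better), Dunn and mean
    silhouette is standardized across candidates; the winner has the best
    mean standardized score.
    """
    points = np.asarray(points, dtype=float)
    solutions: dict[str, ClusterSolution] = {}
    rows = []
    for i, alg in enumerate(candidates):
        sol = fit_algorithm(
            points, alg, k,
            seed=None if seed is None else seed + i,
            linkage_method=linkage_method,
        )
        conn, dunn, sil = validation_indices(points, sol)
        solutions[alg] = sol
        rows.append(
            {"algorithm": alg, "connectivity": conn, "dunn": dunn,
             "silhouette": sil}
        )
    table = pd.DataFrame(rows).set_index("algorithm")
    scored = pd.DataFrame(
        {
            "connectivity": -table["connectivity"],
            "dunn": table["dunn"],
            "silhouette": table["silhouette"],
        }
    )
    sds = scored.std(ddof=0).replace(0.0, 1.0)
    z = (scored - scored.mean()) / sds
    mean_score = z.mean(axis=1)
    winner = mean_score.idxmax()
    report = ValidationReport(
        index_table=table.assign(mean_standardized=mean_score),
        chosen_k=k,
        chosen_algorithm=str(winner),
    )
    logger.info("algorithm selection at k=%d: %s wins", k, winner)
    return solutions[str(winner)], report
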