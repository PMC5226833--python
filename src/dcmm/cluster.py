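"""Ensemble clustering of inter-basin transitions via kinetic arrows.

Each switch of the decoded internal state links two homogeneous
components; concatenating their log off-diagonal rates (the N(N-1)
"before" rates followed by the N(N-1) "after" rates, in fixed (a, b)
lexicographic order) gives a 2N(N-1)-dimensional *kinetic arrow*.  At
equilibrium every transition class has an antiparallel partner, so the
arrow set should split into mirror pairs: the mirror operator swaps the
before/after blocks.  k-means in arrow space followed by an exhaustive
search over perfect matchings of clusters into antiparallel pairs
yields the centroid pairing distance D_c(K) and the element-level
pairing score D(K); the optimal number of transition classes is
K* = argmin D(K) over even K, subject to a minimum-cluster-size rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "KineticArrow",
    "ClusterScan",
    "mirror",
    "build_arrows",
    "kmeans_arrows",
    "pair_centroids",
    "pairing_score",
    "select_clusters",
    "landscape_graph",
    "perfect_matchings",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticArrow:
    """One inter-basin transition in log-rate space.

    vector : 2*N*(N-1) natural-log per-frame rates (before block, then
    after block).  source/target identify the flanking components.
    """

    trace_id: str
    vector: np.ndarray
    source_label: int
    target_label: int
    source_interval: tuple
    target_interval: tuple

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("arrow coordinates must be finite (regularize rates)")
        object.__setattr__(self, "vector", v)

    @property
    def dim(self) -> int:
        return len(self.vector)


@dataclass
class ClusterScan:
    """D(K) scan over even cluster counts."""

    K_values: list
    assignments: dict
    centroids: dict
    S_star: dict
    D_c: dict
    D: dict
    eligible: dict
    K_star: int | None


def mirror(v):
    """Swap the before/after halves of an arrow vector (an involution)."""
    v = np.asarray(v, dtype=float)
    h = v.shape[-1] // 2
    return np.concatenate([v[..., h:], v[..., :h]], axis=-1)


def _offdiag_log_rates(rates):
    """Off-diagonal entries in (a, b) lexicographic order, natural log."""
    rates = np.asarray(rates, dtype=float)
    N = rates.shape[0]
    mask = ~np.eye(N, dtype=bool)
    return np.log(rates[mask])


def build_arrows(components_by_trace):
    """One arrow per adjacent component pair with differing labels.

    components_by_trace : mapping trace_id -> time-ordered component
    list (or an iterable of such lists).  Traces with a single
    component contribute nothing.  Component pairs that are not
    contiguous in time (e.g. because a low-confidence component between
    them was filtered out) are skipped.
    """
    if not isinstance(components_by_trace, dict):
        components_by_trace = {
            str(i): comps for i, comps in enumerate(components_by_trace)
        }
    arrows = []
    for trace_id, comps in components_by_trace.items():
        for before, after in zip(comps, comps[1:]):
            if before.label == after.label or before.t_end != after.t_start:
                continue
            vec = np.concatenate(
                [_offdiag_log_rates(before.rates), _offdiag_log_rates(after.rates)]
            )
            arrows.append(
                KineticArrow(
                    trace_id=trace_id,
                    vector=vec,
                    source_label=before.label,
                    target_label=after.label,
                    source_interval=(before.t_start, before.t_end),
                    target_interval=(after.t_start, after.t_end),
                )
            )
    return arrows


def _arrow_matrix(arrows):
    return np.array([a.vector for a in arrows])


def _kmedians(X, K, n_init, rng):
    """Lloyd iteration with city-block distance and median centroids."""
    best_inertia, best = np.inf, None
    for _ in range(n_init):
        centers = X[rng.choice(len(X), K, replace=False)]
        for _ in range(300):
            d = np.abs(X[:, None, :] - centers[None]).sum(axis=2)
            labels = d.argmin(axis=1)
            new = centers.copy()
            for k in range(K):
                pts = X[labels == k]
                if len(pts):
                    new[k] = np.median(pts, axis=0)
            if np.allclose(new, centers):
                break
            centers = new
        inertia = np.abs(X - centers[labels]).sum()
        if inertia < best_inertia:
            best_inertia, best = inertia, (labels, centers)
    return best[0], best[1], best_inertia


def kmeans_arrows(arrows, K, n_init=200, seed=None, metric="sqeuclidean"):
    """Best-of-n_init k-means over the arrow vectors.

    Returns (labels, centroids).  metric 'sqeuclidean' uses the
    standard k-means objective; 'cityblock' runs an L1/median Lloyd
    variant.  An empty cluster in the best solution is re-seeded.
    """
    X = _arrow_matrix(arrows)
    if K > len(X):
        raise ValueError("K cannot exceed the number of arrows")
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        if metric == "sqeuclidean":
            km = KMeans(
                n_clusters=K,
                n_init=n_init,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X)
            labels, centroids = km.labels_, km.cluster_centers_
        elif metric == "cityblock":
            labels, centroids, _ = _kmedians(X, K, n_init, rng)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        if len(np.unique(labels)) == K:
            return labels, centroids
        logger.info("empty cluster at K=%d (attempt %d); re-seeding", K, attempt)
    warnings.warn(f"empty cluster persisted at K={K}", RuntimeWarning, stacklevel=2)
    return labels, centroids


def perfect_matchings(items):
    """Yield all partitions of `items` into unordered pairs ((K-1)!! of them)."""
    items = list(items)
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for i, second in enumerate(rest):
        remaining = rest[:i] + rest[i + 1 :]
        for sub in perfect_matchings(remaining):
            yield ((first, second),) + sub


def pair_centroids(centroids):
    """Best antiparallel pairing of centroids.

    Returns (S_star, D_c): the perfect matching of clusters minimizing
    the centroid pairing distance D_c = (2/K) * sum over matched pairs
    of ||C_i - mirror(C_j)||^2, found exhaustively over all (K-1)!!
    matchings.  K must be even.
    """
    C = np.asarray(centroids, dtype=float)
    K = len(C)
    if K % 2 != 0:
        raise ValueError("pairing requires an even number of clusters")
    Cm = mirror(C)
    # d[i, j] = ||C_i - mirror(C_j)|| (symmetric: mirror is an isometric involution)
    d = np.linalg.norm(C[:, None, :] - Cm[None], axis=2)
    best, best_val = None, np.inf
    for matching in perfect_matchings(range(K)):
        val = sum(d[i, j] ** 2 for i, j in matching)
        if val < best_val:
            best, best_val = matching, val
    return best, float(2.0 / K * best_val)


def pairing_score(arrows, assignment, S_star):
    """Element-level pairing score D = (2/K) * sum over matched pairs of
    the mean distance between each element of one cluster and the
    mirror of each element of its partner."""
    X = _arrow_matrix(arrows)
    Xm = mirror(X)
    assignment = np.asarray(assignment)
    K = 2 * len(S_star)
    total = 0.0
    for i, j in S_star:
        Xi = X[assignment == i]
        Xj_m = Xm[assignment == j]
        dists = np.linalg.norm(Xi[:, None, :] - Xj_m[None], axis=2)
        total += dists.mean()
    return float(2.0 / K * total)


def select_clusters(
    arrows,
    K_range=None,
    min_cluster_size=10,
    n_init=200,
    seed=None,
    metric="sqeuclidean",
) -> ClusterScan:
    """Scan even K, pair clusters, and select K* = argmin D(K).

    Cluster counts whose smallest cluster falls below
    `min_cluster_size` are reported but ineligible for K*; with no
    eligible K, K_star is None.
    """
    if K_range is None:
        K_range = range(2, min(15, len(arrows) + 1), 2)
    K_values = [int(K) for K in K_range]
    if any(K % 2 for K in K_values):
        raise ValueError("cluster counts must be even (antiparallel pairing)")
    root = np.random.SeedSequence(seed)
    assignments, centroids, S_stars, D_cs, Ds, eligible = {}, {}, {}, {}, {}, {}
    for K, ss in zip(K_values, root.spawn(len(K_values))):
        labels, cents = kmeans_arrows(
            arrows, K, n_init=n_init, seed=ss.generate_state(1)[0] % (2**31),
            metric=metric,
        )
        S_star, D_c = pair_centroids(cents)
        D = pairing_score(arrows, labels, S_star)
        sizes = np.bincount(labels, minlength=K)
        assignments[K] = labels
        centroids[K] = cents
        S_stars[K] = S_star
        D_cs[K] = D_c
        Ds[K] = D
        eligible[K] = bool(sizes.min() >= min_cluster_size)
    candidates = [K for K in K_values if eligible[K]]
    K_star = min(candidates, key=lambda K: Ds[K]) if candidates else None
    return ClusterScan(
        K_values=K_values,
        assignments=assignments,
        centroids=centroids,
        S_star=S_stars,
        D_c=D_cs,
        D=Ds,
        eligible=eligible,
        K_star=K_star,
    )


def landscape_graph(centroids, S_star, merge_tol=None):
    """Graph of inferred basins linked by matched cluster pairs.

    Each matched pair contributes one undirected edge between the basin
    its arrows leave (the "before" rate signature) and the basin they
    enter (the "after" signature).  Endpoints closer than `merge_tol`
    (city-block in log-rate space) are merged into one basin node; with
    merge_tol None only identical endpoints merge.  A pair whose two
    endpoints coincide becomes a self-loop and is flagged suspicious.
    """
    C = np.asarray(centroids, dtype=float)
    h = C.shape[1] // 2
    endpoints = []
    edges = []
    for i, j in S_star:
        # the pair's consensus basin signatures: before of i ~ after of j
        before = (C[i, :h] + C[j, h:]) / 2.0
        after = (C[i, h:] + C[j, :h]) / 2.0
        edges.append((len(endpoints), len(endpoints) + 1, (i, j)))
        endpoints.extend([before, after])
    endpoints = np.array(endpoints)
    tol = 0.0 if merge_tol is None else float(merge_tol)
    prox = nx.Graph()
    prox.add_nodes_from(range(len(endpoints)))
    for a in range(len(endpoints)):
        for b in range(a + 1, len(endpoints)):
            if np.abs(endpoints[a] - endpoints[b]).max() <= tol:
                prox.add_edge(a, b)
    node_of = {}
    basins = []
    for comp in nx.connected_components(prox):
        basin = len(basins)
        basins.append(endpoints[sorted(comp)].mean(axis=0))
        for e in comp:
            node_of[e] = basin
    G = nx.MultiGraph()
    for basin, sig in enumerate(basins):
        G.add_node(basin, signature=sig)
    for a, b, pair in edges:
        u, v = node_of[a], node_of[b]
        G.add_edge(
            u,
            v,
            clusters=pair,
            before_rates=np.exp(C[pair[0], :h]),
            after_rates=np.exp(C[pair[0], h:]),
            self_loop=bool(u == v),
        )
        if u == v:
            warnings.warn(
                f"matched pair {pair} forms a self-loop (before/after rates coincide)",
                RuntimeWarning,
                stacklevel=2,
            )
    return G
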