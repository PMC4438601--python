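"""Weighted graph metrics over proportional sparsity thresholds.

A connectivity matrix is converted into a family of weighted, undirected
graphs by retaining the strongest S * n(n-1)/2 positive edges for each
sparsity S on a grid (default 0.10-0.50 in steps of 0.05).  At each
threshold the module computes:

* mean clustering coefficient C (Onnela geometric-mean-of-triangle-weights,
  weights max-normalised),
* characteristic path length L and global efficiency Eglob on distances
  d = 1/w,
* mean local efficiency Eloc (global efficiency of each node's induced
  neighbourhood subgraph),
* modularity Q (Louvain optimisation with restarts, Newman weighted formula),
* normalised variants gamma = C/<C_rand>, lambda = L/<L_rand> and
  small-worldness sigma = gamma/lambda, where the null distribution comes
  from degree-preserving (Maslov-Sneppen) double-edge swaps with the weight
  multiset reassigned at random.

Metrics are implemented directly on adjacency arrays for speed; they agree
with networkx and brute-force definitions (see the test suite).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "WeightedGraph",
    "GlobalMetrics",
    "NodeMetrics",
    "threshold_proportional",
    "clustering_coefficient",
    "clustering_mean",
    "path_and_efficiency",
    "local_efficiency",
    "newman_modularity",
    "modularity",
    "randomize_graph",
    "normalized_metrics",
    "node_level_metrics",
    "metric_curves",
    "DEFAULT_SPARSITY_GRID",
]

DEFAULT_SPARSITY_GRID: tuple[float, ...] = tuple(
    round(0.10 + 0.05 * i, 2) for i in range(9))  # 0.10 .. 0.50

#: global metric names produced by :func:`metric_curves`
CURVE_METRICS = ("clustering", "path_length", "global_efficiency",
                 "local_efficiency", "modularity", "gamma", "lambda",
                 "sigma", "global_efficiency_norm", "local_efficiency_norm")


@dataclass
class WeightedGraph:
    """Thresholded weighted undirected graph (nonnegative, no self-loops)."""

    adjacency: np.ndarray
    sparsity: float | None = None
    n_requested_edges: int | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("no self-loops allowed")
        if A.min() < 0:
            raise ValueError("adjacency weights must be nonnegative")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency)
        return G


@dataclass
class GlobalMetrics:
    """Global topology summary at one sparsity, with null normalisation."""

    clustering: float
    path_length: float
    global_efficiency: float
    local_efficiency: float
    modularity: float
    gamma: float
    lam: float
    sigma: float
    global_efficiency_norm: float
    local_efficiency_norm: float
    n_rand: int
    seed: int | None
    n_null_excluded: int = 0
    null_values: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "modularity": self.modularity,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "global_efficiency_norm": self.global_efficiency_norm,
            "local_efficiency_norm": self.local_efficiency_norm,
        }


@dataclass
class NodeMetrics:
    """Per-node and per-edge centrality/segregation metrics."""

    node_ids: list
    degree: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    betweenness: np.ndarray
    edge_betweenness: dict  # (i, j) -> value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_ids,
            "degree": self.degree,
            "clustering": self.clustering,
            "local_efficiency": self.local_efficiency,
            "betweenness": self.betweenness,
        })


def _as_adjacency(G) -> np.ndarray:
    if isinstance(G, WeightedGraph):
        return G.adjacency
    return np.asarray(G, float)


def threshold_proportional(C: ConnectivityMatrix | np.ndarray, S: float,
                           rank_by: str = "signed") -> WeightedGraph:
    """Retain the strongest ``round(S * n(n-1)/2)`` positive edges.

    Edges are ranked by signed weight by default; ``rank_by="abs"`` ranks by
    magnitude instead.  Negative edges are never retained, because path
    metrics are undefined for negative weights.  Ties at the cutoff are
    broken deterministically by lexicographic (i, j) node-pair order.
    """
    if not 0 < S < 1:
        raise ValueError("sparsity S must lie in (0, 1)")
    W = C.values if isinstance(C, ConnectivityMatrix) else np.asarray(C, float)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    w = W[iu]
    m_req = int(round(S * n * (n - 1) / 2))
    key = np.abs(w) if rank_by == "abs" else w
    # sort by (-key, i, j): lexsort uses last key as primary
    order = np.lexsort((iu[1], iu[0], -key))
    keep = order[:m_req]
    keep = keep[key[keep] > 0]  # never retain zero (or, signed mode, negative) edges
    if keep.size < m_req:
        warnings.warn(
            f"only {keep.size} retainable edges available for requested "
            f"{m_req} at S={S}; retaining all of them")
    A = np.zeros_like(W)
    A[iu[0][keep], iu[1][keep]] = np.abs(w[keep]) if rank_by == "abs" else w[keep]
    A = A + A.T
    return WeightedGraph(A, sparsity=float(S), n_requested_edges=m_req)


def clustering_coefficient(G) -> np.ndarray:
    """Onnela weighted clustering per node, weights max-normalised.

    C_i = (M^3)_ii / (k_i (k_i - 1)) with M = (W / max W)^(1/3) and k the
    binary degree; nodes of degree < 2 contribute 0.
    """
    W = _as_adjacency(G)
    n = W.shape[0]
    if n == 0 or W.max() == 0:
        return np.zeros(n)
    M = np.cbrt(W / W.max())
    tri = np.einsum("ij,jk,ki->i", M, M, M)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return c


def clustering_mean(G) -> float:
    """Mean Onnela clustering over all nodes (isolated nodes count as 0)."""
    c = clustering_coefficient(G)
    return float(c.mean()) if c.size else 0.0


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    # vectorised Floyd-Warshall on d = 1/w; beats sparse Dijkstra for the
    # dense small-to-medium graphs this pipeline produces
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(D.shape[0]):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def path_and_efficiency(G) -> tuple[float, float]:
    """Characteristic path length and global efficiency on d = 1/w.

    L averages shortest-path distance over *connected* ordered node pairs
    (disconnected pairs are excluded; their count is available via
    :func:`path_efficiency_detail`).  Eglob averages 1/d over all ordered
    pairs with 1/inf = 0, so it degrades gracefully under disconnection.
    """
    L, eglob, _ = path_efficiency_detail(G)
    return L, eglob


def path_efficiency_detail(G) -> tuple[float, float, int]:
    W = _as_adjacency(G)
    n = W.shape[0]
    if n < 2:
        return 0.0, 0.0, 0
    d = _distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    dv = d[off]
    finite = np.isfinite(dv)
    n_disc = int((~finite).sum())
    L = float(dv[finite].mean()) if finite.any() else math.inf
    inv = np.where(finite, 1.0 / np.where(finite, dv, 1.0), 0.0)
    eglob = float(inv.mean())
    return L, eglob, n_disc


def _subgraph_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d[off]), 1.0 / d[off], 0.0)
    return float(inv.mean())


def local_efficiency(G) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean.

    The local efficiency of node i is the global efficiency of the weighted
    subgraph induced on i's neighbours; nodes of degree < 2 score 0.
    """
    W = _as_adjacency(G)
    n = W.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(W[i] > 0)
        if nb.size < 2:
            continue
        eloc[i] = _subgraph_efficiency(W[np.ix_(nb, nb)])
    return eloc, float(eloc.mean()) if n else 0.0


def newman_modularity(G, membership) -> float:
    """Newman weighted modularity of a given partition.

    Q = sum_c [ w_cc / w  -  (d_c / 2w)^2 ] with w the total edge weight,
    w_cc twice the intra-community weight and d_c the community strength.
    """
    W = _as_adjacency(G)
    membership = np.asarray(membership)
    total2 = W.sum()  # = 2 * total edge weight
    if total2 <= 0:
        raise ValueError("graph has no positive weight")
    deg = W.sum(axis=1)
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        q += W[np.ix_(idx, idx)].sum() / total2 - (deg[idx].sum() / total2) ** 2
    return float(q)


def _exact_modularity(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Globally optimal partition by exhaustive set-partition enumeration."""
    n = W.shape[0]
    best_q, best_member = -np.inf, np.zeros(n, dtype=int)

    def recurse(i, member, n_blocks):
        nonlocal best_q, best_member
        if i == n:
            q = newman_modularity(W, member)
            if q > best_q:
                best_q, best_member = q, member.copy()
            return
        for b in range(n_blocks):
            member[i] = b
            recurse(i + 1, member, n_blocks)
        member[i] = n_blocks
        recurse(i + 1, member, n_blocks + 1)
        member[i] = 0

    recurse(1, np.zeros(n, dtype=int), 1)
    return best_q, best_member


def modularity(G, resolution: float = 1.0, n_restarts: int = 20,
               seed: int | None = None,
               exact_max: int = 8) -> tuple[float, np.ndarray]:
    """Modularity-optimal community structure.

    For graphs of at most ``exact_max`` nodes (and resolution 1) the optimum
    is found exactly by enumerating all set partitions; larger graphs use
    best-of-restarts Louvain.  Returns (Q, membership); Q is always
    recomputed from the returned partition with :func:`newman_modularity`,
    independent of the optimiser's internal score.
    """
    W = _as_adjacency(G)
    if W.sum() <= 0:
        raise ValueError("modularity undefined for an all-zero graph")
    if W.shape[0] <= exact_max and resolution == 1.0:
        return _exact_modularity(W)
    Gx = nx.from_numpy_array(W)
    rng = np.random.default_rng(seed)
    best_q, best_member = -np.inf, None
    for _ in range(max(1, n_restarts)):
        s = int(rng.integers(0, 2 ** 31 - 1))
        comms = nx.community.louvain_communities(
            Gx, weight="weight", resolution=resolution, seed=s)
        member = np.empty(W.shape[0], dtype=int)
        for label, nodes in enumerate(comms):
            member[list(nodes)] = label
        q = newman_modularity(W, member)
        if q > best_q:
            best_q, best_member = q, member
    return best_q, best_member


def randomize_graph(G, n_swaps_per_edge: int = 10,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> WeightedGraph:
    """Degree-preserving null graph (Maslov-Sneppen double-edge swaps).

    Topology is rewired by repeated double-edge swaps (``n_swaps_per_edge``
    attempts per edge); the original weight multiset is then reassigned to
    the surviving edges in random order.  The binary degree sequence and the
    sorted weight list are preserved exactly.
    """
    W = _as_adjacency(G)
    n = W.shape[0]
    rng = rng if rng is not None else np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    mask = W[iu] > 0
    ii, jj = iu[0][mask], iu[1][mask]
    weights = W[iu][mask]
    m = len(ii)
    if m < 2:
        warnings.warn("fewer than 2 edges; shuffling weights only")
        perm = rng.permutation(m)
        A = np.zeros_like(W)
        A[ii, jj] = weights[perm]
        return WeightedGraph(A + A.T)
    edges = list(zip(ii.tolist(), jj.tolist()))
    edge_set = {a * n + b for a, b in edges}
    attempts = n_swaps_per_edge * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        x1, y1 = (a, d) if a < d else (d, a)
        x2, y2 = (c, b) if c < b else (b, c)
        k1, k2 = x1 * n + y1, x2 * n + y2
        if k1 in edge_set or k2 in edge_set:
            continue
        edge_set.discard(a * n + b)
        edge_set.discard(edges[e2][0] * n + edges[e2][1])
        edge_set.add(k1)
        edge_set.add(k2)
        edges[e1] = (x1, y1)
        edges[e2] = (x2, y2)
    perm = rng.permutation(m)
    A = np.zeros_like(W)
    arr = np.array(edges)
    A[arr[:, 0], arr[:, 1]] = weights[perm]
    return WeightedGraph(A + A.T)


def normalized_metrics(G, n_rand: int = 100, seed: int | None = None,
                       n_swaps_per_edge: int = 10, n_restarts: int = 20,
                       normalize_efficiency: bool = True,
                       keep_null_values: bool = False) -> GlobalMetrics:
    """All global metrics with random-network normalisation.

    gamma = C / <C_rand>, lambda = L / <L_rand>, sigma = gamma / lambda,
    with the null ensemble of ``n_rand`` degree-preserving rewired graphs.
    Normalised efficiencies are computed analogously; modularity is reported
    raw.  Nulls with zero clustering are excluded from the clustering null
    mean (their count is reported).
    """
    G = G if isinstance(G, WeightedGraph) else WeightedGraph(_as_adjacency(G))
    rng = np.random.default_rng(seed)
    C = clustering_mean(G)
    L, eglob, _ = path_efficiency_detail(G)
    _, eloc = local_efficiency(G)
    Q, _ = modularity(G, n_restarts=n_restarts,
                      seed=int(rng.integers(0, 2 ** 31 - 1)))
    c_null, l_null, eg_null, el_null = [], [], [], []
    for _ in range(n_rand):
        null = randomize_graph(G, n_swaps_per_edge=n_swaps_per_edge, rng=rng)
        c_null.append(clustering_mean(null))
        ln, egn, _ = path_efficiency_detail(null)
        l_null.append(ln)
        eg_null.append(egn)
        if normalize_efficiency:
            _, eln = local_efficiency(null)
            el_null.append(eln)
    c_null = np.array(c_null)
    ok = c_null > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        warnings.warn("every null network has zero clustering; gamma/sigma "
                      "undefined (graph too sparse for triangles)")
    c_mean = c_null[ok].mean() if ok.any() else np.nan
    l_arr = np.array(l_null)
    l_fin = l_arr[np.isfinite(l_arr)]
    l_mean = l_fin.mean() if l_fin.size else np.nan
    gamma = C / c_mean if c_mean and np.isfinite(c_mean) else np.nan
    lam = L / l_mean if l_mean and np.isfinite(l_mean) else np.nan
    sigma = gamma / lam if lam and np.isfinite(lam) and lam != 0 else np.nan
    eg_mean = float(np.mean(eg_null)) if eg_null else np.nan
    eglob_norm = eglob / eg_mean if eg_mean else np.nan
    if normalize_efficiency and el_null:
        el_mean = float(np.mean(el_null))
        eloc_norm = eloc / el_mean if el_mean else np.nan
    else:
        eloc_norm = np.nan
    nulls = {}
    if keep_null_values:
        nulls = {"clustering": c_null.tolist(), "path_length": l_null,
                 "global_efficiency": eg_null, "local_efficiency": el_null}
    return GlobalMetrics(
        clustering=C, path_length=L, global_efficiency=eglob,
        local_efficiency=eloc, modularity=Q, gamma=float(gamma),
        lam=float(lam), sigma=float(sigma),
        global_efficiency_norm=float(eglob_norm),
        local_efficiency_norm=float(eloc_norm), n_rand=n_rand, seed=seed,
        n_null_excluded=n_excluded, null_values=nulls)


def node_level_metrics(G, node_ids=None) -> NodeMetrics:
    """Degree, clustering, local efficiency and (edge) betweenness per node.

    Betweenness is weighted-shortest-path (Brandes) on distances 1/w,
    unnormalised (raw dependency pair counts).
    """
    W = _as_adjacency(G)
    n = W.shape[0]
    if node_ids is None:
        node_ids = list(range(n))
    Gx = nx.from_numpy_array(W)
    for u, v, data in Gx.edges(data=True):
        data["distance"] = 1.0 / data["weight"]
    btw = nx.betweenness_centrality(Gx, weight="distance", normalized=False)
    ebtw = nx.edge_betweenness_centrality(Gx, weight="distance",
                                          normalized=False)
    eloc, _ = local_efficiency(W)
    return NodeMetrics(
        node_ids=list(node_ids),
        degree=(W > 0).sum(axis=1),
        clustering=clustering_coefficient(W),
        local_efficiency=eloc,
        betweenness=np.array([btw[i] for i in range(n)]),
        edge_betweenness={(min(u, v), max(u, v)): val
                          for (u, v), val in ebtw.items()},
    )


def metric_curves(C: ConnectivityMatrix | np.ndarray,
                  sparsity_grid=DEFAULT_SPARSITY_GRID,
                  n_rand: int = 100, seed: int | None = None,
                  n_swaps_per_edge: int = 10, n_restarts: int = 20,
                  normalize_efficiency: bool = True,
                  subject_id: str = "", session: str = "") -> pd.DataFrame:
    """Evaluate every global metric at every sparsity on the grid.

    Returns a tidy frame with columns (subject, session, sparsity, metric,
    value).  One independent null family is generated per grid point, with
    per-point seeds spawned deterministically from ``seed`` so curves are
    reproducible and grid refinement never changes values at shared points.
    """
    grid = [float(s) for s in sparsity_grid]
    if sorted(grid) != grid or not all(0 < s < 1 for s in grid):
        raise ValueError("sparsity grid must be sorted and within (0, 1)")
    rows = []
    for s in grid:
        # seed keyed on the grid value itself, not its index, so refining
        # the grid leaves shared points unchanged
        point_seed = None if seed is None else np.random.SeedSequence(
            (int(seed), int(round(s * 1000)))).generate_state(1)[0] % (2**31)
        g = threshold_proportional(C, s)
        gm = normalized_metrics(
            g, n_rand=n_rand, seed=point_seed,
            n_swaps_per_edge=n_swaps_per_edge, n_restarts=n_restarts,
            normalize_efficiency=normalize_efficiency)
        for metric, value in gm.as_dict().items():
            rows.append((subject_id, session, s, metric, value))
    return pd.DataFrame(rows, columns=["subject", "session", "sparsity",
                                       "metric", "value"])
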