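"""Hierarchical clustering of connectivity profiles and graph topology.

Connectivity matrices are binarized at fixed graph densities (top edges by
signed Fisher-z, strongest positive first) and summarized by global
efficiency, small-worldness, modularity, and assortativity, plus nodal
degree.  Group comparison reuses the rat-random-intercept mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .stats import bh_fdr, mixed_model_ttest

__all__ = [
    "Dendrogram",
    "BinaryGraph",
    "ward_cluster",
    "binarize",
    "global_efficiency",
    "characteristic_path_length",
    "mean_clustering",
    "small_worldness",
    "modularity",
    "assortativity",
    "graph_metrics",
    "compare_topology",
    "DEFAULT_DENSITIES",
]

DEFAULT_DENSITIES = (0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class Dendrogram:
    """Ward merge history and the partition at a requested cut."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: np.ndarray  # cluster id per region at the cut
    k: int

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at a stated density."""

    adjacency: np.ndarray  # boolean (n, n), symmetric, zero diagonal
    density: float
    meta: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency.astype(int))
        return g


def ward_cluster(matrix: np.ndarray, k: int = 7) -> Dendrogram:
    """Agglomerative Ward clustering of regional connectivity profiles.

    Each region's profile is its row of the (group-mean) Fisher-z matrix
    with the self-connection zeroed; successive merges minimize the Ward
    sum-of-squares criterion on Euclidean distances between profiles.
    Zeroing (rather than deleting) the diagonal keeps the profile
    coordinates aligned across regions, so relabeling the regions permutes
    the resulting partition exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {n} regions into {k} clusters")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("connectivity matrix contains non-finite values")
    profiles = matrix.copy()
    np.fill_diagonal(profiles, 0.0)
    Z = hierarchy.linkage(pdist(profiles), method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Dendrogram(linkage=Z, labels=labels, k=k)


def binarize(z: np.ndarray, density: float, meta: dict | None = None) -> BinaryGraph:
    """Keep the strongest edges by signed Fisher-z at the requested density.

    The edge count is round(density * n(n-1)/2); ties are broken by the
    lexicographic (i, j) order of the edge list, so the result is
    deterministic and edge sets are nested across increasing densities.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    m = int(round(density * vals.size))
    if m < 1:
        raise ValueError(f"density {density} keeps zero edges")
    order = np.lexsort((ju, iu, -vals))  # by -z, then (i, j)
    keep = order[:m]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density, meta=meta)


def _pairwise_distances(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import shortest_path

    return shortest_path(adj.astype(float), method="D", unweighted=True)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs;
    unreachable pairs contribute zero."""
    d = _pairwise_distances(g.adjacency)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over reachable node pairs."""
    d = _pairwise_distances(g.adjacency)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        return np.inf
    return float(vals[finite].mean())


def mean_clustering(g: BinaryGraph) -> float:
    """Average local clustering coefficient (zero for degree < 2 nodes)."""
    return float(nx.average_clustering(g.to_networkx()))


def _rewired_null(g: BinaryGraph, rng: np.random.Generator, swap_factor: int = 10):
    gg = g.to_networkx()
    m = gg.number_of_edges()
    if m < 2:
        return g
    nswap = swap_factor * m
    try:
        nx.double_edge_swap(
            gg, nswap=nswap, max_tries=nswap * 20, seed=int(rng.integers(2**31))
        )
    except nx.NetworkXAlgorithmError:
        pass  # ran out of tries; keep the partial rewiring
    adj = nx.to_numpy_array(gg, nodelist=range(g.n_nodes)) > 0
    return BinaryGraph(adjacency=adj, density=g.density)


def small_worldness(
    g: BinaryGraph, n_null: int = 20, seed: int = 0, swap_factor: int = 10
) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    C is the mean clustering coefficient, L the characteristic path length
    over reachable pairs; the null values are averaged over ``n_null``
    degree-preserving rewired graphs.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    C = mean_clustering(g)
    L = characteristic_path_length(g)
    nulls = [_rewired_null(g, rng, swap_factor) for _ in range(n_null)]
    Cr = np.mean([mean_clustering(h) for h in nulls])
    Lr = np.mean([characteristic_path_length(h) for h in nulls])
    if Cr == 0 or L == 0 or not np.isfinite(L) or not np.isfinite(Lr):
        return float("nan")
    return float((C / Cr) / (L / Lr))


def modularity(
    g: BinaryGraph, seed: int = 0, n_restarts: int = 10, resolution: float = 1.0
):
    """Newman modularity Q maximized by the Louvain heuristic.

    Best partition over ``n_restarts`` seeded restarts; returns
    ``(Q, labels)``.  An edgeless graph is a parameter error.
    """
    if g.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    gg = g.to_networkx()
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        part = nx.community.louvain_communities(
            gg, seed=seed * 1000 + r, resolution=resolution
        )
        q = nx.community.modularity(gg, part, resolution=resolution)
        if q > best_q:
            best_q, best_part = q, part
    labels = np.empty(g.n_nodes, dtype=int)
    for c, nodes in enumerate(best_part):
        for v in nodes:
            labels[v] = c
    return float(best_q), labels


def assortativity(g: BinaryGraph) -> float:
    """Degree assortativity: Pearson correlation of degrees across edge
    endpoints.  Returns NaN for degree-regular graphs (zero variance)."""
    if g.n_edges < 2:
        raise ValueError("assortativity needs at least 2 edges")
    deg = g.degrees()
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    # Each undirected edge contributes both orientations.
    x = np.concatenate([deg[iu], deg[ju]]).astype(float)
    y = np.concatenate([deg[ju], deg[iu]]).astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def graph_metrics(
    z: np.ndarray,
    densities=DEFAULT_DENSITIES,
    n_null: int = 20,
    seed: int = 0,
    meta: dict | None = None,
) -> pd.DataFrame:
    """All global metrics plus nodal degrees for one scan at each density."""
    rows = []
    for d in densities:
        g = binarize(z, d, meta=meta)
        q, _ = modularity(g, seed=seed)
        row = {
            "density": d,
            "global_efficiency": global_efficiency(g),
            "small_worldness": small_worldness(g, n_null=n_null, seed=seed),
            "modularity": q,
            "assortativity": assortativity(g),
        }
        for node, deg in enumerate(g.degrees()):
            row[f"degree_{node:03d}"] = deg
        if meta:
            row.update({k: v for k, v in meta.items() if np.isscalar(v) or v is None})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_topology(
    metrics: pd.DataFrame,
    sex: np.ndarray,
    rat: np.ndarray,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sex contrast of global metrics per density, and nodal degree per node.

    ``metrics`` must stack :func:`graph_metrics` outputs, one block per
    scan, with identical density grids; ``sex`` and ``rat`` give one label
    per scan.  Global metrics are tested per density with the mixed model;
    nodal degree is tested per node (FDR over nodes, within density).
    """
    densities = np.sort(metrics["density"].unique())
    n_scans = len(sex)
    if len(metrics) != n_scans * densities.size:
        raise ValueError("metric table does not align with the scan labels")
    global_rows, degree_rows = [], []
    deg_cols = [c for c in metrics.columns if c.startswith("degree_")]
    for d in densities:
        sub = metrics[metrics["density"] == d]
        if len(sub) != n_scans:
            raise ValueError(f"density {d} missing for some scans")
        for metric in (
            "global_efficiency",
            "small_worldness",
            "modularity",
            "assortativity",
        ):
            y = sub[metric].to_numpy()
            ok = np.isfinite(y)
            try:
                res = mixed_model_ttest(
                    y[ok], np.asarray(sex)[ok], np.asarray(rat)[ok]
                )
                est, t, dfree, p = res.estimate, res.t, res.df, res.p
            except ValueError:
                # too few scans with a finite value (e.g. NaN assortativity
                # on regular graphs): record the gap rather than abort
                est = t = dfree = p = np.nan
            global_rows.append(
                {
                    "density": d,
                    "metric": metric,
                    "estimate": est,
                    "t": t,
                    "df": dfree,
                    "p": p,
                }
            )
        pvals, rows_d = [], []
        for col in deg_cols:
            y = sub[col].to_numpy(dtype=float)
            res = mixed_model_ttest(y, sex, rat)
            pvals.append(res.p)
            rows_d.append(
                {
                    "density": d,
                    "node": int(col.split("_")[1]),
                    "estimate": res.estimate,
                    "t": res.t,
                    "p": res.p,
                }
            )
        # Constant degree columns yield an undefined test (NaN p); exclude
        # them from the FDR family instead of treating them as evidence.
        pvals = np.asarray(pvals, dtype=float)
        finite = np.isfinite(pvals)
        q = np.full(pvals.size, np.nan)
        if finite.any():
            q[finite] = bh_fdr(pvals[finite])
        for r, qq in zip(rows_d, q):
            r["q"] = qq
            r["significant"] = bool(qq < alpha) if np.isfinite(qq) else False
        degree_rows.extend(rows_d)
    return pd.DataFrame(global_rows), pd.DataFrame(degree_rows)
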