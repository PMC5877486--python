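"""Global graph metrics on per-epoch connectivity matrices.

Each connectivity matrix is read as the adjacency matrix of a weighted graph
over electrode sites: SL matrices directly (symmetric, similarity in [0, 1],
undirected), RWE matrices after mapping each divergence v to the bounded
similarity 1/(1+v) (asymmetric, directed). Shortest-path metrics use edge
lengths 1/similarity.

The summary block holds seven global features for undirected graphs — mean
binarized node degree, connection density, mean weighted clustering
coefficient (Onnela geometric-mean form; Fagiolo form when directed),
characteristic path length, global efficiency, mean relative betweenness
centrality and the small-world index sigma = (C/C_rand)/(L/L_rand) against
weight-shuffled surrogates — and five for directed graphs, where degree and
density are omitted: a directed RWE graph is fully connected by construction,
so those two values would be constant across epochs and carry no stage
information.

Degree and density are computed on a binarized graph keeping the strongest
fraction of edges (default 30%); all weighted metrics use the full matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

#: Feature order of the undirected (SL) block.
UNDIRECTED_FEATURES = (
    "mean_degree", "density", "mean_clustering", "char_path_length",
    "global_efficiency", "mean_betweenness", "small_world",
)
#: Feature order of the directed (RWE) block: degree and density omitted.
DIRECTED_FEATURES = UNDIRECTED_FEATURES[2:]


@dataclass
class WeightedGraph:
    """Similarity-weighted graph over electrode sites; zero diagonal."""

    weights: np.ndarray
    directed: bool
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.array(self.weights, dtype=np.float64)  # own copy
        m = self.weights.shape[0]
        if self.weights.shape != (m, m):
            raise ValueError("Weight matrix must be square")
        if np.any(self.weights < 0):
            raise ValueError("Graph weights must be non-negative")
        np.fill_diagonal(self.weights, 0.0)
        if not self.directed and not np.allclose(self.weights, self.weights.T):
            raise ValueError("Undirected graph requires a symmetric matrix")
        if not self.node_labels:
            self.node_labels = tuple(f"n{i}" for i in range(m))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class GraphFeatures:
    """Named global feature block of one connectivity graph."""

    mean_degree: float | None
    density: float | None
    mean_clustering: float
    char_path_length: float
    global_efficiency: float
    mean_betweenness: float
    small_world: float

    def as_array(self) -> np.ndarray:
        vals = [self.mean_degree, self.density, self.mean_clustering,
                self.char_path_length, self.global_efficiency,
                self.mean_betweenness, self.small_world]
        return np.array([v for v in vals if v is not None], dtype=np.float64)


def to_graph(mat) -> WeightedGraph:
    """Build the weighted graph of a connectivity matrix.

    SL values are similarities already; RWE divergences v are mapped to
    1/(1+v) so larger spectral divergence means weaker coupling, bounded in
    (0, 1].
    """
    # local import: staging of matrices lives in sibling modules
    from .rwe import RWEMatrix
    from .sl import SLMatrix

    if isinstance(mat, SLMatrix):
        w = mat.values.copy()
        directed = False
    elif isinstance(mat, RWEMatrix):
        if np.any(mat.values < 0):
            raise ValueError("RWE matrix entries must be non-negative")
        w = 1.0 / (1.0 + mat.values)
        directed = True
    else:
        raise TypeError(f"Cannot build a graph from {type(mat).__name__}")
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise ValueError("Connectivity matrix has negative entries")
    return WeightedGraph(weights=w, directed=directed)


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def binary_degree_density(
    g: WeightedGraph, threshold_frac: float = 0.3
) -> tuple[float, float]:
    """Mean node degree and density after keeping the strongest edges.

    The strongest ceil(threshold_frac * E) of the E possible edges are kept;
    ties at the cut weight are all kept, so density can exceed the requested
    fraction. Undirected graphs only (the directed RWE graph is complete, so
    the features are uninformative there).
    """
    if g.directed:
        raise ValueError("Degree/density are defined for undirected graphs only")
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must lie in (0, 1]")
    m = g.n_nodes
    iu = np.triu_indices(m, k=1)
    w = g.weights[iu]
    n_edges = w.size
    k = ceil(threshold_frac * n_edges)
    cut = np.sort(w)[::-1][k - 1]
    keep = w >= cut
    adj = np.zeros((m, m))
    adj[iu[0][keep], iu[1][keep]] = 1.0
    adj += adj.T
    mean_degree = float(adj.sum(axis=1).mean())
    density = float(keep.sum() / n_edges)
    return mean_degree, density


def _nx_graph(g: WeightedGraph, attr: str = "weight") -> nx.Graph:
    cls = nx.DiGraph if g.directed else nx.Graph
    gx = cls()
    gx.add_nodes_from(range(g.n_nodes))
    idx = np.nonzero(g.weights)
    for a, b in zip(*idx):
        if g.directed or a < b:
            gx.add_edge(int(a), int(b), **{attr: float(g.weights[a, b])})
    return gx


def weighted_clustering(g: WeightedGraph) -> float:
    """Mean geometric-mean triangle intensity (Onnela; Fagiolo if directed).

    Weights are normalized by the maximum weight; nodes without a connected
    pair of neighbours contribute 0.
    """
    gx = _nx_graph(g)
    cc = nx.clustering(gx, weight="weight")
    return float(np.mean(list(cc.values()))) if cc else 0.0


def _length_matrix(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path lengths on 1/similarity edge lengths."""
    with np.errstate(divide="ignore"):
        lengths = np.where(g.weights > 0, 1.0 / g.weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return shortest_path(lengths, method="D", directed=g.directed)


def path_length_efficiency(g: WeightedGraph) -> tuple[float, float]:
    """Characteristic path length and global efficiency.

    L is the mean shortest-path length over reachable ordered pairs (a warning
    is logged when some pairs are unreachable); efficiency is the mean of
    1/length over all ordered pairs, unreachable pairs contributing 0.
    """
    d = _length_matrix(g)
    m = g.n_nodes
    off = ~np.eye(m, dtype=bool)
    dvals = d[off]
    finite = np.isfinite(dvals)
    if not finite.any():
        logger.warning("Graph has no connected pairs; path length undefined")
        return float("inf"), 0.0
    if not finite.all():
        logger.warning(
            "%d of %d node pairs unreachable; L averaged over reachable pairs",
            int((~finite).sum()), dvals.size,
        )
    char_path = float(dvals[finite].mean())
    inv = np.zeros_like(dvals)
    inv[finite] = 1.0 / dvals[finite]
    efficiency = float(inv.mean())
    return char_path, efficiency


def mean_betweenness(g: WeightedGraph) -> float:
    """Mean relative betweenness centrality (shortest paths on 1/similarity).

    Normalized per node by (M-1)(M-2)/2 pairs (undirected) or (M-1)(M-2)
    (directed).
    """
    gx = _nx_graph(g)
    for a, b in gx.edges:
        gx[a][b]["length"] = 1.0 / gx[a][b]["weight"]
    bc = nx.betweenness_centrality(gx, weight="length", normalized=True)
    return float(np.mean(list(bc.values()))) if bc else 0.0


def _shuffle_weights(
    g: WeightedGraph, rng: np.random.Generator
) -> WeightedGraph:
    """Degree/strength-preserving null: permute weights over existing edges.

    The edge support (hence every node's degree) is kept; only the weight
    assignment is randomized. On the complete connectivity graphs produced by
    SL/RWE this also preserves the exact weight multiset.
    """
    m = g.n_nodes
    w = np.zeros((m, m))
    if g.directed:
        mask = (~np.eye(m, dtype=bool)) & (g.weights > 0)
        w[mask] = rng.permutation(g.weights[mask])
    else:
        iu = np.triu_indices(m, k=1)
        mask = np.zeros((m, m), dtype=bool)
        mask[iu] = True
        mask &= g.weights > 0
        w[mask] = rng.permutation(g.weights[mask])
        w += w.T
    return WeightedGraph(weights=w, directed=g.directed)


def small_world_index(
    g: WeightedGraph, n_rand: int = 20, seed: int = 0
) -> float:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    C_rand and L_rand are means over ``n_rand`` surrogates obtained by
    shuffling the weights over the (complete) edge set, which preserves the
    degree sequence and the weight distribution. Deterministic given seed.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    c = weighted_clustering(g)
    length, _ = path_length_efficiency(g)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_rand):
        s = _shuffle_weights(g, rng)
        cs.append(weighted_clustering(s))
        sl_len, _ = path_length_efficiency(s)
        ls.append(sl_len)
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    if c_rand == 0 or l_rand == 0 or not np.isfinite(l_rand) or length == 0:
        return float("nan")
    return float((c / c_rand) / (length / l_rand))


def graph_feature_block(
    mat,
    threshold_frac: float = 0.3,
    n_rand: int = 20,
    seed: int = 0,
) -> GraphFeatures:
    """The global feature block of one connectivity matrix.

    Seven values for SL (undirected), five for RWE (directed; degree and
    density omitted). Order is fixed by UNDIRECTED_FEATURES/DIRECTED_FEATURES.
    """
    g = to_graph(mat)
    if g.directed:
        mean_deg, density = None, None
    else:
        mean_deg, density = binary_degree_density(g, threshold_frac)
    clustering = weighted_clustering(g)
    char_path, efficiency = path_length_efficiency(g)
    betweenness = mean_betweenness(g)
    sigma = small_world_index(g, n_rand=n_rand, seed=seed)
    return GraphFeatures(
        mean_degree=mean_deg,
        density=density,
        mean_clustering=clustering,
        char_path_length=char_path,
        global_efficiency=efficiency,
        mean_betweenness=betweenness,
        small_world=sigma,
    )
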