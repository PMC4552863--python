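"""Structural characterization of connectomes.

Small-worldness follows the ratio construction: the mean local clustering
coefficient ``C`` and mean shortest path ``L`` of the network are compared
with their averages over one hundred degree-sequence-preserving random
surrogates, ``gamma = C / <C_r>_100`` and ``mu = L / <L_r>_100``; their
ratio ``sigma_sw = gamma / mu`` exceeds 1 for small-world networks.
Communities are found with the walktrap random-walk method (walk length
6, dendrogram cut at maximum modularity) and partition quality is the
standard Newman-Girvan modularity.  Coupling strengths are made
comparable across connectomes by rescaling the chemical maximum with the
average chemical degree and the electrical maximum with the smallest
positive eigenvalue ``omega_m`` of the electrical Laplacian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructureReport",
    "RescaleInputs",
    "small_worldness",
    "detect_communities",
    "modularity",
    "rescale_couplings",
    "degree_profiles",
    "smallest_positive_laplacian_eigenvalue",
    "structure_report",
]


@dataclass(frozen=True)
class RescaleInputs:
    """Quantities entering the coupling rescaling between two networks.

    ``omega_m_*`` is the smallest positive eigenvalue of the electrical
    Laplacian ``G = K - A`` and ``dbar_*`` the average chemical degree.
    """

    g_n_ref: float
    g_l_ref: float
    omega_m_ref: float
    omega_m_target: float
    dbar_ref: float
    dbar_target: float

    def __post_init__(self):
        for name in ("g_n_ref", "g_l_ref", "omega_m_ref", "omega_m_target",
                     "dbar_ref", "dbar_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StructureReport:
    mean_clustering: float
    mean_shortest_path: float
    mu: float
    gamma: float
    sigma_sw: float
    modularity: float
    community_labels: np.ndarray
    degree_pdf: dict
    cc_profile: dict
    knn_profile: dict

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key in ("mean_clustering", "mean_shortest_path", "mu",
                        "gamma", "sigma_sw", "modularity"):
                fh.write(f"{key} = {getattr(self, key)!r}\n")
            fh.write(f"n_communities = {len(set(self.community_labels.tolist()))}\n")


def _as_nx(adj: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(adj))


def _as_ig(adj: np.ndarray) -> ig.Graph:
    adj = np.asarray(adj)
    edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(adj, k=1)))]
    return ig.Graph(n=adj.shape[0], edges=edges)


def _degree_preserving_surrogate(g: nx.Graph, rng: np.random.Generator,
                                 max_attempts: int = 10) -> nx.Graph:
    """Configuration-model style rewiring: repeated double edge swaps keep
    the degree sequence exactly.  If every attempt leaves the surrogate
    disconnected, the last one is returned and path lengths downstream
    fall back to its largest component."""
    m = g.number_of_edges()
    surr = None
    for _ in range(max_attempts):
        surr = g.copy()
        try:
            nx.double_edge_swap(surr, nswap=10 * m, max_tries=200 * m,
                                seed=int(rng.integers(0, 2**31 - 1)))
        except nx.NetworkXException:
            # saturated graphs (e.g. K_n) admit no swaps; the copy itself
            # is the only degree-matched surrogate
            pass
        if nx.is_connected(surr):
            return surr
    logger.info("surrogate stayed disconnected after %d attempts; "
                "using largest component for path lengths", max_attempts)
    return surr


def _mean_shortest_path(g: nx.Graph) -> float:
    if nx.is_connected(g):
        return nx.average_shortest_path_length(g)
    comp = g.subgraph(max(nx.connected_components(g), key=len))
    return nx.average_shortest_path_length(comp)


def small_worldness(adj: np.ndarray, n_random: int = 100, rng=None):
    """Small-worldness ``sigma_sw = gamma / mu`` against ``n_random``
    degree-matched random surrogates.

    Returns ``(mu, gamma, sigma_sw)``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    g = _as_nx(adj)
    if not nx.is_connected(g):
        raise ValueError("small_worldness requires a connected graph")
    C = nx.average_clustering(g)
    L = nx.average_shortest_path_length(g)
    Cr = np.empty(n_random)
    Lr = np.empty(n_random)
    for i in range(n_random):
        surr = _degree_preserving_surrogate(g, rng)
        Cr[i] = nx.average_clustering(surr)
        Lr[i] = _mean_shortest_path(surr)
    mu = L / Lr.mean()
    gamma = C / Cr.mean() if Cr.mean() > 0 else np.inf
    return float(mu), float(gamma), float(gamma / mu)


def detect_communities(adj: np.ndarray, steps: int = 6) -> np.ndarray:
    """Walktrap community labels (walk length ``steps``), dendrogram cut
    at maximum modularity."""
    g = _as_ig(adj)
    if not g.is_connected():
        raise ValueError("community detection requires a connected graph")
    clustering = g.community_walktrap(steps=steps).as_clustering()
    return np.array(clustering.membership, dtype=np.int64)


def modularity(adj: np.ndarray, labels) -> float:
    """Newman-Girvan modularity Q of a partition."""
    labels = np.asarray(labels)
    adj = np.asarray(adj)
    if len(labels) != adj.shape[0]:
        raise ValueError("labels must cover all nodes")
    return float(_as_ig(adj).modularity([int(x) for x in labels]))


def rescale_couplings(inputs: RescaleInputs) -> tuple[float, float]:
    """Maximum couplings for a new network from a reference parameter
    space: the chemical maximum scales with the average-chemical-degree
    ratio, the electrical maximum with the ``omega_m`` ratio."""
    g_n = (inputs.dbar_ref / inputs.dbar_target) * inputs.g_n_ref
    g_l = (inputs.omega_m_ref / inputs.omega_m_target) * inputs.g_l_ref
    return g_n, g_l


def smallest_positive_laplacian_eigenvalue(adj: np.ndarray,
                                           tol: float = 1e-9) -> float:
    """Smallest positive eigenvalue of the (combinatorial) graph
    Laplacian ``G = K - A``."""
    adj = np.asarray(adj, dtype=float)
    G = np.diag(adj.sum(axis=1)) - adj
    ev = np.linalg.eigvalsh(G)
    pos = ev[ev > tol]
    if pos.size == 0:
        raise ValueError("Laplacian has no positive eigenvalue")
    return float(pos[0])


def degree_profiles(adj: np.ndarray):
    """Degree-class profiles over the normalized degree ``kbar = k/k_max``.

    Nodes are grouped by their exact normalized degree (discrete degree
    classes, no histogram binning).  Returns three dicts keyed by kbar:
    the degree pdf, the mean local clustering ``CC(kbar)``, and the mean
    normalized neighbour degree ``knn(kbar)``.
    """
    adj = np.asarray(adj)
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    g = _as_nx(adj)
    k = adj.sum(axis=1).astype(float)
    kmax = k.max()
    if kmax == 0:
        raise ValueError("graph has no edges")
    kbar = k / kmax
    clustering = nx.clustering(g)
    pdf, cc, knn = {}, {}, {}
    for val in np.unique(kbar):
        nodes = np.nonzero(kbar == val)[0]
        pdf[float(val)] = len(nodes) / adj.shape[0]
        cc[float(val)] = float(np.mean([clustering[i] for i in nodes]))
        knn_vals = []
        for i in nodes:
            nbrs = np.nonzero(adj[i])[0]
            if nbrs.size:
                knn_vals.append(kbar[nbrs].mean())
        knn[float(val)] = float(np.mean(knn_vals)) if knn_vals else np.nan
    return pdf, cc, knn


def structure_report(adj: np.ndarray, n_random: int = 100, rng=None,
                     walktrap_steps: int = 6) -> StructureReport:
    """Full structural summary of one adjacency matrix."""
    mu, gamma, sigma = small_worldness(adj, n_random=n_random, rng=rng)
    labels = detect_communities(adj, steps=walktrap_steps)
    Q = modularity(adj, labels)
    pdf, cc, knn = degree_profiles(adj)
    g = _as_nx(adj)
    return StructureReport(
        mean_clustering=float(nx.average_clustering(g)),
        mean_shortest_path=float(nx.average_shortest_path_length(g)),
        mu=mu, gamma=gamma, sigma_sw=sigma, modularity=Q,
        community_labels=labels, degree_pdf=pdf, cc_profile=cc,
        knn_profile=knn)
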