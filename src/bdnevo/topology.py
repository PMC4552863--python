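"""Connectome construction and I/O.

A brain dynamical network (BDN) couples neurons through two undirected
binary adjacency matrices: ``A`` for electrical (gap-junction, diffusive)
synapses and ``B`` for chemical (excitatory, sigmoidal) synapses.  The
model-generated connectomes used for network evolution place electrical
links strictly inside clusters and chemical links strictly between
clusters; empirical connectomes carry a single adjacency used for both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "generate_small_world_cluster",
    "generate_alt_cluster",
    "build_ring_of_clusters",
    "load_connectome",
    "save_connectome",
]

_MAX_RETRIES = 100


@dataclass
class Connectome:
    """Two-layer binary connectome of a brain dynamical network.

    Attributes
    ----------
    electrical_adj : ndarray
        Symmetric 0/1 matrix ``A`` of electrical (diffusive) synapses.
    chemical_adj : ndarray
        Symmetric 0/1 matrix ``B`` of chemical (excitatory) synapses.
    cluster_labels : ndarray or None
        Integer cluster label per neuron; ``None`` for empirical networks
        without a planted modular structure.
    node_names : list or None
        Original node identifiers from a loaded file (internal indexing is
        always 0-based).
    """

    electrical_adj: np.ndarray
    chemical_adj: np.ndarray
    cluster_labels: np.ndarray | None = None
    node_names: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.electrical_adj = np.asarray(self.electrical_adj, dtype=np.int8)
        self.chemical_adj = np.asarray(self.chemical_adj, dtype=np.int8)
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels, dtype=np.int64)
        self.validate()

    @property
    def n_neurons(self) -> int:
        return self.electrical_adj.shape[0]

    @property
    def combined(self) -> np.ndarray:
        """Union adjacency ``C`` (a pair counts as linked if it is linked
        in either layer)."""
        return np.maximum(self.electrical_adj, self.chemical_adj)

    @property
    def electrical_laplacian(self) -> np.ndarray:
        """Graph Laplacian ``G = K - A`` of the electrical layer (float)."""
        A = self.electrical_adj.astype(float)
        return np.diag(A.sum(axis=1)) - A

    def validate(self) -> None:
        for name, M in (("electrical_adj", self.electrical_adj),
                        ("chemical_adj", self.chemical_adj)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square, got shape {M.shape}")
            if not np.array_equal(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(M) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
            if not np.isin(M, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        if self.electrical_adj.shape != self.chemical_adj.shape:
            raise ValueError("electrical and chemical adjacency sizes differ")
        if self.cluster_labels is not None and len(self.cluster_labels) != self.n_neurons:
            raise ValueError("cluster_labels length does not match n_neurons")

    def is_connected(self) -> bool:
        """Connectivity of the combined graph ``C`` (required before any
        Lyapunov-exponent estimation)."""
        g = nx.from_numpy_array(self.combined)
        return nx.is_connected(g)

    def copy(self) -> "Connectome":
        return Connectome(
            self.electrical_adj.copy(),
            self.chemical_adj.copy(),
            None if self.cluster_labels is None else self.cluster_labels.copy(),
            None if self.node_names is None else list(self.node_names),
        )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _nx_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def generate_small_world_cluster(n: int, k_ring: int, p_rewire: float,
                                 rng=None) -> np.ndarray:
    """Connected Watts-Strogatz small-world graph as a 0/1 adjacency.

    A ring lattice of ``n`` nodes each linked to its ``k_ring`` nearest
    neighbours has each edge rewired with probability ``p_rewire``; the
    edge count ``n * k_ring / 2`` is conserved.  Rewirings that disconnect
    the graph are redrawn up to a bounded number of attempts.
    """
    if k_ring % 2 != 0:
        raise ValueError(f"k_ring must be even, got {k_ring}")
    if k_ring < 2:
        raise ValueError(f"k_ring must be >= 2, got {k_ring}")
    if n <= k_ring:
        raise ValueError(f"need n > k_ring, got n={n}, k_ring={k_ring}")
    rng = _as_rng(rng)
    g = nx.connected_watts_strogatz_graph(
        n, k_ring, p_rewire, tries=_MAX_RETRIES, seed=_nx_seed(rng))
    return nx.to_numpy_array(g, dtype=np.int8)


def generate_alt_cluster(kind: str, n: int, params: dict | None = None,
                         rng=None) -> np.ndarray:
    """Connected cluster graph of an alternative family.

    kind
        ``erdos_renyi`` (param ``p``), ``barabasi_albert`` (param ``m``),
        or ``perturbed_star`` (param ``f``, the fraction of star edges
        rewired to uniformly random non-star pairs; default 0.20).
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    params = dict(params or {})
    rng = _as_rng(rng)
    if kind == "erdos_renyi":
        p = params.get("p", 0.3)
        for _ in range(_MAX_RETRIES):
            g = nx.gnp_random_graph(n, p, seed=_nx_seed(rng))
            if nx.is_connected(g):
                return nx.to_numpy_array(g, dtype=np.int8)
        raise RuntimeError(
            f"could not draw a connected G({n}, {p}) in {_MAX_RETRIES} attempts")
    if kind == "barabasi_albert":
        m = params.get("m", 2)
        g = nx.barabasi_albert_graph(n, m, seed=_nx_seed(rng))
        return nx.to_numpy_array(g, dtype=np.int8)
    if kind == "perturbed_star":
        f = params.get("f", 0.20)
        return _perturbed_star(n, f, rng)
    raise ValueError(f"unknown cluster kind: {kind!r}")


def _perturbed_star(n: int, f: float, rng: np.random.Generator) -> np.ndarray:
    """Star graph with a fraction ``f`` of its spokes rewired to random
    non-star (leaf-leaf) pairs, conserving the edge count."""
    n_rewire = int(round(f * (n - 1)))
    for _ in range(_MAX_RETRIES):
        g = nx.star_graph(n - 1)  # node 0 is the hub
        removable = [tuple(e) for e in g.edges()]
        idx = rng.choice(len(removable), size=n_rewire, replace=False)
        for i in idx:
            g.remove_edge(*removable[i])
        leaf_pairs = [(u, v) for u in range(1, n) for v in range(u + 1, n)
                      if not g.has_edge(u, v)]
        new_idx = rng.choice(len(leaf_pairs), size=n_rewire, replace=False)
        for i in new_idx:
            g.add_edge(*leaf_pairs[i])
        if nx.is_connected(g):
            return nx.to_numpy_array(g, dtype=np.int8)
    raise RuntimeError(
        f"perturbed star stayed disconnected after {_MAX_RETRIES} attempts")


_CLUSTER_GENERATORS = {
    "small_world": lambda n, params, rng: generate_small_world_cluster(
        n, params.get("k_ring", 4), params.get("p_rewire", 0.1), rng),
    "erdos_renyi": lambda n, params, rng: generate_alt_cluster("erdos_renyi", n, params, rng),
    "barabasi_albert": lambda n, params, rng: generate_alt_cluster("barabasi_albert", n, params, rng),
    "perturbed_star": lambda n, params, rng: generate_alt_cluster("perturbed_star", n, params, rng),
}


def build_ring_of_clusters(N_c: int, n_per_cluster: int,
                           cluster_kind: str = "small_world",
                           cluster_params: dict | None = None,
                           rng=None) -> Connectome:
    """Starting topology for network evolution: a closed ring of clusters.

    ``N_c`` clusters of electrically coupled neurons are generated
    independently and placed on the block diagonal of ``A``.  One hub per
    cluster (its maximum-degree node, smallest index on ties) is linked to
    the hub of each neighbouring cluster by a chemical synapse, so ``B``
    is a single cycle of ``N_c`` inter-cluster links.
    """
    if N_c < 3:
        raise ValueError(f"need N_c >= 3, got {N_c}")
    if n_per_cluster < 3:
        raise ValueError(f"need n_per_cluster >= 3, got {n_per_cluster}")
    if cluster_kind not in _CLUSTER_GENERATORS:
        raise ValueError(f"unknown cluster_kind: {cluster_kind!r}")
    rng = _as_rng(rng)
    params = dict(cluster_params or {})

    N_n = N_c * n_per_cluster
    A = np.zeros((N_n, N_n), dtype=np.int8)
    B = np.zeros((N_n, N_n), dtype=np.int8)
    labels = np.repeat(np.arange(N_c), n_per_cluster)
    hubs = []
    for c in range(N_c):
        adj = _CLUSTER_GENERATORS[cluster_kind](n_per_cluster, params, rng)
        if not nx.is_connected(nx.from_numpy_array(adj)):
            raise RuntimeError(f"cluster {c} graph is disconnected")
        lo = c * n_per_cluster
        A[lo:lo + n_per_cluster, lo:lo + n_per_cluster] = adj
        hubs.append(lo + int(np.argmax(adj.sum(axis=1))))
    for c in range(N_c):
        i, j = hubs[c], hubs[(c + 1) % N_c]
        B[i, j] = B[j, i] = 1
    return Connectome(A, B, cluster_labels=labels)


# ---------------------------------------------------------------------------
# File I/O


def _read_edge_list(path: str) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'u v' edge, got {raw.strip()!r}")
            u, v = parts[0], parts[1]
            if u == v:
                warnings.warn(f"{path}:{lineno}: self-loop on {u!r} dropped")
                g.add_node(u)
                continue
            g.add_edge(u, v)
    return g


def _read_csv_matrix(path: str) -> np.ndarray:
    import pandas as pd

    with open(path) as fh:
        tokens = fh.readline().rstrip("\n").split(",")

    def _numeric(tok: str) -> bool:
        try:
            return np.isfinite(float(tok))
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens)
    df = pd.read_csv(path, header=0 if has_header else None,
                     index_col=0 if has_header else None)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(
            f"{path}: adjacency matrix must be square, got {M.shape}")
    if not np.isfinite(M).all():
        bad = np.argwhere(~np.isfinite(M))[0]
        raise ValueError(f"{path}: non-finite entry at cell {tuple(bad)}")
    return M


def load_connectome(path: str, format: str = "edge_list") -> Connectome:
    """Read an empirical connectome and normalize it for simulation.

    The loaded graph is symmetrized (an arc in either direction becomes an
    undirected link), binarized, stripped of self-loops, and isolated
    nodes are removed.  Both the electrical and the chemical layer are set
    to the loaded adjacency; pass two files and combine by hand to split
    the layers.  Original node labels are kept in ``node_names``.
    """
    if format == "edge_list":
        g = _read_edge_list(path)
    elif format == "csv_matrix":
        M = _read_csv_matrix(path)
        if np.any(np.diag(M) != 0):
            warnings.warn(f"{path}: self-loops on the diagonal dropped")
            np.fill_diagonal(M, 0)
        g = nx.from_numpy_array((np.maximum(M, M.T) > 0).astype(np.int8))
    elif format == "graphml":
        g = nx.Graph(nx.read_graphml(path))
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise ValueError(f"unknown format: {format!r}")

    isolated = list(nx.isolates(g))
    if isolated:
        logger.info("removing %d isolated node(s): %s", len(isolated), isolated)
        g.remove_nodes_from(isolated)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no connected nodes remain")
    try:  # numeric labels sort numerically, anything else lexically
        names = sorted(g.nodes(), key=float)
    except (TypeError, ValueError):
        names = sorted(g.nodes(), key=str)
    adj = nx.to_numpy_array(g, nodelist=names, dtype=np.int8)
    adj = (adj > 0).astype(np.int8)
    return Connectome(adj, adj.copy(), node_names=list(names))


def save_connectome(net: Connectome, path: str, format: str = "edge_list",
                    layer: str = "combined") -> None:
    """Write one layer (``electrical``, ``chemical`` or ``combined``) of a
    connectome as an edge list, dense CSV matrix, or GraphML file."""
    M = {"electrical": net.electrical_adj, "chemical": net.chemical_adj,
         "combined": net.combined}[layer]
    names = net.node_names or list(range(net.n_neurons))
    if format == "edge_list":
        with open(path, "w") as fh:
            fh.write(f"# {layer} layer, {net.n_neurons} nodes\n")
            for i, j in zip(*np.nonzero(np.triu(M))):
                fh.write(f"{names[i]} {names[j]}\n")
    elif format == "csv_matrix":
        import pandas as pd

        pd.DataFrame(M, index=names, columns=names).to_csv(path)
    elif format == "graphml":
        g = nx.from_numpy_array(M)
        nx.relabel_nodes(g, dict(enumerate(names)), copy=False)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def save_cluster_labels(net: Connectome, path: str) -> None:
    """Write cluster labels as a two-column ``node,label`` CSV."""
    if net.cluster_labels is None:
        raise ValueError("connectome has no cluster labels")
    names = net.node_names or list(range(net.n_neurons))
    with open(path, "w") as fh:
        fh.write("node,label\n")
        for name, lab in zip(names, net.cluster_labels):
            fh.write(f"{name},{lab}\n")
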