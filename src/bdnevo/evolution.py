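"""Network evolution by maximization of information flow capacity.

Starting from a ring of electrically coupled clusters joined by a cycle of
chemical links, candidate chemical synapses between neurons of *different*
clusters are tried one by one in uniformly random order.  A candidate is
retained iff it strictly increases the information flow capacity
``I_c = lambda1 - lambda2`` of the network; otherwise it is removed.  The
electrical topology and both coupling strengths are never modified, no
intra-cluster chemical link is ever added, and links are never deleted.
Every inter-cluster pair is visited exactly once, so the run ends when the
candidate pool is exhausted; the final ``I_c`` is called mMIR and can
never fall below the starting value.

After each acceptance the global order parameter and the per-cluster mean
pairwise synchronization are recorded; regressing them on the acceptance
index classifies each cluster's trend as Hebbian-like (synchrony grows as
synapses are added) or no-Hebbian-like (synchrony decays).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import HRParams, SimConfig, SynapseParams, initial_state, simulate
from .lyapunov import two_largest_exponents
from .synchronization import cluster_mean_sync, order_parameter, pairwise_sync
from .topology import Connectome

logger = logging.getLogger(__name__)

__all__ = ["EvolutionTrace", "evolve", "sync_slopes"]


@dataclass
class EvolutionTrace:
    """Record of one evolution run.

    ``ic_history[0]`` is the starting capacity; each later entry follows
    an accepted link, so the series is strictly increasing after index 0.
    ``rho_history`` and ``cluster_sync_history`` are aligned with it.
    """

    accepted_links: list = field(default_factory=list)
    ic_history: list = field(default_factory=list)
    rho_history: list = field(default_factory=list)
    cluster_sync_history: list = field(default_factory=list)
    n_candidates_tested: int = 0
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def mMIR(self) -> float:
        """Information flow capacity of the finally evolved network."""
        return self.ic_history[-1]

    def to_json(self, path: str) -> None:
        payload = {
            "accepted_links": [[int(i), int(j)] for i, j in self.accepted_links],
            "ic_history": [float(x) for x in self.ic_history],
            "rho_history": [float(x) for x in self.rho_history],
            "cluster_sync_history": [[float(x) for x in row]
                                     for row in self.cluster_sync_history],
            "n_candidates_tested": self.n_candidates_tested,
            "mMIR": float(self.mMIR),
            "seed": self.seed,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "EvolutionTrace":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            accepted_links=[tuple(e) for e in d["accepted_links"]],
            ic_history=d["ic_history"], rho_history=d["rho_history"],
            cluster_sync_history=d["cluster_sync_history"],
            n_candidates_tested=d["n_candidates_tested"],
            seed=d.get("seed"), config=d.get("config", {}))


def inter_cluster_candidates(net: Connectome) -> list[tuple[int, int]]:
    """All unordered pairs of neurons in distinct clusters that are not
    yet chemically linked."""
    labels = net.cluster_labels
    B = net.chemical_adj
    N = net.n_neurons
    return [(i, j) for i in range(N) for j in range(i + 1, N)
            if labels[i] != labels[j] and B[i, j] == 0]


def _sync_point(net, hr, syn, cfg, state0):
    traj = simulate(net, hr, syn, cfg, state0=state0)
    post = traj.post_transient()
    _, rho, _ = order_parameter(post.phi)
    rho_pair = pairwise_sync(post.phi, net)
    cl = cluster_mean_sync(rho_pair, net.cluster_labels, net.combined)
    return rho, cl


def evolve(start: Connectome, hr: HRParams = HRParams(),
           syn: SynapseParams = SynapseParams(),
           cfg: SimConfig = SimConfig(), rng=None,
           candidate_cfg: SimConfig | None = None,
           ) -> tuple[Connectome, EvolutionTrace]:
    """Grow the chemical layer greedily under the capacity criterion.

    ``rng`` (or ``cfg.seed``) fixes both the candidate visiting order and
    the initial condition; the same seed-derived state is reused for every
    candidate evaluation so that ``I_c`` comparisons are not confounded by
    initial-condition noise.  ``candidate_cfg`` may shorten the
    per-candidate Lyapunov runs (only the comparison sign matters); it
    defaults to ``cfg``.
    """
    if start.cluster_labels is None:
        raise ValueError("evolution requires a connectome with cluster_labels")
    seed = cfg.seed
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    candidate_cfg = candidate_cfg or cfg

    net = start.copy()
    state0 = initial_state(net, rng)
    candidates = inter_cluster_candidates(net)
    order = rng.permutation(len(candidates))

    trace = EvolutionTrace(seed=seed, config={
        "g_n": syn.g_n, "g_l": syn.g_l, "dt": cfg.dt, "t_f": cfg.t_f,
        "t_t": cfg.t_t, "candidate_t_f": candidate_cfg.t_f})
    current_ic = two_largest_exponents(
        net, hr, syn, candidate_cfg, state0=state0).info_capacity
    trace.ic_history.append(current_ic)
    rho, cl = _sync_point(net, hr, syn, cfg, state0)
    trace.rho_history.append(rho)
    trace.cluster_sync_history.append(cl)

    for idx in order:
        i, j = candidates[idx]
        trace.n_candidates_tested += 1
        net.chemical_adj[i, j] = net.chemical_adj[j, i] = 1
        try:
            ic = two_largest_exponents(
                net, hr, syn, candidate_cfg, state0=state0).info_capacity
        except FloatingPointError as exc:
            logger.warning("candidate (%d, %d) rejected: %s", i, j, exc)
            net.chemical_adj[i, j] = net.chemical_adj[j, i] = 0
            continue
        if ic > current_ic:
            current_ic = ic
            trace.accepted_links.append((i, j))
            trace.ic_history.append(ic)
            rho, cl = _sync_point(net, hr, syn, cfg, state0)
            trace.rho_history.append(rho)
            trace.cluster_sync_history.append(cl)
            logger.debug("accepted link (%d, %d): I_c=%.5f", i, j, ic)
        else:
            net.chemical_adj[i, j] = net.chemical_adj[j, i] = 0
            logger.debug("rejected link (%d, %d): I_c=%.5f <= %.5f",
                         i, j, ic, current_ic)
    return net, trace


def sync_slopes(trace: EvolutionTrace):
    """Synchronization trends over the growth process.

    Ordinary least-squares slopes of the global order parameter and of
    each cluster's mean pairwise synchrony against the acceptance index.
    A positive slope is labelled ``hebbian_like`` (adding synapses raises
    synchrony), a non-positive one ``no_hebbian_like``.

    Returns ``(theta_global, theta_clusters, labels)``.
    """
    n_accept = len(trace.ic_history) - 1
    if n_accept < 3:
        raise ValueError(
            f"need at least 3 acceptance events to fit slopes, got {n_accept}")
    x = np.arange(len(trace.rho_history), dtype=float)
    theta_global = float(np.polyfit(x, np.asarray(trace.rho_history, dtype=float), 1)[0])
    cl = np.asarray(trace.cluster_sync_history, dtype=float)
    theta_clusters = []
    labels = []
    for c in range(cl.shape[1]):
        y = cl[:, c]
        ok = np.isfinite(y)
        slope = float(np.polyfit(x[ok], y[ok], 1)[0]) if ok.sum() >= 2 else np.nan
        theta_clusters.append(slope)
        labels.append("hebbian_like" if slope > 0 else "no_hebbian_like")
    return theta_global, np.array(theta_clusters), labels
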