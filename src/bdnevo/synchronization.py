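"""Phase-synchronization measures for brain dynamical networks.

Global coherence is the Kuramoto order parameter: the modulus of the
population-mean phasor ``z(t) = (1/N) sum_j exp(i phi_j(t))``, averaged
over time.  ``rho = 1`` is complete phase synchronization, ``rho = 0``
complete desynchronization.  Pairwise coherence ``rho_ij`` is the modulus
of the time-averaged phasor of the phase difference of a *connected* pair
(the adjacency masks unconnected pairs to zero), and cluster-level
synchrony is the mean of ``rho_ij`` over connected intra-cluster pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .topology import Connectome

__all__ = [
    "SyncResult",
    "order_parameter",
    "pairwise_sync",
    "cluster_mean_sync",
    "sync_measures",
]

_MIN_SAMPLES = 10


@dataclass
class SyncResult:
    rho_t: np.ndarray
    rho: float
    Phi_t: np.ndarray
    rho_pair: np.ndarray
    cluster_means: np.ndarray | None
    window: float  # length of the averaging window (t_f - t_t surrogate)

    def rho_pair_long(self):
        """Pairwise synchronization as a long-format (i, j, value) table."""
        import pandas as pd

        i, j = np.triu_indices_from(self.rho_pair, k=1)
        return pd.DataFrame({"i": i, "j": j, "value": self.rho_pair[i, j]})


def order_parameter(phases: np.ndarray):
    """Kuramoto order parameter of a phase record.

    Parameters
    ----------
    phases : ndarray, shape (n_samples, n_neurons)
        Post-transient unwrapped phases.

    Returns
    -------
    rho_t : instantaneous coherence series in [0, 1]
    rho : time-averaged order parameter
    Phi_t : mean-phase series
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.size == 0 or phases.shape[1] == 0:
        raise ValueError("order_parameter needs at least one neuron and sample")
    z = np.exp(1j * phases).mean(axis=1)
    rho_t = np.abs(z)
    return rho_t, float(rho_t.mean()), np.angle(z)


def pairwise_sync(phases: np.ndarray, net: Connectome) -> np.ndarray:
    """Pairwise phase-locking matrix ``rho_ij`` over the finite recording
    window (surrogate for the infinite-time average).

    Entry (i, j) is ``C_ij * | < exp(i (phi_i - phi_j)) >_t |``; pairs not
    linked in the combined adjacency are exactly zero.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] < _MIN_SAMPLES:
        raise ValueError(
            f"averaging window has {phases.shape[0]} samples; "
            f"need at least {_MIN_SAMPLES}")
    if phases.shape[1] != net.n_neurons:
        raise ValueError("phase record width does not match the connectome")
    E = np.exp(1j * phases)
    M = (E.T.conj() @ E) / phases.shape[0]  # M[i, j] = <exp(i(phi_j - phi_i))>
    rho = np.abs(M) * net.combined
    rho = (rho + rho.T) / 2  # enforce exact symmetry against rounding
    np.fill_diagonal(rho, 0.0)
    return np.minimum(rho, 1.0)


def cluster_mean_sync(rho_pair: np.ndarray, cluster_labels: np.ndarray,
                      adj: np.ndarray) -> np.ndarray:
    """Per-cluster mean of ``rho_ij`` over connected intra-cluster pairs.

    A cluster with no internal links has no defined synchrony level and is
    reported as NaN (never as 0, which would mean full drift).
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != rho_pair.shape[0]:
        raise ValueError("cluster_labels must cover every neuron")
    out = []
    for c in np.unique(labels):
        nodes = np.nonzero(labels == c)[0]
        sub_adj = adj[np.ix_(nodes, nodes)]
        iu = np.triu_indices(len(nodes), k=1)
        mask = sub_adj[iu] > 0
        if not mask.any():
            out.append(np.nan)
        else:
            out.append(float(rho_pair[np.ix_(nodes, nodes)][iu][mask].mean()))
    return np.array(out)


def sync_measures(traj: Trajectory, net: Connectome) -> SyncResult:
    """All synchronization measures of a trajectory, computed on the
    post-transient samples only."""
    post = traj.post_transient()
    rho_t, rho, Phi_t = order_parameter(post.phi)
    rho_pair = pairwise_sync(post.phi, net)
    cluster_means = None
    if net.cluster_labels is not None:
        cluster_means = cluster_mean_sync(rho_pair, net.cluster_labels,
                                          net.combined)
    window = float(post.times[-1] - post.times[0]) if len(post.times) > 1 else 0.0
    return SyncResult(rho_t, rho, Phi_t, rho_pair, cluster_means, window)
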