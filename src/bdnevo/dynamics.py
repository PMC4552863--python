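"""Coupled Hindmarsh-Rose brain dynamical network.

Each neuron carries the three-variable Hindmarsh-Rose (HR) system — the
membrane potential ``p``, a fast recovery current ``q`` and a slow
adaptation current ``n`` — at the standard spike-bursting parameters, for
which each uncoupled neuron is chaotic.  Neurons are coupled by two layers:

* electrical synapses: linear diffusive coupling ``-g_l * sum_j G_ij p_j``
  through the graph Laplacian ``G = K - A`` of the electrical adjacency;
* chemical excitatory synapses: ``-g_n (p_i - V_syn) * sum_j B_ij S(p_j)``
  with a sigmoidal activation ``S``.

A fourth state variable, the phase ``phi_i`` defined from the fast pair
``(p_i, q_i)``, is integrated alongside and feeds the synchronization
measures; it never feeds back into the dynamics.

Integration is explicit first-order Euler with step ``dt = 0.01``, the
reference protocol for this model; statistics downstream must exclude the
transient (``t < t_t``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .topology import Connectome

logger = logging.getLogger(__name__)

__all__ = [
    "HRParams",
    "SynapseParams",
    "SimConfig",
    "Trajectory",
    "chemical_activation",
    "vector_field",
    "initial_state",
    "simulate",
]

# Initial conditions that place the trajectory quickly on the attractor;
# each neuron gets a single uniform jitter eta_i in [0, 0.5] added to all
# three coordinates.
P_BASE = -1.30784489
Q_BASE = -7.32183132
N_BASE = 3.35299859


@dataclass(frozen=True)
class HRParams:
    """Constants of the single-neuron Hindmarsh-Rose system.

    Defaults give multi-scale chaotic spike bursting; ``r`` sets the slow
    timescale and ``p0`` the resting-potential offset.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    s: float = 4.0
    p0: float = -1.6
    I_ext: float = 3.25
    r: float = 0.005

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class SynapseParams:
    """Chemical-synapse sigmoid and the two coupling strengths.

    ``V_syn = 2`` keeps ``(p_i - V_syn) < 0`` on the attractor (where
    ``|p| < 2``), so the chemical coupling is excitatory.
    """

    theta_syn: float = -0.25
    lambda_sig: float = 10.0
    V_syn: float = 2.0
    g_n: float = 0.0
    g_l: float = 0.0

    def __post_init__(self):
        if self.g_n < 0 or self.g_l < 0:
            raise ValueError("coupling strengths must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.01
    t_f: float = 2500.0
    t_t: float = 300.0
    seed: int | None = None
    record_stride: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.t_t < self.t_f:
            raise ValueError(f"need 0 < t_t < t_f, got t_t={self.t_t}, t_f={self.t_f}")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Recorded state series; rows are samples, columns neurons."""

    times: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_slow: np.ndarray
    phi: np.ndarray
    t_t: float = 0.0

    @property
    def is_transient(self) -> np.ndarray:
        return self.times < self.t_t

    def post_transient(self) -> "Trajectory":
        """View restricted to samples at or after the transient time; all
        statistics are computed on these samples."""
        m = ~self.is_transient
        return Trajectory(self.times[m], self.p[m], self.q[m],
                          self.n_slow[m], self.phi[m], t_t=self.t_t)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        n_s, n_n = self.p.shape
        pd.DataFrame({
            "time": np.repeat(self.times, n_n),
            "neuron": np.tile(np.arange(n_n), n_s),
            "p": self.p.ravel(),
            "q": self.q.ravel(),
            "n": self.n_slow.ravel(),
            "phi": self.phi.ravel(),
        }).to_csv(path, index=False)


def chemical_activation(p, params: SynapseParams = SynapseParams()):
    """Sigmoidal activation S(p) of the chemical synapses, in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-params.lambda_sig * (np.asarray(p, dtype=float)
                                                     - params.theta_syn)))


def _csr(adj: np.ndarray):
    """Adjacency rows packed as (indptr, indices) int64 arrays."""
    N = adj.shape[0]
    indptr = np.zeros(N + 1, dtype=np.int64)
    cols = []
    for i in range(N):
        nz = np.nonzero(adj[i])[0]
        cols.append(nz)
        indptr[i + 1] = indptr[i] + len(nz)
    indices = (np.concatenate(cols) if cols else np.empty(0)).astype(np.int64)
    return indptr, indices


def vector_field(state: np.ndarray, hr: HRParams, syn: SynapseParams,
                 net: Connectome) -> np.ndarray:
    """Time derivative of the full network state.

    ``state`` is the concatenation ``(p, q, n, phi)`` of length ``4 N_n``.
    Where ``p_i^2 + q_i^2`` vanishes the phase derivative is undefined; it
    is set to 0 for that neuron and a debug message logged.
    """
    N = net.n_neurons
    if state.shape != (4 * N,):
        raise ValueError(f"state must have length {4 * N}, got {state.shape}")
    p, q, n = state[:N], state[N:2 * N], state[2 * N:3 * N]
    S = chemical_activation(p, syn)
    B = net.chemical_adj.astype(float)
    G = net.electrical_laplacian
    pdot = (q - hr.a * p**3 + hr.b * p**2 - n + hr.I_ext
            - syn.g_n * (p - syn.V_syn) * (B @ S)
            - syn.g_l * (G @ p))
    qdot = hr.c - hr.d * p**2 - q
    ndot = hr.r * (hr.s * (p - hr.p0) - n)
    denom = p**2 + q**2
    phidot = np.zeros(N)
    ok = denom > 0
    if not ok.all():
        logger.debug("phase derivative undefined for %d neuron(s); set to 0",
                     int((~ok).sum()))
    phidot[ok] = (qdot[ok] * p[ok] - pdot[ok] * q[ok]) / denom[ok]
    return np.concatenate([pdot, qdot, ndot, phidot])


def initial_state(net: Connectome, rng=None, independent_jitter: bool = False
                  ) -> np.ndarray:
    """Seeded initial condition near the bursting attractor.

    Each neuron starts at the common base point with a uniform jitter
    ``eta_i ~ U[0, 0.5]``; by default the same draw offsets ``p_i``,
    ``q_i`` and ``n_i``.  Phases start at 0.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    N = net.n_neurons
    if independent_jitter:
        ep, eq, en = rng.uniform(0, 0.5, (3, N))
    else:
        ep = eq = en = rng.uniform(0, 0.5, N)
    return np.concatenate([P_BASE + ep, Q_BASE + eq, N_BASE + en, np.zeros(N)])


@njit(cache=True)
def _euler_kernel(p, q, n, phi,
                  A_indptr, A_indices, deg_e, B_indptr, B_indices,
                  a, b, c, d, s, p0, Iext, r, theta, lam, Vsyn, gn, gl,
                  dt, n_steps, record_stride,
                  out_p, out_q, out_n, out_phi):  # pragma: no cover - jit
    N = p.shape[0]
    S = np.empty(N)
    pdot = np.empty(N)
    qdot = np.empty(N)
    ndot = np.empty(N)
    phidot = np.empty(N)
    rec = 0
    for step in range(n_steps + 1):
        if step % record_stride == 0:
            for i in range(N):
                out_p[rec, i] = p[i]
                out_q[rec, i] = q[i]
                out_n[rec, i] = n[i]
                out_phi[rec, i] = phi[i]
            rec += 1
        if step == n_steps:
            break
        for i in range(N):
            S[i] = 1.0 / (1.0 + np.exp(-lam * (p[i] - theta)))
        for i in range(N):
            chem = 0.0
            for jj in range(B_indptr[i], B_indptr[i + 1]):
                chem += S[B_indices[jj]]
            elec = deg_e[i] * p[i]
            for jj in range(A_indptr[i], A_indptr[i + 1]):
                elec -= p[A_indices[jj]]
            pdot[i] = (q[i] - a * p[i]**3 + b * p[i]**2 - n[i] + Iext
                       - gn * (p[i] - Vsyn) * chem - gl * elec)
            qdot[i] = c - d * p[i]**2 - q[i]
            ndot[i] = r * (s * (p[i] - p0) - n[i])
            denom = p[i] * p[i] + q[i] * q[i]
            phidot[i] = (qdot[i] * p[i] - pdot[i] * q[i]) / denom if denom > 0.0 else 0.0
        for i in range(N):
            p[i] += dt * pdot[i]
            q[i] += dt * qdot[i]
            n[i] += dt * ndot[i]
            phi[i] += dt * phidot[i]
            if not (np.isfinite(p[i]) and np.isfinite(q[i]) and np.isfinite(n[i])):
                return step + 1, i
    return -1, -1


def simulate(net: Connectome, hr: HRParams = HRParams(),
             syn: SynapseParams = SynapseParams(),
             cfg: SimConfig = SimConfig(), rng=None,
             state0: np.ndarray | None = None) -> Trajectory:
    """Forward-Euler integration of the coupled network.

    ``rng`` (or ``cfg.seed``) seeds the initial-condition jitter; an
    explicit ``state0`` overrides it.  Samples every ``record_stride``
    steps are stored, including t=0; those before ``cfg.t_t`` are flagged
    transient.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if state0 is None:
        state0 = initial_state(net, rng)
    N = net.n_neurons
    if state0.shape != (4 * N,):
        raise ValueError(f"state0 must have length {4 * N}")
    n_steps = int(round(cfg.t_f / cfg.dt))
    n_rec = n_steps // cfg.record_stride + 1
    out = [np.empty((n_rec, N)) for _ in range(4)]
    A_indptr, A_indices = _csr(net.electrical_adj)
    B_indptr, B_indices = _csr(net.chemical_adj)
    deg_e = net.electrical_adj.sum(axis=1).astype(np.float64)
    p, q, n, phi = (state0[:N].copy(), state0[N:2 * N].copy(),
                    state0[2 * N:3 * N].copy(), state0[3 * N:].copy())
    bad_step, bad_neuron = _euler_kernel(
        p, q, n, phi, A_indptr, A_indices, deg_e, B_indptr, B_indices,
        hr.a, hr.b, hr.c, hr.d, hr.s, hr.p0, hr.I_ext, hr.r,
        syn.theta_syn, syn.lambda_sig, syn.V_syn, syn.g_n, syn.g_l,
        cfg.dt, n_steps, cfg.record_stride, *out)
    if bad_step >= 0:
        raise FloatingPointError(
            f"numerical overflow at step {bad_step} (t={bad_step * cfg.dt:.3f}) "
            f"in neuron {bad_neuron}; reduce dt or couplings")
    times = np.arange(n_rec) * (cfg.record_stride * cfg.dt)
    return Trajectory(times, out[0], out[1], out[2], out[3], t_t=cfg.t_t)
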