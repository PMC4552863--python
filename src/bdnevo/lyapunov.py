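"""Two largest Lyapunov exponents and the information-flow-capacity bound.

The mutual information rate (MIR) between any two nodes of a connected
dynamical network is bounded above by ``I_c = lambda_1 - lambda_2``, the
gap between the two largest Lyapunov exponents of the network dynamics.
``I_c`` serves as the network's information flow capacity: it is large
near criticality (``lambda_1 > 0``, ``lambda_2`` marginally positive) and
collapses to ~0 when the network synchronizes (``lambda_1 ≈ lambda_2``).

Exponents are computed with the classical Benettin tangent-space method:
two tangent vectors are evolved under the analytic Jacobian alongside the
trajectory and re-orthonormalized (Gram-Schmidt) at a fixed interval; the
exponents are the time-averaged log stretch factors accumulated after the
transient.  The tangent space covers the ``(p, q, n)`` coordinates only:
the phases never feed back into the dynamics, so including them would only
add a spurious neutral direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dynamics import HRParams, SimConfig, SynapseParams, _csr, initial_state
from .topology import Connectome

__all__ = [
    "LyapunovEstimate",
    "two_largest_exponents",
    "info_capacity",
    "benettin_exponents",
    "tangent_apply",
]


@dataclass
class LyapunovEstimate:
    """Result of a two-exponent Benettin run.

    ``history`` has one row per re-orthonormalization after the transient:
    (time, running lambda1, running lambda2).
    """

    lambda1: float
    lambda2: float
    history: np.ndarray

    def __post_init__(self):
        if self.lambda1 < self.lambda2:
            raise ValueError("lambda1 must be >= lambda2")

    @property
    def info_capacity(self) -> float:
        return info_capacity(self.lambda1, self.lambda2)

    def history_to_csv(self, path: str) -> None:
        np.savetxt(path, self.history, delimiter=",",
                   header="time,lambda1_running,lambda2_running", comments="")


def info_capacity(lambda1: float, lambda2: float) -> float:
    """Upper bound ``I_c = lambda1 - lambda2`` for the mutual information
    rate between any two nodes of the network."""
    if lambda1 < lambda2:
        raise ValueError(
            f"lambda1 ({lambda1}) must be >= lambda2 ({lambda2}); "
            "arguments are ordered")
    return lambda1 - lambda2


@njit(cache=True)
def _lyap_kernel(p, q, n, A_indptr, A_indices, deg_e, B_indptr, B_indices,
                 a, b, c, d, s, p0, Iext, r, theta, lam, Vsyn, gn, gl,
                 dt, n_steps, transient_steps, renorm_interval,
                 v1, v2, hist):  # pragma: no cover - jit
    N = p.shape[0]
    S = np.empty(N)
    Sp = np.empty(N)
    pdot = np.empty(N)
    qdot = np.empty(N)
    ndot = np.empty(N)
    w1 = np.empty(3 * N)
    w2 = np.empty(3 * N)
    sum_log1 = 0.0
    sum_log2 = 0.0
    T = 0.0
    n_hist = 0
    n_reinit = 0
    for step in range(n_steps):
        for i in range(N):
            S[i] = 1.0 / (1.0 + np.exp(-lam * (p[i] - theta)))
            Sp[i] = lam * S[i] * (1.0 - S[i])
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
            # Jacobian applied to both tangent vectors
            diag = -3.0 * a * p[i]**2 + 2.0 * b * p[i] - gn * chem - gl * deg_e[i]
            off1 = 0.0
            off2 = 0.0
            for jj in range(A_indptr[i], A_indptr[i + 1]):
                off1 += v1[A_indices[jj]]
                off2 += v2[A_indices[jj]]
            off1 *= gl
            off2 *= gl
            coef = -gn * (p[i] - Vsyn)
            for jj in range(B_indptr[i], B_indptr[i + 1]):
                j = B_indices[jj]
                off1 += coef * Sp[j] * v1[j]
                off2 += coef * Sp[j] * v2[j]
            w1[i] = diag * v1[i] + v1[N + i] - v1[2 * N + i] + off1
            w2[i] = diag * v2[i] + v2[N + i] - v2[2 * N + i] + off2
            w1[N + i] = -2.0 * d * p[i] * v1[i] - v1[N + i]
            w2[N + i] = -2.0 * d * p[i] * v2[i] - v2[N + i]
            w1[2 * N + i] = r * s * v1[i] - r * v1[2 * N + i]
            w2[2 * N + i] = r * s * v2[i] - r * v2[2 * N + i]
        for i in range(N):
            p[i] += dt * pdot[i]
            q[i] += dt * qdot[i]
            n[i] += dt * ndot[i]
            if not (np.isfinite(p[i]) and np.isfinite(q[i]) and np.isfinite(n[i])):
                return np.nan, np.nan, n_hist, n_reinit, step + 1
        for i in range(3 * N):
            v1[i] += dt * w1[i]
            v2[i] += dt * w2[i]
        if (step + 1) % renorm_interval == 0:
            norm1 = 0.0
            for i in range(3 * N):
                norm1 += v1[i] * v1[i]
            norm1 = np.sqrt(norm1)
            if not np.isfinite(norm1):
                return np.nan, np.nan, n_hist, n_reinit, step + 1
            if norm1 == 0.0:
                v1[0] = 1.0
                for i in range(1, 3 * N):
                    v1[i] = 0.0
                norm1 = 1.0
                n_reinit += 1
            else:
                for i in range(3 * N):
                    v1[i] /= norm1
            proj = 0.0
            for i in range(3 * N):
                proj += v2[i] * v1[i]
            for i in range(3 * N):
                v2[i] -= proj * v1[i]
            norm2 = 0.0
            for i in range(3 * N):
                norm2 += v2[i] * v2[i]
            norm2 = np.sqrt(norm2)
            if not np.isfinite(norm2):
                return np.nan, np.nan, n_hist, n_reinit, step + 1
            if norm2 == 0.0:
                idx = 1 if 3 * N > 1 else 0
                for i in range(3 * N):
                    v2[i] = 0.0
                v2[idx] = 1.0
                proj = v2[idx] * v1[idx]
                for i in range(3 * N):
                    v2[i] -= proj * v1[i]
                nrm = 0.0
                for i in range(3 * N):
                    nrm += v2[i] * v2[i]
                nrm = np.sqrt(nrm)
                for i in range(3 * N):
                    v2[i] /= nrm
                norm2 = 1.0
                n_reinit += 1
            else:
                for i in range(3 * N):
                    v2[i] /= norm2
            if step + 1 > transient_steps:
                sum_log1 += np.log(norm1)
                sum_log2 += np.log(norm2)
                T += renorm_interval * dt
                hist[n_hist, 0] = (step + 1) * dt
                hist[n_hist, 1] = sum_log1 / T
                hist[n_hist, 2] = sum_log2 / T
                n_hist += 1
    if T == 0.0:
        return np.nan, np.nan, n_hist, n_reinit, -1
    return sum_log1 / T, sum_log2 / T, n_hist, n_reinit, -1


def two_largest_exponents(net: Connectome, hr: HRParams = HRParams(),
                          syn: SynapseParams = SynapseParams(),
                          cfg: SimConfig = SimConfig(), rng=None,
                          renorm_interval: int = 10,
                          state0: np.ndarray | None = None) -> LyapunovEstimate:
    """Benettin estimate of the two largest exponents of the coupled HR
    network, accumulated over ``[t_t, t_f]``.

    The initial tangent vectors are the first two columns of the identity
    (seed-independent); ``rng``/``cfg.seed`` only affects the initial
    state, and an explicit ``state0`` makes the run fully deterministic.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if state0 is None:
        state0 = initial_state(net, rng)
    N = net.n_neurons
    p, q, n = (state0[:N].copy(), state0[N:2 * N].copy(),
               state0[2 * N:3 * N].copy())
    v1 = np.zeros(3 * N)
    v2 = np.zeros(3 * N)
    v1[0] = 1.0
    v2[min(1, 3 * N - 1)] = 1.0
    n_steps = int(round(cfg.t_f / cfg.dt))
    transient_steps = int(round(cfg.t_t / cfg.dt))
    A_indptr, A_indices = _csr(net.electrical_adj)
    B_indptr, B_indices = _csr(net.chemical_adj)
    deg_e = net.electrical_adj.sum(axis=1).astype(np.float64)
    hist = np.empty((n_steps // renorm_interval + 1, 3))
    l1, l2, n_hist, n_reinit, bad_step = _lyap_kernel(
        p, q, n, A_indptr, A_indices, deg_e, B_indptr, B_indices,
        hr.a, hr.b, hr.c, hr.d, hr.s, hr.p0, hr.I_ext, hr.r,
        syn.theta_syn, syn.lambda_sig, syn.V_syn, syn.g_n, syn.g_l,
        cfg.dt, n_steps, transient_steps, renorm_interval, v1, v2, hist)
    if bad_step >= 0:
        raise FloatingPointError(
            f"non-finite state or tangent growth at step {bad_step} "
            f"(t={bad_step * cfg.dt:.3f})")
    if n_reinit:
        import logging

        logging.getLogger(__name__).warning(
            "degenerate tangent vector reinitialized %d time(s)", n_reinit)
    l1, l2 = max(l1, l2), min(l1, l2)
    return LyapunovEstimate(l1, l2, hist[:n_hist])


def tangent_apply(state: np.ndarray, v: np.ndarray, hr: HRParams,
                  syn: SynapseParams, net: Connectome) -> np.ndarray:
    """Analytic Jacobian of the ``(p, q, n)`` subsystem applied to a
    tangent vector of length ``3 N_n`` (reference implementation used for
    cross-checks against finite differences)."""
    N = net.n_neurons
    p = state[:N]
    dp, dq, dn = v[:N], v[N:2 * N], v[2 * N:3 * N]
    S = 1.0 / (1.0 + np.exp(-syn.lambda_sig * (p - syn.theta_syn)))
    Sp = syn.lambda_sig * S * (1.0 - S)
    A = net.electrical_adj.astype(float)
    B = net.chemical_adj.astype(float)
    deg = A.sum(axis=1)
    chem = B @ S
    diag = -3 * hr.a * p**2 + 2 * hr.b * p - syn.g_n * chem - syn.g_l * deg
    wp = (diag * dp + dq - dn + syn.g_l * (A @ dp)
          - syn.g_n * (p - syn.V_syn) * (B @ (Sp * dp)))
    wq = -2 * hr.d * p * dp - dq
    wn = hr.r * hr.s * dp - hr.r * dn
    return np.concatenate([wp, wq, wn])


def benettin_exponents(f, jac_mul, x0: np.ndarray, dt: float, t_f: float,
                       t_t: float = 0.0, n_exp: int = 2,
                       renorm_interval: int = 10) -> np.ndarray:
    """Generic Benettin/Gram-Schmidt exponent estimator for an arbitrary
    ODE ``x' = f(x)`` integrated with first-order Euler.

    Parameters
    ----------
    f : callable
        ``f(x) -> xdot``.
    jac_mul : callable
        ``jac_mul(x, V) -> J(x) @ V`` for a matrix of tangent columns.
    n_exp : int
        Number of leading exponents to return (sorted descending).

    Used as the independent oracle path: for a constant-coefficient linear
    system the exponents are the leading real parts of the eigenvalues.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    V = np.eye(dim)[:, :n_exp]
    n_steps = int(round(t_f / dt))
    transient_steps = int(round(t_t / dt))
    sum_log = np.zeros(n_exp)
    T = 0.0
    for step in range(n_steps):
        xdot = f(x)
        V = V + dt * jac_mul(x, V)
        x = x + dt * xdot
        if (step + 1) % renorm_interval == 0:
            Q, R = np.linalg.qr(V)
            diag = np.abs(np.diag(R))
            if np.any(diag == 0) or not np.all(np.isfinite(diag)):
                raise FloatingPointError(
                    f"degenerate tangent matrix at step {step + 1}")
            V = Q
            if step + 1 > transient_steps:
                sum_log += np.log(diag)
                T += renorm_interval * dt
    if T == 0.0:
        raise ValueError("no post-transient accumulation; increase t_f")
    return np.sort(sum_log / T)[::-1]
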