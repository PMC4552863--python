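import numpy as np
import pytest

from bdnevo.dynamics import (HRParams, SimConfig, SynapseParams,
                             chemical_activation, initial_state, simulate,
                             vector_field)
from bdnevo.synchronization import order_parameter
from bdnevo.topology import Connectome


class TestChemicalActivation:
    def test_sigmoid_midpoint(self):
        syn = SynapseParams()
        assert chemical_activation(syn.theta_syn, syn) == pytest.approx(0.5)

    def test_saturation(self):
        assert chemical_activation(50.0) == pytest.approx(1.0)
        assert chemical_activation(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_value_at_zero(self):
        # 1 / (1 + exp(-10 * (0 - (-0.25)))) = 1 / (1 + exp(-2.5))
        assert chemical_activation(0.0) == pytest.approx(0.924142, abs=1e-6)

    def test_strictly_increasing(self):
        p = np.linspace(-3, 3, 200)
        assert (np.diff(chemical_activation(p)) > 0).all()


class TestVectorField:
    def test_hand_arithmetic_at_origin(self, single_neuron):
        state = np.zeros(4)
        d = vector_field(state, HRParams(), SynapseParams(), single_neuron)
        assert d[0] == pytest.approx(3.25)   # pdot = I_ext
        assert d[1] == pytest.approx(1.0)    # qdot = c
        assert d[2] == pytest.approx(0.032)  # ndot = r*s*(0 - p0)
        assert d[3] == 0.0                   # phase fallback at p=q=0

    def test_decoupled_limit_equals_independent_neurons(self, ring18,
                                                        single_neuron):
        rng = np.random.default_rng(0)
        state = rng.normal(size=4 * 18)
        d = vector_field(state, HRParams(), SynapseParams(g_n=0, g_l=0), ring18)
        for i in range(18):
            s1 = state[i::18]
            d1 = vector_field(s1, HRParams(), SynapseParams(), single_neuron)
            assert d[i::18] == pytest.approx(d1)

    def test_equal_potentials_kill_electrical_term(self, ring18):
        # Laplacian rows sum to zero, so uniform p gives no diffusive current
        state = np.concatenate([np.full(18, 0.7), np.zeros(3 * 18)])
        d0 = vector_field(state, HRParams(), SynapseParams(g_l=0.0), ring18)
        d5 = vector_field(state, HRParams(), SynapseParams(g_l=5.0), ring18)
        assert d0 == pytest.approx(d5)

    def test_wrong_state_size_rejected(self, ring18):
        with pytest.raises(ValueError, match="length 72"):
            vector_field(np.zeros(10), HRParams(), SynapseParams(), ring18)


class TestInitialState:
    def test_deterministic_under_seed(self, ring18):
        s1 = initial_state(ring18, np.random.default_rng(5))
        s2 = initial_state(ring18, np.random.default_rng(5))
        assert np.array_equal(s1, s2)

    def test_jitter_distribution(self, single_neuron):
        rng = np.random.default_rng(0)
        draws = np.array([initial_state(single_neuron, rng)[0]
                          for _ in range(10_000)]) - (-1.30784489)
        assert draws.min() >= 0.0 and draws.max() <= 0.5
        assert draws.mean() == pytest.approx(0.25, abs=0.01)

    def test_shared_jitter_across_coordinates(self, ring18):
        s = initial_state(ring18, np.random.default_rng(1))
        N = ring18.n_neurons
        eta_p = s[:N] - (-1.30784489)
        eta_q = s[N:2 * N] - (-7.32183132)
        eta_n = s[2 * N:3 * N] - 3.35299859
        assert eta_p == pytest.approx(eta_q)
        assert eta_p == pytest.approx(eta_n)
        assert (s[3 * N:] == 0).all()


class TestSimulate:
    def test_single_neuron_membrane_potential_bounded(self, single_neuron):
        cfg = SimConfig(t_f=1000.0, seed=0)
        traj = simulate(single_neuron, cfg=cfg)
        post = traj.post_transient()
        assert np.abs(post.p).max() < 2.0

    def test_excitatory_sign_condition(self, ring18):
        # (p - V_syn) < 0 post-transient keeps chemical coupling excitatory
        cfg = SimConfig(t_f=600.0, seed=2)
        traj = simulate(ring18, syn=SynapseParams(g_n=0.5, g_l=0.5), cfg=cfg)
        assert (traj.post_transient().p < SynapseParams().V_syn).all()

    def test_deterministic_under_seed(self, ring18):
        cfg = SimConfig(t_f=400.0, seed=9)
        t1 = simulate(ring18, cfg=cfg)
        t2 = simulate(ring18, cfg=cfg)
        assert np.array_equal(t1.p, t2.p)
        assert np.array_equal(t1.phi, t2.phi)

    def test_all_values_finite(self, ring18):
        cfg = SimConfig(t_f=400.0, seed=3)
        traj = simulate(ring18, syn=SynapseParams(g_n=1.0, g_l=1.0), cfg=cfg)
        for arr in (traj.p, traj.q, traj.n_slow, traj.phi):
            assert np.isfinite(arr).all()

    def test_first_order_convergence(self, single_neuron):
        # step-halving: global error of Euler shrinks ~linearly in dt
        state0 = initial_state(single_neuron, np.random.default_rng(4))
        def run(dt):
            cfg = SimConfig(dt=dt, t_f=5.0, t_t=1.0, record_stride=1)
            return simulate(single_neuron, cfg=cfg, state0=state0)
        ref = run(0.0003125)
        errs = []
        for dt in (0.01, 0.005, 0.0025):
            traj = run(dt)
            stride = int(round(dt / 0.0003125))
            errs.append(np.abs(traj.p[:, 0] - ref.p[::stride, 0][:len(traj.p)]).max())
        # halving dt should roughly halve the error
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.5)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.5)

    def test_overflow_aborts_with_diagnostic(self, single_neuron):
        cfg = SimConfig(dt=1.0, t_f=50.0, t_t=1.0, seed=0)
        with pytest.raises(FloatingPointError, match="neuron 0"):
            simulate(single_neuron, cfg=cfg)

    def test_transient_flagging(self, single_neuron):
        cfg = SimConfig(t_f=400.0, t_t=300.0, seed=0)
        traj = simulate(single_neuron, cfg=cfg)
        assert traj.is_transient.sum() == (traj.times < 300.0).sum()
        assert (traj.post_transient().times >= 300.0).all()


class TestCouplingDrivesSynchrony:
    def test_strong_electrical_coupling_raises_order_parameter(self, ws12):
        rhos = {}
        for g_l in (0.01, 2.0):
            cfg = SimConfig(t_f=600.0, seed=1)
            traj = simulate(ws12, syn=SynapseParams(g_l=g_l), cfg=cfg)
            _, rhos[g_l], _ = order_parameter(traj.post_transient().phi)
        assert rhos[2.0] > rhos[0.01]


class TestConfigValidation:
    def test_transient_must_precede_final_time(self):
        with pytest.raises(ValueError):
            SimConfig(t_f=100.0, t_t=200.0)

    def test_positive_dt_required(self):
        with pytest.raises(ValueError):
            SimConfig(dt=0.0)
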