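"""Stochastic LIF update rule, synaptic plasticity and the simulator."""

import numpy as np
import pytest

import socnet
from socnet.dynamics import (LIFParams, NetworkState, PlasticityParams,
                             firing_probability, plasticity_update,
                             run_simulation, step)

from conftest import make_chain_net


class TestFiringProbability:
    def test_at_threshold_uses_spontaneous_branch(self):
        """V - theta = 0 is not strictly above threshold."""
        p = firing_probability(0.0, LIFParams(p_spont=1e-4))
        assert p == pytest.approx(1e-4)

    def test_unit_gain_argument_gives_half(self):
        """Gamma*(V-theta) = 1 puts the saturating gain at 1/2."""
        p = firing_probability(1.25, LIFParams(Gamma=0.8))
        assert p == pytest.approx(0.5)

    def test_saturates_toward_one(self):
        p = firing_probability(1e6, LIFParams(Gamma=0.8))
        assert 1 - p < 1e-5

    def test_monotone_and_bounded(self):
        v = np.linspace(0, 100, 2001)
        p = firing_probability(v, LIFParams())
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p < 1))


class TestPlasticityUpdate:
    def test_recovery_only(self):
        assert plasticity_update(1.0, 0, PlasticityParams(tau=500, u=0.1)) \
            == pytest.approx(1.002)

    def test_recovery_and_depression(self):
        assert plasticity_update(2.0, 1, PlasticityParams(tau=500, u=0.1)) \
            == pytest.approx(1.802)

    def test_stationary_balance_single_edge(self):
        """Bernoulli(rho) presynaptic spikes: long-run mean W = 1/(tau*u*rho)."""
        rng = np.random.default_rng(1)
        tau, u, rho = 500.0, 0.1, 0.01
        params = PlasticityParams(tau=tau, u=u)
        w, ws = 2.0, []
        for _ in range(400_000):
            w = plasticity_update(w, int(rng.random() < rho), params)
            ws.append(w)
        mean_w = np.mean(ws[50_000:])
        assert mean_w == pytest.approx(1.0 / (tau * u * rho), rel=0.10)


class TestStep:
    def test_quiescent_state_is_absorbing(self, small_er_net):
        lif = LIFParams(p_spont=0.0)
        st = NetworkState(V=np.zeros(small_er_net.N),
                          X=np.zeros(small_er_net.N, dtype=np.int8),
                          weights=small_er_net.weights.copy())
        rng = np.random.default_rng(0)
        for _ in range(10):
            st = step(st, small_er_net, lif, PlasticityParams(), rng)
            assert st.X.sum() == 0
            assert np.all(st.V == 0)

    def test_input_average_over_presynaptic_spikes(self):
        """Two presynaptic spikes of strength 1.5 into k=2 target: V = 1.5."""
        net = make_chain_net([(0, 2, 1.5), (1, 2, 1.5)])
        lif = LIFParams(p_spont=0.0)
        st = NetworkState(V=np.array([10.0, 10.0, 0.0]),
                          X=np.zeros(3, dtype=np.int8),
                          weights=net.weights.copy())
        rng = np.random.default_rng(0)  # P(fire)=~1 for V=10, Gamma=0.8
        st = step(st, net, lif, PlasticityParams(enabled=False), rng)
        assert st.X[0] == 1 and st.X[1] == 1
        assert st.V[2] == pytest.approx(0.5 * (1.5 + 1.5))

    def test_fired_neuron_resets_to_zero(self):
        net = make_chain_net([(0, 1, 3.0)])
        st = NetworkState(V=np.array([50.0, 50.0]),
                          X=np.zeros(2, dtype=np.int8),
                          weights=net.weights.copy())
        st = step(st, net, LIFParams(), PlasticityParams(),
                  np.random.default_rng(0))
        assert st.X[1] == 1
        assert st.V[1] == 0.0  # reset wins over any input


class TestRunSimulation:
    def test_quiescent_run(self, small_er_net):
        tr = run_simulation(small_er_net, LIFParams(p_spont=0.0),
                            PlasticityParams(enabled=False), 10, w_init=1.0,
                            seed=0)
        assert tr.probe_counts.sum() == 0
        assert np.allclose(tr.mean_W, 1.0)

    def test_mean_w_grows_linearly_without_spikes(self, small_er_net):
        """With no spikes ever, W[t] = W_init + t/tau exactly."""
        tau = 250.0
        tr = run_simulation(small_er_net, LIFParams(p_spont=0.0),
                            PlasticityParams(tau=tau, u=0.3), 50, w_init=2.0,
                            seed=0)
        assert np.allclose(tr.mean_W, 2.0 + tr.t / tau)

    def test_matches_reference_step_bitwise(self, small_er_net):
        """The compiled path and the reference path share the RNG stream."""
        lif = LIFParams(p_spont=0.005)
        plast = PlasticityParams(tau=100, u=0.2)
        T = 200
        tr = run_simulation(small_er_net, lif, plast, T, w_init=1.5, seed=17,
                            record_raster=True)
        rng = np.random.default_rng([17, 0])
        st = NetworkState(V=np.zeros(small_er_net.N),
                          X=np.zeros(small_er_net.N, dtype=np.int8),
                          weights=np.full(small_er_net.n_edges, 1.5))
        counts, events = [], []
        for t in range(1, T + 1):
            st = step(st, small_er_net, lif, plast, rng)
            counts.append(int(st.X.sum()))
            events.extend((t, i) for i in np.nonzero(st.X)[0])
        assert np.array_equal(tr.probe_counts, counts)
        assert np.array_equal(np.column_stack([tr.spike_t, tr.spike_i]),
                              np.array(events))

    def test_determinism_and_seed_sensitivity(self, small_er_net):
        args = (small_er_net, LIFParams(), PlasticityParams(tau=200, u=0.2))
        a = run_simulation(*args, 500, w_init=1.5, seed=3, record_raster=True)
        b = run_simulation(*args, 500, w_init=1.5, seed=3, record_raster=True)
        c = run_simulation(*args, 500, w_init=1.5, seed=4, record_raster=True)
        assert np.array_equal(a.spike_t, b.spike_t)
        assert np.array_equal(a.spike_i, b.spike_i)
        assert not np.array_equal(a.probe_counts, c.probe_counts)

    def test_spontaneous_rate(self, small_er_net):
        """With W=0 fixed, the spike count is Binomial(N, p_spont) per step."""
        p = 0.002
        T = 20_000
        tr = run_simulation(small_er_net, LIFParams(p_spont=p),
                            PlasticityParams(enabled=False), T, w_init=0.0,
                            seed=5)
        n = small_er_net.N
        expected = n * p
        se = np.sqrt(n * p * (1 - p) / T)
        assert abs(tr.probe_counts.mean() - expected) < 3 * se

    def test_recovery_term_conservation(self, small_er_net):
        """Summed strength gain from recovery alone is n_edges / tau per step."""
        tau = 125.0
        net = small_er_net
        before = np.full(net.n_edges, 1.0)
        after = plasticity_update(before, np.zeros(net.n_edges),
                                  PlasticityParams(tau=tau, u=0.5))
        assert (after - before).sum() == pytest.approx(net.n_edges / tau)

    def test_v_nonnegative_throughout(self, small_er_net):
        lif = LIFParams(mu=0.7, I_ext=0.01, p_spont=0.01)
        st = NetworkState(V=np.zeros(small_er_net.N),
                          X=np.zeros(small_er_net.N, dtype=np.int8),
                          weights=small_er_net.weights.copy())
        rng = np.random.default_rng(2)
        for _ in range(50):
            st = step(st, small_er_net, lif, PlasticityParams(tau=50, u=0.5),
                      rng)
            assert np.all(st.V >= 0)
            assert np.all(st.weights > 0)

    def test_probe_subset_counts_only_probed_neurons(self, small_er_net):
        tr_all = run_simulation(small_er_net, LIFParams(p_spont=0.01),
                                PlasticityParams(enabled=False), 300,
                                w_init=0.0, seed=8)
        tr_sub = run_simulation(small_er_net, LIFParams(p_spont=0.01),
                                PlasticityParams(enabled=False), 300,
                                w_init=0.0, seed=8, probe=50)
        assert tr_sub.probe_counts.sum() < tr_all.probe_counts.sum()
        assert np.all(tr_sub.probe_counts <= tr_all.probe_counts)

    def test_trace_csv_round_trip(self, small_er_net, tmp_path):
        tr = run_simulation(small_er_net, LIFParams(p_spont=0.01),
                            PlasticityParams(tau=100, u=0.1), 50,
                            w_init=1.0, seed=1)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "probe_spikes", "mean_W"]
        assert np.array_equal(df["probe_spikes"].to_numpy(), tr.probe_counts)
        assert np.allclose(df["mean_W"].to_numpy(), tr.mean_W)
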