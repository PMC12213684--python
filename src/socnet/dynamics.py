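"""Discrete-time stochastic leaky integrate-and-fire dynamics with
activity-dependent synapses.

The membrane potential of neuron i evolves synchronously as

    V_i[t+1] = mu * V_i[t] + I_ext + (1 / k_i) * sum_j W_ij X_j[t]

where the sum runs over presynaptic neighbours j, k_i is the in-degree, and a
neuron that fired at t is reset to V_i[t+1] = 0.  Firing is stochastic: above
threshold the probability is the saturating gain function
Gamma (V - theta) / (1 + Gamma (V - theta)); at or below threshold a small
spontaneous probability p_spont applies.

Each synapse recovers by a fixed increment 1/tau per step and is depressed by
a fraction u whenever its presynaptic neuron fires:

    W_ij[t+1] = W_ij[t] + 1/tau - u * W_ij[t] * X_j[t]

The interplay of slow recovery and spike-triggered depression drives the
network-mean synaptic strength toward the critical value without external
tuning (self-organized criticality).

Two update paths are provided: :func:`step`, a transparent reference
implementation used for unit-level checks, and :func:`run_simulation`, a
numba-compiled loop suitable for 1e5-step runs on thousands of neurons.  Both
consume random draws in the same order (one uniform per neuron per step, in
neuron order), so given the same seed they produce bitwise identical spike
rasters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numba import njit

from .networks import DirectedNetwork


@dataclass(frozen=True)
class LIFParams:
    """Single-neuron parameters of the stochastic LIF model.

    Defaults are the study conditions: zero leak and external input, gain
    0.8, threshold 0 and spontaneous firing probability 1e-4 per step.
    """

    mu: float = 0.0
    I_ext: float = 0.0
    Gamma: float = 0.8
    theta: float = 0.0
    p_spont: float = 1e-4

    def __post_init__(self) -> None:
        if self.Gamma <= 0:
            raise ValueError("Gamma must be positive")
        if not 0.0 <= self.p_spont <= 1.0:
            raise ValueError("p_spont must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")


@dataclass(frozen=True)
class PlasticityParams:
    """Synaptic recovery/depression rule parameters.

    tau is the recovery time constant in steps (strength grows by 1/tau per
    step); u in (0, 1) is the fraction of strength lost per presynaptic
    spike.  With ``enabled=False`` the weights stay fixed (used for the
    critical-point scan).
    """

    tau: float = 500.0
    u: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled:
            if self.tau <= 0:
                raise ValueError("tau must be positive")
            if not 0.0 < self.u < 1.0:
                raise ValueError("u must lie in (0, 1)")


@dataclass
class NetworkState:
    """Full dynamical state at one time step (reference path)."""

    V: np.ndarray
    X: np.ndarray
    weights: np.ndarray
    t: int = 0


@dataclass
class SimTrace:
    """Recorded output of a simulation run.

    Per-step series are indexed by time t = 1 .. T: ``probe_counts[t-1]`` is
    the number of probe-set spikes sampled during step t, and
    ``mean_W[t-1]`` is the network-mean synaptic strength W[t] after that
    step's plasticity update (edges whose presynaptic neuron has in-degree
    0 or 1 are excluded; see :func:`socnet.metrics.network_mean_weight`).
    """

    probe_counts: np.ndarray
    mean_W: np.ndarray
    spike_t: Optional[np.ndarray] = None
    spike_i: Optional[np.ndarray] = None
    seed: Optional[int] = None

    @property
    def T(self) -> int:
        return len(self.probe_counts)

    @property
    def t(self) -> np.ndarray:
        return np.arange(1, self.T + 1)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t,probe_spikes,mean_W\n")
            for t, c, w in zip(self.t, self.probe_counts, self.mean_W):
                fh.write(f"{t},{c},{w:.12g}\n")

    def raster_to_csv(self, path) -> None:
        if self.spike_t is None:
            raise ValueError("raster was not recorded")
        with open(path, "w") as fh:
            fh.write("t,neuron_id\n")
            for t, i in zip(self.spike_t, self.spike_i):
                fh.write(f"{t},{i}\n")


def firing_probability(V: Union[float, np.ndarray], params: LIFParams):
    """Spike probability given the membrane potential.

    Strictly above threshold: Gamma*(V-theta) / (1 + Gamma*(V-theta)),
    saturating toward 1; at or below threshold: p_spont.  The boundary
    V == theta takes the spontaneous branch.
    """
    v = np.asarray(V, dtype=float)
    d = v - params.theta
    g = params.Gamma * d
    with np.errstate(invalid="ignore"):
        p = np.where(d > 0, g / (1.0 + g), params.p_spont)
    if np.ndim(V) == 0:
        return float(p)
    return p


def plasticity_update(W, X_pre, params: PlasticityParams):
    """One synaptic update: W + 1/tau - u * W * X_pre (X_pre in {0, 1})."""
    return W + 1.0 / params.tau - params.u * np.asarray(W) * np.asarray(X_pre)


def step(state: NetworkState, net: DirectedNetwork, lif: LIFParams,
         plast: PlasticityParams, rng: np.random.Generator) -> NetworkState:
    """Reference synchronous update (one uniform draw per neuron, in order).

    Order of operations within a step: sample spikes from the current
    potentials, propagate them, reset fired neurons, then apply the synaptic
    rule using the just-sampled spikes.
    """
    N = net.N
    p = firing_probability(state.V, lif)
    X = (rng.random(N) < p).astype(np.int8)
    acc = np.zeros(N)
    fired_edges = X[net.src] == 1
    np.add.at(acc, net.tgt[fired_edges], state.weights[fired_edges])
    k = net.in_degree
    inp = np.divide(acc, k, out=np.zeros(N), where=k > 0)
    V_new = lif.mu * state.V + lif.I_ext + inp
    V_new[X == 1] = 0.0
    if plast.enabled:
        W_new = plasticity_update(state.weights, X[net.src], plast)
    else:
        W_new = state.weights.copy()
    return NetworkState(V=V_new, X=X, weights=W_new, t=state.t + 1)


@njit(cache=True)
def _sim_chunk(V, W, src, tgt, out_ptr, out_eid, k_in, qual, n_qual,
               mu, I_ext, Gamma, theta, p_spont,
               inv_tau, u, plast_on,
               probe, uniforms, X_buf, probe_counts, mean_w, off):
    steps, N = uniforms.shape
    E = src.shape[0]
    acc = np.zeros(N)
    for t in range(steps):
        cnt = 0
        for i in range(N):
            d = V[i] - theta
            if d > 0.0:
                g = Gamma * d
                p = g / (1.0 + g)
            else:
                p = p_spont
            if uniforms[t, i] < p:
                X_buf[t, i] = 1
                if probe[i]:
                    cnt += 1
            else:
                X_buf[t, i] = 0
        probe_counts[off + t] = cnt
        for i in range(N):
            acc[i] = 0.0
        for i in range(N):
            if X_buf[t, i] == 1:
                for ptr in range(out_ptr[i], out_ptr[i + 1]):
                    e = out_eid[ptr]
                    acc[tgt[e]] += W[e]
        for i in range(N):
            if X_buf[t, i] == 1:
                V[i] = 0.0
            else:
                inp = acc[i] / k_in[i] if k_in[i] > 0 else 0.0
                V[i] = mu * V[i] + I_ext + inp
        if plast_on:
            sw = 0.0
            for e in range(E):
                w = W[e] + inv_tau - u * W[e] * X_buf[t, src[e]]
                W[e] = w
                if qual[e]:
                    sw += w
            if n_qual > 0:
                mean_w[off + t] = sw / n_qual
            else:
                mean_w[off + t] = np.nan


def run_simulation(net: DirectedNetwork, lif: LIFParams,
                   plast: PlasticityParams, T: int,
                   w_init: Optional[float] = None,
                   probe: Union[str, int, np.ndarray] = "all",
                   seed: int = 0,
                   record_raster: bool = False,
                   chunk: int = 2000) -> SimTrace:
    """Run the network for T steps from a quiescent start.

    All membrane potentials start at 0; all edge strengths start at
    ``w_init`` (or the network's stored weights when ``w_init`` is None).
    ``probe`` selects the subset of neurons whose spikes are counted per
    step: ``"all"``, an explicit array of node ids, or an integer size of a
    uniformly sampled subset.  Deterministic given ``seed``.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    N, E = net.N, net.n_edges
    W = (np.full(E, float(w_init)) if w_init is not None
         else net.weights.astype(float).copy())
    V = np.zeros(N)

    if isinstance(probe, str):
        if probe != "all":
            raise ValueError("probe must be 'all', an int or an array")
        probe_mask = np.ones(N, dtype=np.bool_)
    elif isinstance(probe, (int, np.integer)):
        sel = np.random.default_rng([seed, 1]).choice(N, size=min(int(probe), N),
                                                      replace=False)
        probe_mask = np.zeros(N, dtype=np.bool_)
        probe_mask[sel] = True
    else:
        probe_mask = np.zeros(N, dtype=np.bool_)
        probe_mask[np.asarray(probe, dtype=int)] = True

    order = np.argsort(net.src, kind="stable").astype(np.int64)
    out_ptr = np.zeros(N + 1, dtype=np.int64)
    out_ptr[1:] = np.cumsum(np.bincount(net.src, minlength=N))
    # network-mean exclusion rule: edges whose presynaptic neuron has
    # in-degree 0 or 1 fire (hence depress) so rarely that their strength
    # grows almost unopposed; they are left out of the recorded mean
    qual = net.in_degree[net.src] >= 2
    n_qual = int(qual.sum())

    probe_counts = np.zeros(T, dtype=np.int64)
    mean_w = np.full(T, np.nan)
    if not plast.enabled:
        const_mean = float(W[qual].mean()) if n_qual else np.nan
        mean_w[:] = const_mean

    rng = np.random.default_rng([seed, 0])
    spike_ts: list[np.ndarray] = []
    spike_is: list[np.ndarray] = []
    k_in = net.in_degree.astype(np.int64)
    off = 0
    while off < T:
        cs = min(chunk, T - off)
        uniforms = rng.random((cs, N))
        X_buf = np.empty((cs, N), dtype=np.uint8)
        _sim_chunk(V, W, net.src, net.tgt, out_ptr, order, k_in,
                   qual, n_qual,
                   lif.mu, lif.I_ext, lif.Gamma, lif.theta, lif.p_spont,
                   1.0 / plast.tau if plast.enabled else 0.0,
                   plast.u if plast.enabled else 0.0,
                   plast.enabled,
                   probe_mask, uniforms, X_buf, probe_counts, mean_w, off)
        if record_raster:
            tt, ii = np.nonzero(X_buf)
            spike_ts.append(tt + off + 1)
            spike_is.append(ii)
        off += cs

    trace = SimTrace(probe_counts=probe_counts, mean_W=mean_w, seed=seed)
    if record_raster:
        trace.spike_t = (np.concatenate(spike_ts) if spike_ts
                         else np.empty(0, dtype=np.int64))
        trace.spike_i = (np.concatenate(spike_is) if spike_is
                         else np.empty(0, dtype=np.int64))
    net.weights = W  # final strengths, useful for inspection
    return trace
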