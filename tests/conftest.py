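import numpy as np
import pytest

import socnet


@pytest.fixture(scope="session")
def small_er_net():
    """A small random network shared by dynamics-level tests."""
    spec = socnet.NetworkSpec(kind="random", N=200, avg_degree=8, seed=42)
    return socnet.build_network(spec)


@pytest.fixture(scope="session")
def er2000_net():
    """Reduced-scale random network matching the experiment defaults."""
    spec = socnet.NetworkSpec(kind="random", N=2000, avg_degree=8, seed=0)
    return socnet.build_network(spec)


@pytest.fixture(scope="session")
def er2000_wc(er2000_net):
    """Susceptibility-estimated critical strength for the shared network.

    Computed once per session; several acceptance-level checks reuse it.
    """
    est = socnet.estimate_critical_point(
        er2000_net, socnet.LIFParams(), W_min=1.5, W_max=2.3, W_step=0.02,
        steps_per_W=50_000, seed=11, probe=400)
    return est


@pytest.fixture(scope="session")
def me_tables_tau200(er2000_wc):
    """ME replicate tables for the regular and random topologies at
    tau=200, u=0.5 (10 runs each, against each topology's own W_c)."""
    cfg = socnet.ExperimentConfig(
        N=2000, T=30_000, master_seed=5,
        wc_w_min=1.5, wc_w_max=3.2, wc_w_step=0.02, wc_steps_per_W=50_000)
    wc_regular = socnet.estimate_wc("regular", cfg)
    regular = socnet.run_me_replicates("regular", cfg, tau=200, u=0.5,
                                       n_runs=10, W_c=wc_regular)
    random_ = socnet.run_me_replicates("random", cfg, tau=200, u=0.5,
                                       n_runs=10, W_c=er2000_wc.W_c)
    return {"regular": regular, "random": random_}


def make_chain_net(weights_spec):
    """Build a tiny explicit network from (src, tgt, w) triples."""
    src = np.array([e[0] for e in weights_spec])
    tgt = np.array([e[1] for e in weights_spec])
    w = np.array([e[2] for e in weights_spec], dtype=float)
    n = int(max(src.max(), tgt.max())) + 1
    return socnet.DirectedNetwork(N=n, src=src, tgt=tgt, weights=w)
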