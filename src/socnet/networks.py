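"""Directed network construction for the five benchmark topologies.

All generators produce networks with a matched edge budget of
``N * avg_degree / 2`` directed edges: an undirected skeleton is built first
(ring lattice, Watts-Strogatz, Barabasi-Albert, stochastic-block or
Erdos-Renyi), then every undirected edge is assigned one direction uniformly
at random.  Because each skeleton edge contributes exactly one directed edge,
reciprocal pairs (i->j together with j->i) are impossible by construction —
the model excludes immediate recurrent loops so that cascade causality stays
unidirectional.

``avg_degree`` always refers to the mean *total* degree (in plus out), so a
network with N = 100 and avg_degree = 8 has 400 directed edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .errors import InfeasibleNetworkError

NETWORK_KINDS = ("regular", "small_world", "scale_free", "modular", "random")

#: Fraction of modular-network edges placed within blocks (the remainder
#: connects distinct blocks).  The block model's connection probabilities are
#: derived from this fraction and the edge budget.
MODULAR_WITHIN_FRACTION = 0.9


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one of the five named random-graph constructions.

    Parameters
    ----------
    kind:
        One of ``regular``, ``small_world``, ``scale_free``, ``modular``,
        ``random``.
    N:
        Number of nodes (neurons).
    avg_degree:
        Mean total degree (in + out); must be even so the ring-lattice
        skeleton is well defined and the edge budget is integral.
    p_rewire:
        Watts-Strogatz rewiring probability (``small_world`` only).
    B:
        Number of blocks (``modular`` only).
    p_in, p_out:
        Optional within/between-block connection probabilities for the
        block model.  When omitted they are derived so that roughly 90% of
        the edge budget falls within blocks.
    seed:
        Seed for all randomness in the construction (skeleton sampling,
        budget trimming/augmentation and edge orientation).
    """

    kind: str
    N: int
    avg_degree: int = 8
    p_rewire: float = 0.1
    B: int = 10
    p_in: Optional[float] = None
    p_out: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise InfeasibleNetworkError(
                f"unknown network kind {self.kind!r}; expected one of {NETWORK_KINDS}"
            )
        if self.N < 2:
            raise InfeasibleNetworkError("N must be at least 2")
        if self.avg_degree < 2 or self.avg_degree % 2 != 0:
            raise InfeasibleNetworkError("avg_degree must be even and >= 2")
        if self.avg_degree >= self.N:
            raise InfeasibleNetworkError("avg_degree must be smaller than N")
        if not 0.0 <= self.p_rewire <= 1.0:
            raise InfeasibleNetworkError("p_rewire must lie in [0, 1]")
        if self.kind == "modular" and self.B < 2:
            raise InfeasibleNetworkError("modular networks need B >= 2 blocks")

    @property
    def n_edges(self) -> int:
        """Directed edge budget shared by all five kinds."""
        return self.N * self.avg_degree // 2


@dataclass
class DirectedNetwork:
    """A directed network with per-edge synaptic strengths.

    Edges are stored as parallel arrays ``src`` / ``tgt`` (0-based node ids);
    ``weights[e]`` is the synaptic strength W_ij of the edge from presynaptic
    neuron ``src[e]`` = j to postsynaptic neuron ``tgt[e]`` = i.
    """

    N: int
    src: np.ndarray
    tgt: np.ndarray
    weights: np.ndarray
    kind: str = "custom"
    seed: Optional[int] = None
    in_degree: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.int64)
        self.tgt = np.asarray(self.tgt, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (len(self.src) == len(self.tgt) == len(self.weights)):
            raise InfeasibleNetworkError("src, tgt and weights must be aligned")
        if np.any(self.src == self.tgt):
            raise InfeasibleNetworkError("self-loops are not allowed")
        self.in_degree = np.bincount(self.tgt, minlength=self.N)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.src.tolist(), self.tgt.tolist()))

    def reciprocal_pair_count(self) -> int:
        """Number of edge pairs (j->i, i->j) present simultaneously."""
        forward = set(zip(self.src.tolist(), self.tgt.tolist()))
        return sum(1 for j, i in forward if (i, j) in forward)

    def duplicate_edge_count(self) -> int:
        return self.n_edges - len(set(zip(self.src.tolist(), self.tgt.tolist())))

    def set_uniform_weights(self, w: float) -> None:
        self.weights = np.full(self.n_edges, float(w))

    def to_undirected_graph(self) -> nx.Graph:
        """Undirected skeleton (directions dropped)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(zip(self.src.tolist(), self.tgt.tolist()))
        return g

    # -- plain-text edge-list round trip ---------------------------------
    def to_tsv(self, path) -> None:
        """Write ``source<TAB>target<TAB>weight`` rows with a header line."""
        with open(path, "w") as fh:
            fh.write(f"# N={self.N} kind={self.kind} seed={self.seed}\n")
            for j, i, w in zip(self.src, self.tgt, self.weights):
                fh.write(f"{j}\t{i}\t{w:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "DirectedNetwork":
        meta = {}
        src, tgt, wts = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                    continue
                j, i, w = line.split("\t")
                src.append(int(j))
                tgt.append(int(i))
                wts.append(float(w))
        n = int(meta.get("N", max(max(src, default=0), max(tgt, default=0)) + 1))
        seed = meta.get("seed")
        seed = None if seed in (None, "None") else int(seed)
        return cls(N=n, src=np.array(src), tgt=np.array(tgt),
                   weights=np.array(wts), kind=meta.get("kind", "custom"),
                   seed=seed)


def _augment_to_budget(g: nx.Graph, budget: int, rng: np.random.Generator) -> None:
    """Add uniformly random absent edges until ``g`` has ``budget`` edges."""
    n = g.number_of_nodes()
    max_edges = n * (n - 1) // 2
    if budget > max_edges:
        raise InfeasibleNetworkError(
            f"edge budget {budget} exceeds the maximum {max_edges} for N={n}"
        )
    attempts = 0
    while g.number_of_edges() < budget:
        a = int(rng.integers(n))
        b = int(rng.integers(n))
        if a != b and not g.has_edge(a, b):
            g.add_edge(a, b)
        attempts += 1
        if attempts > 1000 * budget:  # pragma: no cover - resampling guard
            raise InfeasibleNetworkError("could not reach edge budget by resampling")


def _trim_to_budget(g: nx.Graph, budget: int, rng: np.random.Generator) -> None:
    """Remove uniformly random edges until ``g`` has ``budget`` edges."""
    excess = g.number_of_edges() - budget
    if excess <= 0:
        return
    edges = list(g.edges())
    idx = rng.choice(len(edges), size=excess, replace=False)
    g.remove_edges_from(edges[i] for i in idx)


def _modular_skeleton(spec: NetworkSpec, rng: np.random.Generator) -> nx.Graph:
    budget = spec.n_edges
    base = spec.N // spec.B
    sizes = [base + (1 if b < spec.N % spec.B else 0) for b in range(spec.B)]
    within_pairs = sum(s * (s - 1) // 2 for s in sizes)
    between_pairs = spec.N * (spec.N - 1) // 2 - within_pairs
    if spec.p_in is not None and spec.p_out is not None:
        p_in, p_out = spec.p_in, spec.p_out
    else:
        p_in = min(1.0, MODULAR_WITHIN_FRACTION * budget / max(within_pairs, 1))
        p_out = min(1.0, (1 - MODULAR_WITHIN_FRACTION) * budget / max(between_pairs, 1))
    probs = [[p_in if a == b else p_out for b in range(spec.B)] for a in range(spec.B)]
    g = nx.stochastic_block_model(sizes, probs, seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # drop block metadata / potential multiedges
    _trim_to_budget(g, budget, rng)
    _augment_to_budget(g, budget, rng)
    return g


def _skeleton(spec: NetworkSpec, rng: np.random.Generator) -> nx.Graph:
    budget = spec.n_edges
    nx_seed = int(rng.integers(2**31))
    if spec.kind == "regular":
        return nx.watts_strogatz_graph(spec.N, spec.avg_degree, 0.0, seed=nx_seed)
    if spec.kind == "small_world":
        return nx.watts_strogatz_graph(spec.N, spec.avg_degree, spec.p_rewire,
                                       seed=nx_seed)
    if spec.kind == "scale_free":
        m = spec.avg_degree // 2
        g = nx.barabasi_albert_graph(spec.N, m, seed=nx_seed)
        # preferential attachment yields m*(N-m) = budget - m^2 edges; top up
        # with uniformly random extra edges to hit the shared budget exactly
        _augment_to_budget(g, budget, rng)
        return g
    if spec.kind == "modular":
        return _modular_skeleton(spec, rng)
    if spec.kind == "random":
        return nx.gnm_random_graph(spec.N, budget, seed=nx_seed)
    raise InfeasibleNetworkError(f"unknown kind {spec.kind!r}")  # pragma: no cover


def build_network(spec: NetworkSpec, w_init: float = 1.0) -> DirectedNetwork:
    """Build a directed network from a :class:`NetworkSpec`.

    The undirected skeleton is sampled first, then every edge is oriented
    uniformly at random, which guarantees the absence of reciprocal pairs.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g = _skeleton(spec, rng)
    if g.number_of_edges() != spec.n_edges:
        raise InfeasibleNetworkError(
            f"skeleton has {g.number_of_edges()} edges, expected {spec.n_edges}"
        )
    und = np.array(sorted(g.edges()), dtype=np.int64)
    flip = rng.random(len(und)) < 0.5
    src = np.where(flip, und[:, 1], und[:, 0])
    tgt = np.where(flip, und[:, 0], und[:, 1])
    return DirectedNetwork(
        N=spec.N, src=src, tgt=tgt,
        weights=np.full(len(und), float(w_init)),
        kind=spec.kind, seed=spec.seed,
    )


def clustering_coefficient(net: DirectedNetwork) -> float:
    """Mean local clustering of the undirected skeleton.

    Edge directions are ignored; the value lies in [0, 1].  For a ring
    lattice with even degree k the closed form is 3(k-2) / (4(k-1)).
    """
    if net.N < 3:
        raise InfeasibleNetworkError("clustering needs at least 3 nodes")
    return float(nx.average_clustering(net.to_undirected_graph()))
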