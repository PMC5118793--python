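"""Evolving a Life-like rule on a network tessellation.

The network plays the role of the cellular-automaton lattice: every node is
a binary cell, its neighborhood is given by the adjacency matrix, and the
update replaces the usual alive-neighbor count with the neighborhood
density rho_i = (1/k_i) * sum_j A_ij s_j.  The synchronous evolution of all
nodes over t steps is recorded as a space-time diagram whose columns are
node time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .rules import LifeLikeRule, interval_index


class NetworkTessellation:
    """Simple undirected graph used as a CA lattice.

    Nodes are 0..N-1.  Internally the adjacency is a CSR matrix so the
    synchronous update is a single sparse mat-vec per step.
    """

    def __init__(self, n_nodes: int, edges) -> None:
        if n_nodes <= 0:
            raise ValueError("network needs at least one node")
        self.n_nodes = int(n_nodes)
        seen = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                continue  # self-loops carry no neighborhood information
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise ValueError(f"edge ({u}, {v}) outside 0..{n_nodes - 1}")
            seen.add((min(u, v), max(u, v)))
        self._edges = frozenset(seen)
        if seen:
            rows, cols = zip(*seen)
            data = np.ones(len(seen), dtype=np.float64)
            upper = sp.coo_matrix(
                (data, (rows, cols)), shape=(n_nodes, n_nodes)
            )
            self.adjacency = (upper + upper.T).tocsr()
        else:
            self.adjacency = sp.csr_matrix((n_nodes, n_nodes), dtype=np.float64)
        self.degrees = np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def edges(self) -> frozenset:
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def neighbors(self, node: int) -> np.ndarray:
        row = self.adjacency.getrow(node)
        return row.indices.copy()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, graph) -> "NetworkTessellation":
        # numeric-looking labels sort numerically ("2" before "10")
        def key(n):
            try:
                return (0, int(n))
            except (TypeError, ValueError):
                return (1, str(n))

        order = {n: i for i, n in enumerate(sorted(graph.nodes, key=key))}
        edges = ((order[u], order[v]) for u, v in graph.edges())
        return cls(graph.number_of_nodes(), edges)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NetworkTessellation(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class SpaceTimeDiagram:
    """Binary (t+1) x N matrix; row 0 is the initial configuration."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2:
            raise ValueError("space-time diagram must be 2-D")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("space-time diagram must be binary")
        self.matrix = m

    @property
    def n_steps(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[1]

    def node_series(self, node: int) -> np.ndarray:
        return self.matrix[:, node]

    def ordered_by_degree(self, net: NetworkTessellation) -> np.ndarray:
        """Columns sorted by ascending degree — visualization only.

        Feature extraction never uses this ordering; descriptors are
        permutation invariant.
        """
        order = np.argsort(net.degrees, kind="stable")
        return self.matrix[:, order]


def neighborhood_density(node: int, states, net: NetworkTessellation) -> float:
    """Fraction of node's neighbors that are alive; 0 for isolated nodes."""
    k = net.degrees[node]
    if k == 0:
        return 0.0
    nbrs = net.neighbors(node)
    s = np.asarray(states)
    return float(s[nbrs].sum()) / float(k)


def all_densities(states, net: NetworkTessellation) -> np.ndarray:
    """Vector of neighborhood densities for every node."""
    s = np.asarray(states, dtype=np.float64)
    alive = net.adjacency @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(net.degrees > 0, alive / np.maximum(net.degrees, 1), 0.0)
    return rho


def initial_state(net: NetworkTessellation, sigma: float, seed) -> np.ndarray:
    """Each node independently alive with probability sigma (seeded)."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(net.n_nodes) < sigma).astype(np.uint8)


def step(rule: LifeLikeRule, states, net: NetworkTessellation) -> np.ndarray:
    """One synchronous update of every node.

    A dead node turns alive iff its density falls in a birth interval; an
    alive node stays alive iff its density falls in a survival interval.
    """
    s = np.asarray(states, dtype=np.uint8)
    if s.shape != (net.n_nodes,):
        raise ValueError("state vector length must equal the node count")
    idx = interval_index(all_densities(s, net))
    born = rule.birth_table()[idx]
    survives = rule.survival_table()[idx]
    return np.where(s == 1, survives, born).astype(np.uint8)


def evolve(
    rule: LifeLikeRule,
    net: NetworkTessellation,
    t: int = 350,
    sigma: float = 0.5,
    seed=None,
    initial=None,
) -> SpaceTimeDiagram:
    """Run the automaton for t steps from a random (or given) initial state.

    Returns a diagram with t+1 rows; row 0 is the initial configuration.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if initial is None:
        s = initial_state(net, sigma, seed)
    else:
        s = np.asarray(initial, dtype=np.uint8)
        if s.shape != (net.n_nodes,):
            raise ValueError("initial state length must equal the node count")
    out = np.empty((t + 1, net.n_nodes), dtype=np.uint8)
    out[0] = s
    birth = rule.birth_table()
    survival = rule.survival_table()
    adj = net.adjacency
    deg = np.maximum(net.degrees, 1).astype(np.float64)
    has_nbrs = net.degrees > 0
    for k in range(t):
        alive = adj @ out[k].astype(np.float64)
        rho = np.where(has_nbrs, alive / deg, 0.0)
        idx = interval_index(rho)
        out[k + 1] = np.where(out[k] == 1, survival[idx], birth[idx])
    return SpaceTimeDiagram(out)
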