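"""Synthetic network generators and dataset builders.

Five models: Erdos-Renyi random graphs, Watts-Strogatz small-world rings,
Barabasi-Albert growth with attachment probability proportional to k**alpha
(alpha = 1 is the classic scale-free model), Dorogovtsev-Mendes edge-
selection growth, and geographical graphs with distance-decaying connection
probability.  Dataset builders produce the labeled benchmark collections
(4-model, rule-selection and 5-class scale-free datasets) with per-network
seeds derived deterministically from a master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .automaton import NetworkTessellation

#: Attachment exponents mixed into the 4-model "scalefree" class.
BA_ALPHAS = (0.5, 1.0, 1.5, 2.0)

#: Geographic decay rate, in units of inverse mean point spacing.
DEFAULT_LAMBDA = 1.0

_MODEL_IDS = {
    "random": 1,
    "small_world": 2,
    "scalefree": 3,
    "geographical": 4,
    "scalefree_ba": 5,
    "scalefree_dm": 6,
}


def generate_er(n_nodes: int, mean_degree: float, seed) -> NetworkTessellation:
    """Random graph: each pair connected independently with p = <k>/N."""
    if not 0 < mean_degree < n_nodes:
        raise ValueError("mean degree must lie in (0, N)")
    p = mean_degree / n_nodes
    g = nx.fast_gnp_random_graph(n_nodes, p, seed=_int_seed(seed))
    return NetworkTessellation(n_nodes, g.edges())


def generate_ws(
    n_nodes: int, mean_degree: int, rewire_p: float = 0.1, seed=None
) -> NetworkTessellation:
    """Small-world ring lattice with <k>/2 neighbors per side, rewired."""
    if mean_degree % 2 != 0:
        raise ValueError("small-world mean degree must be even")
    g = nx.watts_strogatz_graph(n_nodes, mean_degree, rewire_p, seed=_int_seed(seed))
    return NetworkTessellation(n_nodes, g.edges())


def generate_ba(
    n_nodes: int, mean_degree: int, alpha: float = 1.0, seed=None
) -> NetworkTessellation:
    """Scale-free growth: new nodes attach m = <k>/2 edges, P(i) ~ k_i**alpha.

    Starts from an (m+1)-clique; targets are sampled without replacement by
    weighted choice, so the construction covers nonlinear attachment
    (alpha != 1) as well as the classic linear model.
    """
    m = mean_degree // 2
    if m < 1:
        raise ValueError("mean degree must be >= 2")
    if n_nodes <= m + 1:
        raise ValueError("N must exceed the seed clique size m+1")
    rng = np.random.default_rng(seed)
    degrees = np.zeros(n_nodes, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((i, j))
    degrees[: m + 1] = m
    for new in range(m + 1, n_nodes):
        w = degrees[:new].astype(float) ** alpha
        targets = rng.choice(new, size=m, replace=False, p=w / w.sum())
        for tgt in targets:
            edges.append((int(tgt), new))
            degrees[tgt] += 1
        degrees[new] = m
    return NetworkTessellation(n_nodes, edges)


def generate_dm(n_nodes: int, mean_degree: int = 8, seed=None) -> NetworkTessellation:
    """Dorogovtsev-Mendes growth: new nodes attach to both endpoints of
    randomly chosen existing edges.

    Each step selects <k>/4 distinct edges and links the new node to every
    distinct endpoint, closing a triangle per selection; the attachment is
    implicitly preferential because high-degree nodes sit on more edges.
    """
    per_step = round(mean_degree / 4)
    if per_step < 1:
        per_step = 1
    if mean_degree % 4 != 0:
        warnings.warn(
            f"mean degree {mean_degree} not divisible by 4; "
            f"attaching to {per_step} edge(s) per step (<k> -> {4 * per_step})"
        )
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = [(0, 1), (0, 2), (1, 2)]
    for new in range(3, n_nodes):
        n_sel = min(per_step, len(edges))
        sel = rng.choice(len(edges), size=n_sel, replace=False)
        targets = {end for e in sel for end in edges[e]}
        for tgt in targets:
            edges.append((tgt, new))
    return NetworkTessellation(n_nodes, edges)


def generate_geographical(
    n_nodes: int,
    mean_degree: float,
    lambda_scale: float = DEFAULT_LAMBDA,
    seed=None,
    tolerance: float = 0.05,
    return_coords: bool = False,
):
    """Geographical graph: N points uniform in the unit square, pair (i, j)
    connected with probability c * exp(-lambda * s_ij).

    The distance s_ij is measured in units of the mean point spacing
    (1/sqrt(N) in the unit square), so the spatial character of the model
    does not change with N: networks of different sizes drawn from the
    same lambda have the same local topology.  The prefactor c is
    calibrated by bisection so the expected mean degree hits the target
    within ``tolerance``.
    """
    if not 0 < mean_degree < n_nodes:
        raise ValueError("mean degree must lie in (0, N)")
    rng = np.random.default_rng(seed)
    coords = rng.random((n_nodes, 2))
    w = np.exp(-lambda_scale * np.sqrt(n_nodes) * pdist(coords))
    target_edges = n_nodes * mean_degree / 2.0

    def expected_edges(c: float) -> float:
        return float(np.minimum(c * w, 1.0).sum())

    lo, hi = 0.0, 1.0
    for _ in range(200):
        if expected_edges(hi) >= target_edges:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            "geographical calibration failed: achievable mean degree "
            f"{2 * expected_edges(hi) / n_nodes:.3f} below target {mean_degree}"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expected_edges(mid) < target_edges:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    achieved = 2 * expected_edges(c) / n_nodes
    if abs(achieved - mean_degree) > tolerance * mean_degree:
        raise RuntimeError(
            f"geographical calibration failed: achieved <k> {achieved:.3f} "
            f"vs target {mean_degree}"
        )
    probs = np.minimum(c * w, 1.0)
    mask = rng.random(probs.size) < probs
    iu, ju = np.triu_indices(n_nodes, k=1)
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    net = NetworkTessellation(n_nodes, edges)
    if return_coords:
        return net, coords
    return net


def perturb_network(
    net: NetworkTessellation, noise_rate: float, seed=None
) -> NetworkTessellation:
    """Rewire noise: remove round(rate*E) random edges and add as many
    random absent pairs, preserving the edge count."""
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise rate must lie in [0, 1]")
    edges = sorted(net.edges)
    n_swap = round(noise_rate * len(edges))
    if n_swap == 0:
        return NetworkTessellation(net.n_nodes, edges)
    rng = np.random.default_rng(seed)
    remove_idx = set(rng.choice(len(edges), size=n_swap, replace=False).tolist())
    kept = [e for i, e in enumerate(edges) if i not in remove_idx]
    present = set(edges)
    added: set[tuple[int, int]] = set()
    while len(added) < n_swap:
        u, v = rng.integers(0, net.n_nodes, size=2)
        if u == v:
            continue
        pair = (min(int(u), int(v)), max(int(u), int(v)))
        if pair in present or pair in added:
            continue
        added.add(pair)
    return NetworkTessellation(net.n_nodes, kept + sorted(added))


_GENERATORS = {
    "random": lambda n, k, seed, **kw: generate_er(n, k, seed),
    "small_world": lambda n, k, seed, **kw: generate_ws(n, int(k), kw.get("rewire_p", 0.1), seed),
    "scalefree": lambda n, k, seed, **kw: generate_ba(n, int(k), kw.get("alpha", 1.0), seed),
    "geographical": lambda n, k, seed, **kw: generate_geographical(
        n, k, kw.get("lambda_scale", DEFAULT_LAMBDA), seed
    ),
    "scalefree_dm": lambda n, k, seed, **kw: generate_dm(n, int(k), seed),
}


def generate_model(model: str, n_nodes: int, mean_degree, seed, **params) -> NetworkTessellation:
    """Dispatch to a generator by model name."""
    if model not in _GENERATORS:
        raise ValueError(f"unknown model {model!r}; known: {sorted(_GENERATORS)}")
    return _GENERATORS[model](n_nodes, mean_degree, seed, **params)


@dataclass
class LabeledNetwork:
    """One generated network with its provenance and class label."""

    net: NetworkTessellation
    label: str
    model: str
    mean_degree: float
    n_nodes: int
    replicate: int
    seed: int
    params: dict = field(default_factory=dict)


def network_seed(master_seed: int, model: str, mean_degree, n_nodes: int, replicate: int) -> int:
    """Deterministic per-network seed from the master seed and coordinates."""
    model_id = _MODEL_IDS.get(model, 0)
    ss = np.random.SeedSequence(
        [int(master_seed), model_id, int(round(10 * float(mean_degree))), int(n_nodes), int(replicate)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def synthetic_dataset(
    master_seed: int,
    models=("random", "small_world", "scalefree", "geographical"),
    mean_degrees=(4, 6, 8, 10, 12, 14, 16),
    sizes=(500, 1000, 1500, 2000),
    replicates: int = 100,
) -> list[LabeledNetwork]:
    """The 4-model collection: models x <k> in {4..16} x N grid x replicates.

    At full benchmark scale (replicates=100, four sizes) this yields
    11200 networks, 2800 per model; smaller replicate counts keep the same
    label structure.  The scale-free class cycles the attachment exponent
    alpha through {0.5, 1.0, 1.5, 2.0} across replicates, covering both
    linear and nonlinear preferential attachment.
    """
    out = []
    for model in models:
        for k in mean_degrees:
            for n in sizes:
                for rep in range(replicates):
                    params = {}
                    if model == "scalefree":
                        params["alpha"] = BA_ALPHAS[rep % len(BA_ALPHAS)]
                    seed = network_seed(master_seed, model, k, n, rep)
                    net = generate_model(model, n, k, seed, **params)
                    out.append(
                        LabeledNetwork(net, model, model, k, n, rep, seed, params)
                    )
    return out


def rule_selection_dataset(
    master_seed: int, replicates: int = 50, n_nodes: int = 500,
    mean_degrees=(4, 6, 8, 10, 12, 14, 16),
) -> list[LabeledNetwork]:
    """Separate 4-model collection used only for scanning rules (N=500)."""
    return synthetic_dataset(
        master_seed + 1_000_003,
        sizes=(n_nodes,),
        mean_degrees=mean_degrees,
        replicates=replicates,
    )


def scalefree_dataset(
    master_seed: int, replicates: int = 100, n_nodes: int = 1000, mean_degree: int = 8
) -> list[LabeledNetwork]:
    """Five scale-free classes: BA with alpha in {0.5, 1, 1.5, 2} and DM."""
    out = []
    for alpha in BA_ALPHAS:
        label = f"ba_alpha_{alpha:g}"
        for rep in range(replicates):
            seed = network_seed(master_seed, "scalefree_ba", alpha * 100 + mean_degree, n_nodes, rep)
            net = generate_ba(n_nodes, mean_degree, alpha, seed)
            out.append(
                LabeledNetwork(net, label, "scalefree_ba", mean_degree, n_nodes, rep, seed, {"alpha": alpha})
            )
    for rep in range(replicates):
        seed = network_seed(master_seed, "scalefree_dm", mean_degree, n_nodes, rep)
        net = generate_dm(n_nodes, mean_degree, seed)
        out.append(
            LabeledNetwork(net, "dm", "scalefree_dm", mean_degree, n_nodes, rep, seed, {})
        )
    return out


def _int_seed(seed) -> int | None:
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(0, 2**31))
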