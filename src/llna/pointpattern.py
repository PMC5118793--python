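"""Proximity networks from 2-D point patterns (stomata-style application).

A point pattern (e.g. stomata centroids segmented from a leaf image) is
turned into a family of networks by connecting points closer than a
threshold radius delta_T; pairwise distances are normalized by the maximum
pairwise distance so delta lives in [0, 1].  Descriptors computed at each
threshold of an ascending sweep are concatenated into one feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import features as feat
from .automaton import NetworkTessellation, evolve
from .measures import measure_diagram
from .rules import LifeLikeRule, parse_rule

#: Default threshold sweep: 0.25 to 1.0 in steps of 0.0625 (13 values).
DEFAULT_DELTAS = tuple(np.arange(0.25, 1.0 + 1e-9, 0.0625).round(4).tolist())


@dataclass
class PointPattern:
    """2-D point coordinates with max-distance-normalized pair distances."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
            raise ValueError("need at least 2 points with (x, y) coordinates")
        self.coordinates = c

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    def normalized_distances(self) -> np.ndarray:
        """Full pairwise distance matrix scaled so the maximum is 1."""
        d = pdist(self.coordinates)
        dmax = d.max()
        if dmax == 0:
            raise ValueError("all points coincide")
        return squareform(d / dmax)


def build_threshold_network(pattern: PointPattern, delta: float) -> NetworkTessellation:
    """Connect points whose normalized distance is <= delta.

    Edge sets are nested: increasing delta only adds edges, ending in the
    complete graph at delta = 1.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    d = pattern.normalized_distances()
    iu, ju = np.triu_indices(pattern.n_points, k=1)
    mask = d[iu, ju] <= delta
    return NetworkTessellation(
        pattern.n_points, zip(iu[mask].tolist(), ju[mask].tolist())
    )


def threshold_sweep_descriptor(
    pattern: PointPattern,
    rule: LifeLikeRule | str,
    t: int = 350,
    sigma: float = 0.5,
    deltas=DEFAULT_DELTAS,
    seed=0,
    descriptor: str = "averages",
) -> np.ndarray:
    """Concatenate per-threshold descriptors over an ascending delta sweep.

    With the default ``averages`` descriptor ([<mu_S>, <mu_W>, <mu_L>])
    the result has length 3 * len(deltas).  Histogram variants concatenate
    their 20 (or 60) values per threshold instead.
    """
    deltas = list(deltas)
    if not deltas or any(b <= a for a, b in zip(deltas, deltas[1:])):
        raise ValueError("deltas must be non-empty and ascending")
    if isinstance(rule, str):
        rule = parse_rule(rule)
    parts = []
    for i, delta in enumerate(deltas):
        net = build_threshold_network(pattern, delta)
        diagram = evolve(rule, net, t=t, sigma=sigma, seed=(int(seed), i))
        measures = measure_diagram(diagram)
        group_max = float(measures.node_lz.max()) or 1.0
        parts.append(feat.assemble(measures, group_max=group_max).get(descriptor))
    return np.concatenate(parts)


def synth_point_pattern(kind: str, n_points: int, seed=None, **params) -> PointPattern:
    """Synthetic point patterns standing in for segmented stomata centroids.

    ``uniform``: homogeneous binomial (Poisson-like) points in the unit
    square.  ``clustered``: parent-offspring (Thomas-like) process with
    ``n_parents`` (default 5) Gaussian clusters of scale ``cluster_sd``
    (default 0.03).  ``regular``: square grid jittered by ``jitter``
    (default 0.01) times the cell size.
    """
    if n_points < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        coords = rng.random((n_points, 2))
    elif kind == "clustered":
        n_parents = params.get("n_parents", 5)
        sd = params.get("cluster_sd", 0.03)
        parents = rng.random((n_parents, 2))
        assign = rng.integers(0, n_parents, size=n_points)
        coords = parents[assign] + rng.normal(scale=sd, size=(n_points, 2))
        coords = np.clip(coords, 0.0, 1.0)
    elif kind == "regular":
        jitter = params.get("jitter", 0.01)
        side = int(np.ceil(np.sqrt(n_points)))
        xs, ys = np.meshgrid(np.arange(side), np.arange(side))
        grid = np.column_stack([xs.ravel(), ys.ravel()])[:n_points] / side
        coords = grid + rng.normal(scale=jitter / side, size=(n_points, 2)) if jitter else grid
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return PointPattern(coords)
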