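"""Shared fixtures: small random graphs and toroidal Moore grids."""

import numpy as np
import pytest

from llna.automaton import NetworkTessellation


def moore_torus(rows: int, cols: int) -> NetworkTessellation:
    """Toroidal grid where every node has exactly the 8 Moore neighbors."""
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    j = ((r + dr) % rows) * cols + (c + dc) % cols
                    if i < j:
                        edges.append((i, j))
    return NetworkTessellation(rows * cols, edges)


def random_net(n: int, p: float, seed: int) -> NetworkTessellation:
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    return NetworkTessellation(n, zip(iu[mask].tolist(), ju[mask].tolist()))


@pytest.fixture(scope="session")
def torus20():
    return moore_torus(20, 20)
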