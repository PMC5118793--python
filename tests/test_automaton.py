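import numpy as np
import pytest
from scipy.signal import convolve2d

from llna.automaton import (
    NetworkTessellation,
    SpaceTimeDiagram,
    all_densities,
    evolve,
    initial_state,
    neighborhood_density,
    step,
)
from llna.rules import LifeLikeRule, birth_satisfied, parse_rule, survival_satisfied

from conftest import moore_torus, random_net


def game_of_life_step(grid: np.ndarray) -> np.ndarray:
    """Independent brute-force Game-of-Life oracle on a toroidal grid."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    n = convolve2d(grid, kernel, mode="same", boundary="wrap")
    return ((n == 3) | ((grid == 1) & (n == 2))).astype(np.uint8)


class TestNetworkTessellation:
    def test_basic_properties(self):
        net = NetworkTessellation(3, [(0, 1), (1, 2)])
        assert net.n_edges == 2
        assert net.degrees.tolist() == [1, 2, 1]
        assert (net.adjacency.toarray() == net.adjacency.toarray().T).all()
        assert net.adjacency.diagonal().sum() == 0

    def test_self_loops_and_duplicates_dropped(self):
        net = NetworkTessellation(3, [(0, 1), (1, 0), (2, 2)])
        assert net.edges == frozenset({(0, 1)})

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            NetworkTessellation(3, [(0, 5)])


class TestDensity:
    def test_fraction_of_alive_neighbors(self):
        # star: node 0 linked to 1..4, two of them alive
        net = NetworkTessellation(5, [(0, i) for i in range(1, 5)])
        states = np.array([0, 1, 1, 0, 0], dtype=np.uint8)
        assert neighborhood_density(0, states, net) == 0.5
        assert neighborhood_density(0, np.zeros(5, dtype=np.uint8), net) == 0.0

    def test_path_graph_center(self):
        net = NetworkTessellation(3, [(0, 1), (1, 2)])
        assert neighborhood_density(1, np.array([1, 0, 1]), net) == 1.0

    def test_isolated_node_density_zero(self):
        net = NetworkTessellation(3, [(0, 1)])
        assert neighborhood_density(2, np.array([1, 1, 1]), net) == 0.0

    def test_vectorized_matches_scalar(self):
        net = random_net(60, 0.1, seed=3)
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, net.n_nodes).astype(np.uint8)
        rho = all_densities(states, net)
        for i in range(net.n_nodes):
            assert rho[i] == pytest.approx(neighborhood_density(i, states, net))


class TestInitialState:
    def test_degenerate_sigmas(self):
        net = random_net(50, 0.1, seed=1)
        assert initial_state(net, 0.0, seed=1).sum() == 0
        assert initial_state(net, 1.0, seed=1).sum() == net.n_nodes

    def test_alive_fraction_near_sigma(self):
        net = random_net(10000, 0.0, seed=1)
        s = initial_state(net, 0.5, seed=7)
        se = 0.5 / np.sqrt(10000)
        assert abs(s.mean() - 0.5) < 3 * se

    def test_reproducible(self):
        net = random_net(100, 0.05, seed=2)
        assert (initial_state(net, 0.5, seed=9) == initial_state(net, 0.5, seed=9)).all()


class TestStep:
    def test_all_dead_fixed_point_without_birth_zero(self):
        net = random_net(40, 0.2, seed=4)
        dead = np.zeros(net.n_nodes, dtype=np.uint8)
        assert step(parse_rule("B3/S23"), dead, net).sum() == 0

    def test_all_alive_fixed_point_with_survival_eight(self):
        net = random_net(40, 0.5, seed=5)
        assert net.degrees.min() >= 1
        alive = np.ones(net.n_nodes, dtype=np.uint8)
        assert step(parse_rule("B3/S238"), alive, net).sum() == net.n_nodes

    def test_oracle_equivalence_random_graphs_and_rules(self):
        """Vectorized step equals per-node birth/survival recomputation."""
        rng = np.random.default_rng(42)
        masks = rng.integers(0, 2**18, size=50)
        for g in range(50):
            n = int(rng.integers(10, 201))
            net = random_net(n, float(rng.uniform(0.02, 0.3)), seed=100 + g)
            states = rng.integers(0, 2, n).astype(np.uint8)
            rule = LifeLikeRule.from_mask(int(masks[g % 50]))
            expected = np.array(
                [
                    (survival_satisfied if s else birth_satisfied)(
                        rule, neighborhood_density(i, states, net)
                    )
                    for i, s in enumerate(states)
                ],
                dtype=np.uint8,
            )
            assert (step(rule, states, net) == expected).all(), rule.canonical_name


class TestMooreGridReduction:
    """On an all-8-neighbor torus, LLNA must equal the classic Life-like CA."""

    def test_b3s23_matches_game_of_life_100_steps(self, torus20):
        rng = np.random.default_rng(11)
        grid = rng.integers(0, 2, (20, 20)).astype(np.uint8)
        rule = parse_rule("B3/S23")
        states = grid.ravel()
        for _ in range(100):
            grid = game_of_life_step(grid)
            states = step(rule, states, torus20)
            assert (states == grid.ravel()).all()

    def test_glider_translates_with_period_four(self, torus20):
        grid = np.zeros((20, 20), dtype=np.uint8)
        # canonical glider
        for r, c in [(0, 1), (1, 2), (2, 0), (2, 1), (2, 2)]:
            grid[r + 5, c + 5] = 1
        rule = parse_rule("B3/S23")
        states = grid.ravel()
        diagram = evolve(rule, torus20, t=4, initial=states)
        final = diagram.matrix[-1].reshape(20, 20)
        assert final.sum() == 5  # glider survives intact
        assert (final == np.roll(np.roll(grid, 1, axis=0), 1, axis=1)).all()


class TestEvolve:
    def test_dimensions_and_initial_row(self):
        net = random_net(30, 0.2, seed=6)
        d = evolve(parse_rule("B3/S23"), net, t=5, sigma=0.5, seed=1)
        assert d.matrix.shape == (6, 30)
        assert (d.matrix[0] == initial_state(net, 0.5, seed=1)).all()

    def test_empty_rule_kills_everything(self):
        net = random_net(30, 0.2, seed=7)
        d = evolve(parse_rule("B/S"), net, t=5, sigma=0.7, seed=2)
        assert d.matrix[1:].sum() == 0

    def test_deterministic_given_seed(self):
        net = random_net(50, 0.1, seed=8)
        r = parse_rule("B135678/S03456")
        d1 = evolve(r, net, t=20, sigma=0.5, seed=3)
        d2 = evolve(r, net, t=20, sigma=0.5, seed=3)
        assert (d1.matrix == d2.matrix).all()

    def test_rejects_t_zero(self):
        net = random_net(10, 0.3, seed=9)
        with pytest.raises(ValueError):
            evolve(parse_rule("B3/S23"), net, t=0, seed=1)


class TestSpaceTimeDiagram:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            SpaceTimeDiagram(np.array([[0, 2], [1, 0]]))

    def test_degree_ordering_is_view_only(self):
        net = NetworkTessellation(3, [(0, 1), (1, 2), (0, 2), (1, 2)])
        d = SpaceTimeDiagram(np.array([[1, 0, 1], [0, 1, 0]], dtype=np.uint8))
        ordered = d.ordered_by_degree(net)
        assert ordered.shape == d.matrix.shape
        assert (np.sort(ordered[0]) == np.sort(d.matrix[0])).all()
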