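import numpy as np
import pytest

from llna.generators import (
    BA_ALPHAS,
    generate_ba,
    generate_dm,
    generate_er,
    generate_geographical,
    generate_ws,
    network_seed,
    perturb_network,
    rule_selection_dataset,
    scalefree_dataset,
    synthetic_dataset,
)


def _simple(net):
    assert net.adjacency.diagonal().sum() == 0
    assert (net.adjacency.toarray() == net.adjacency.toarray().T).all()
    assert net.adjacency.max() <= 1


class TestER:
    def test_mean_degree_within_sampling_error(self):
        ks = [generate_er(1000, 8, seed=s).mean_degree for s in range(50)]
        expected = 8 * 999 / 1000
        se = np.sqrt(2 * 8 / 1000 / 1000) * np.sqrt(1000)  # rough per-replicate SE
        assert abs(np.mean(ks) - expected) < 3 * se / np.sqrt(50) + 0.05

    def test_reproducible_and_simple(self):
        a = generate_er(200, 6, seed=5)
        b = generate_er(200, 6, seed=5)
        assert a.edges == b.edges
        _simple(a)


class TestWS:
    def test_edge_count_exact(self):
        net = generate_ws(500, 4, 0.1, seed=1)
        assert net.n_edges == 500 * 4 // 2
        _simple(net)

    def test_zero_rewiring_is_ring_lattice(self):
        net = generate_ws(20, 4, 0.0, seed=1)
        expected = set()
        for i in range(20):
            for d in (1, 2):
                expected.add(tuple(sorted((i, (i + d) % 20))))
        assert net.edges == frozenset(expected)

    def test_full_rewiring_spreads_degrees(self):
        var0 = np.var(generate_ws(500, 4, 0.0, seed=2).degrees)
        var1 = np.var(generate_ws(500, 4, 1.0, seed=2).degrees)
        assert var0 == 0.0 and var1 > 0.0

    def test_odd_degree_rejected(self):
        with pytest.raises(ValueError):
            generate_ws(100, 5, 0.1, seed=1)


class TestBA:
    def test_edge_count_bookkeeping(self):
        m = 4
        net = generate_ba(500, 2 * m, alpha=1.0, seed=3)
        clique_edges = m * (m + 1) // 2
        assert net.n_edges == clique_edges + m * (500 - m - 1)
        _simple(net)

    def test_linear_attachment_tail_exponent_near_three(self):
        # MLE for the power-law tail of a BA degree distribution
        degs = np.concatenate(
            [generate_ba(5000, 8, 1.0, seed=s).degrees for s in range(3)]
        )
        kmin = 8
        tail = degs[degs >= kmin]
        gamma = 1 + tail.size / np.sum(np.log(tail / (kmin - 0.5)))
        assert 2.4 < gamma < 3.6

    def test_superlinear_concentrates_on_hubs(self):
        frac2 = [
            generate_ba(2000, 8, 2.0, seed=s).degrees.max() / 2000 for s in range(20)
        ]
        frac05 = [
            generate_ba(2000, 8, 0.5, seed=s).degrees.max() / 2000 for s in range(20)
        ]
        assert np.median(frac2) > 3 * np.median(frac05)


class TestDM:
    def test_mean_degree_converges(self):
        ks = [generate_dm(1000, 8, seed=s).mean_degree for s in range(20)]
        assert 7.6 < np.mean(ks) < 8.4

    def test_triangle_growth_linear(self):
        # each edge selection closes at least one triangle
        import networkx as nx

        t_small = sum(nx.triangles(generate_dm(200, 8, seed=1).to_networkx()).values())
        t_large = sum(nx.triangles(generate_dm(800, 8, seed=1).to_networkx()).values())
        assert t_large > 2.5 * t_small

    def test_warns_on_infeasible_degree(self):
        with pytest.warns(UserWarning):
            generate_dm(100, 6, seed=1)


class TestGeographical:
    def test_calibrated_mean_degree(self):
        for k in (4, 16):
            net = generate_geographical(500, k, seed=2)
            assert abs(net.mean_degree - k) < 0.15 * k  # calibration + sampling

    def test_larger_lambda_shortens_edges(self):
        means = []
        for lam in (0.25, 1.0, 4.0):
            net, coords = generate_geographical(
                400, 8, lambda_scale=lam, seed=7, return_coords=True
            )
            lengths = [
                np.linalg.norm(coords[u] - coords[v]) for u, v in net.edges
            ]
            means.append(np.mean(lengths))
        assert means[0] > means[1] > means[2]

    def test_reproducible(self):
        a = generate_geographical(300, 6, seed=9)
        b = generate_geographical(300, 6, seed=9)
        assert a.edges == b.edges
        _simple(a)


class TestPerturb:
    def test_zero_rate_identity(self):
        net = generate_er(200, 8, seed=1)
        assert perturb_network(net, 0.0, seed=2).edges == net.edges

    def test_edge_count_preserved_and_exact_swap(self):
        net = generate_er(200, 10, seed=3)
        e = net.n_edges
        pert = perturb_network(net, 0.1, seed=4)
        assert pert.n_edges == e
        removed = net.edges - pert.edges
        added = pert.edges - net.edges
        assert len(removed) == len(added) == round(0.1 * e)


class TestDatasets:
    def test_synthetic_dataset_structure(self):
        nets = synthetic_dataset(1, sizes=(100,), replicates=2, mean_degrees=(4, 8))
        assert len(nets) == 4 * 2 * 2
        labels = {ln.label for ln in nets}
        assert labels == {"random", "small_world", "scalefree", "geographical"}
        alphas = [ln.params["alpha"] for ln in nets if ln.label == "scalefree"]
        assert set(alphas) <= set(BA_ALPHAS)

    def test_scalefree_dataset_five_classes(self):
        nets = scalefree_dataset(1, replicates=2, n_nodes=120)
        assert len(nets) == 10
        assert len({ln.label for ln in nets}) == 5

    def test_rule_selection_disjoint_from_synthetic(self):
        a = synthetic_dataset(1, sizes=(100,), replicates=1, mean_degrees=(4,))
        b = rule_selection_dataset(1, replicates=1, n_nodes=100, mean_degrees=(4,))
        assert {ln.seed for ln in a}.isdisjoint({ln.seed for ln in b})

    def test_per_network_seeds_deterministic(self):
        s1 = network_seed(7, "random", 8, 500, 3)
        s2 = network_seed(7, "random", 8, 500, 3)
        assert s1 == s2 and 0 <= s1 < 2**31
        assert s1 != network_seed(7, "random", 8, 500, 4)
        assert s1 != network_seed(8, "random", 8, 500, 3)
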