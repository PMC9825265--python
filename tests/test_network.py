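import math

import networkx as nx
import numpy as np
import pytest

from _oracles import brute_chromatic, brute_components, brute_min_boundary_distance, random_graph
from clonemorph.network import (
    CellNetwork,
    average_colorability,
    build_network,
    chromatic_number,
    component_statistics,
    degree_statistics,
    fractal_dimension,
    network_metrics,
)
from clonemorph.synthetic import place_discs
from conftest import sierpinski_carpet


class TestBuildNetwork:
    def test_discs_gap_3um_edge(self):
        img, _ = place_discs([(100.0, 100.0), (100.0, 143.0)], [20.0, 20.0], (256, 256))
        net = build_network(img, adjacency_threshold=5.0)
        assert set(map(frozenset, net.graph.edges)) == {frozenset((1, 2))}

    def test_discs_gap_10um_no_edge(self):
        img, _ = place_discs([(100.0, 100.0), (100.0, 150.0)], [20.0, 20.0], (256, 256))
        net = build_network(img, adjacency_threshold=5.0)
        assert net.n_edges == 0

    def test_matches_planted_truth(self, small_population):
        img, truth = small_population
        net = build_network(img)
        assert {tuple(sorted(e)) for e in net.graph.edges} == truth.adjacency

    def test_matches_brute_force_boundary_distances(self, small_population):
        # exact agreement with the all-pairs boundary-pixel oracle (strict <)
        img, _ = small_population
        net = build_network(img)
        labels = list(img.labels)[:12]  # oracle is O(pixels²); check a subset
        for i, u in enumerate(labels):
            for v in labels[i + 1:]:
                d = brute_min_boundary_distance(img.pixels, u, v, img.pixel_size)
                assert net.graph.has_edge(int(u), int(v)) == (d < 5.0)

    def test_edges_monotone_in_threshold(self, small_population):
        img, _ = small_population
        e3 = set(build_network(img, 3.0).graph.edges)
        e5 = set(build_network(img, 5.0).graph.edges)
        e8 = set(build_network(img, 8.0).graph.edges)
        assert e3 <= e5 <= e8

    def test_empty_image_gives_empty_network(self):
        from clonemorph.io import LabelImage

        net = build_network(LabelImage(np.zeros((32, 32), dtype=int), 1.0))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_node_attributes_match_truth(self, small_population):
        img, truth = small_population
        net = build_network(img)
        for lab in list(img.labels)[:10]:
            c = net.graph.nodes[int(lab)]["centroid"]
            tc = truth.centroids_um[lab]
            assert math.hypot(c[0] - tc[0], c[1] - tc[1]) < 2 * img.pixel_size


class TestDegreeStatistics:
    def test_path_graph_closed_form(self):
        mean, var, ent = degree_statistics(nx.path_graph(3))
        assert mean == pytest.approx(4 / 3)
        assert var == pytest.approx(2 / 9)
        assert ent == pytest.approx(-(2 / 3) * math.log(2 / 3) - (1 / 3) * math.log(1 / 3))

    def test_edgeless_graph(self):
        g = nx.empty_graph(5)
        assert degree_statistics(g) == (0.0, 0.0, 0.0)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            degree_statistics(nx.Graph())

    def test_random_graph_vs_exhaustive_count(self):
        rng = np.random.default_rng(0)
        nodes, edges = random_graph(30, 0.15, rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        degs = [sum(1 for e in edges if n in e) for n in nodes]
        mean, var, _ = degree_statistics(g)
        assert mean == pytest.approx(np.mean(degs))
        assert var == pytest.approx(np.var(degs))


class TestColorability:
    def test_clique_chromatic_numbers(self):
        assert chromatic_number(nx.empty_graph(1)) == (1, True)
        assert chromatic_number(nx.complete_graph(3)) == (3, True)

    def test_averaging_formula_k3_union_k2(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(2))
        assert average_colorability(g) == pytest.approx(2.5)

    def test_five_cycle_needs_three_colors(self):
        chi, exact = chromatic_number(nx.cycle_graph(5))
        assert chi == 3 and exact
        # oracle: exhaustive search proves no 2-coloring exists
        assert brute_chromatic(list(range(5)), set(nx.cycle_graph(5).edges)) == 3

    def test_greedy_bound_above_exact_limit_warns(self):
        g = nx.cycle_graph(30)
        with pytest.warns(UserWarning, match="upper bound"):
            val = average_colorability(g, exact_limit=10)
        assert val >= 2  # greedy is an upper bound on chi = 2

    def test_chi_bounds_on_random_components(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            nodes, edges = random_graph(int(rng.integers(2, 11)), 0.4, rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                chi, exact = chromatic_number(sub)
                assert exact
                omega = max((len(c) for c in nx.find_cliques(sub)), default=1)
                delta = max((d for _, d in sub.degree()), default=0)
                assert omega <= chi <= delta + 1


class TestComponentStatistics:
    def test_connected_graph(self):
        n, h, frac = component_statistics(nx.path_graph(4))
        assert n == 1 and h == 0.0 and frac == 1.0

    def test_sizes_6_and_2(self):
        g = nx.disjoint_union(nx.path_graph(6), nx.path_graph(2))
        n, h, frac = component_statistics(g)
        assert n == 2
        assert frac == pytest.approx(0.75)
        assert h == pytest.approx(-(0.75 * math.log(0.75) + 0.25 * math.log(0.25)))

    def test_uniform_two_mass(self):
        g = nx.disjoint_union(nx.path_graph(4), nx.path_graph(4))
        _, h, _ = component_statistics(g)
        assert h == pytest.approx(math.log(2))

    def test_masses_conserve_node_count(self, small_population):
        img, _ = small_population
        net = build_network(img)
        assert net.component_masses().sum() == net.n_nodes

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(11)
        nodes, edges = random_graph(12, 0.12, rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        comps = brute_components(nodes, edges)
        n, _, frac = component_statistics(g)
        assert n == len(comps)
        assert frac == pytest.approx(max(len(c) for c in comps) / 12)


class TestFractalDimension:
    def test_filled_square(self):
        assert fractal_dimension(np.ones((256, 256), dtype=bool)) == pytest.approx(2.0, abs=0.05)

    def test_straight_line(self):
        line = np.zeros((256, 256), dtype=bool)
        line[100, :] = True
        assert fractal_dimension(line) == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet_depth4(self):
        carpet = sierpinski_carpet(4)  # 81×81, analytic dim log8/log3
        dim = fractal_dimension(carpet, box_sizes=[1, 3, 9, 27])
        assert dim == pytest.approx(math.log(8) / math.log(3), abs=0.05)

    def test_translation_by_whole_boxes(self):
        carpet = sierpinski_carpet(4)
        padded = np.pad(carpet, ((27, 0), (27, 0)))
        d1 = fractal_dimension(carpet, box_sizes=[1, 3, 9, 27])
        d2 = fractal_dimension(padded, box_sizes=[1, 3, 9, 27])
        assert d2 == pytest.approx(d1, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValueError):
            fractal_dimension(np.ones((64, 64), dtype=bool), box_sizes=[2, 4])


class TestMetricsBundle:
    def test_bundle_consistent_with_parts(self, small_population):
        img, _ = small_population
        net = build_network(img)
        m = network_metrics(net, foreground=img.foreground)
        mean, var, ent = degree_statistics(net)
        assert m.mean_degree == mean and m.degree_variance == var
        assert m.component_number == component_statistics(net)[0]
        assert m.colorability_exact
        assert m.fractal_dimension is not None and 0 <= m.fractal_dimension <= 2
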