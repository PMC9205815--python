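"""Morse graph construction, Betti numbers, critical cells, and the bound."""

import itertools

import networkx as nx
import pytest

from conftest import square_landscape
from morsescape import (
    GenotypeSpace,
    MorseGraph,
    NeutralityError,
    TheoremViolationError,
    additive_landscape,
    analyze,
    assert_connected,
    betti_numbers,
    build_morse_function,
    build_morse_graph,
    critical_cells,
    enumerate_rse,
    find_peaks,
    house_of_cards,
    nk_landscape,
    rough_mount_fuji,
    strong_morse_check,
)
from morsescape.morse import write_edge_list


class TestBuildMorseGraph:
    def test_example1_edge_sets(self, example1):
        graph = build_morse_graph(example1)
        assert len(graph.e1) == 5
        assert graph.e2 == frozenset(
            {("001", "100"), ("001", "111"), ("100", "111")}
        )
        assert not graph.e1 & graph.e2

    def test_each_non_peak_is_low_end_of_one_e1_edge(self, example1):
        graph = build_morse_graph(example1)
        peaks = find_peaks(example1)
        W = example1.fitness
        low_ends = sorted(min(e, key=lambda g: W[g]) for e in graph.e1)
        assert low_ends == sorted(set(example1.genotypes()) - peaks)

    def test_additive_landscape_is_a_spanning_tree(self):
        landscape = additive_landscape(3, [1.0, 0.5, 0.25])
        graph = build_morse_graph(landscape)
        assert len(graph.e1) == 7 and len(graph.e2) == 0
        assert nx.is_tree(graph.to_networkx())

    def test_intro_rse_square(self, intro_rse):
        graph = build_morse_graph(intro_rse)
        assert len(graph.e1) == 2 and len(graph.e2) == 1

    def test_e2_bijection_with_rse_instances(self):
        for seed in range(10):
            landscape = house_of_cards(5, seed)
            graph = build_morse_graph(landscape)
            highs = {
                tuple(sorted(i.high_diagonal)) for i in enumerate_rse(landscape)
            }
            assert graph.e2 == frozenset(highs)

    def test_refuses_non_strict(self, intro_sign):
        with pytest.raises(NeutralityError):
            build_morse_graph(intro_sign)

    def test_tie_break_changes_e1_but_not_counts(self, example1):
        a = build_morse_graph(example1, tie_break="lex")
        b = build_morse_graph(example1, tie_break="lex_last")
        assert a.e1 != b.e1  # "000" has two fittest neighbors, 001 and 100
        assert len(a.e1) == len(b.e1)
        assert a.e2 == b.e2


class TestBettiNumbers:
    def test_example1(self, example1):
        graph = build_morse_graph(example1)
        assert betti_numbers(graph) == (1, 1)

    def test_additive_tree(self):
        landscape = additive_landscape(3, [1.0, 0.5, 0.25])
        assert betti_numbers(build_morse_graph(landscape)) == (1, 0)

    def test_edgeless_graph_definition(self):
        graph = MorseGraph(
            vertices=("00", "01", "10", "11"), e1=frozenset(), e2=frozenset()
        )
        assert betti_numbers(graph) == (4, 0)

    def test_agrees_with_cycle_space_rank(self):
        for seed in range(10):
            graph = build_morse_graph(house_of_cards(5, seed))
            g = graph.to_networkx()
            b0, b1 = betti_numbers(graph)
            assert b0 == nx.number_connected_components(g)
            assert b1 == len(nx.cycle_basis(g))


class TestConnectivity:
    def test_example1_connected(self, example1):
        assert assert_connected(build_morse_graph(example1))

    def test_house_of_cards_sweep(self):
        for seed in range(100):
            assert assert_connected(build_morse_graph(house_of_cards(5, seed)))

    def test_single_locus_space(self):
        landscape = additive_landscape(1, [1.0])
        graph = build_morse_graph(landscape)
        assert len(graph.e1) == 1
        assert assert_connected(graph)

    def test_disconnected_graph_trips_the_wire(self):
        graph = MorseGraph(vertices=("0", "1"), e1=frozenset(), e2=frozenset())
        with pytest.raises(TheoremViolationError):
            assert_connected(graph)


class TestMorseFunction:
    def test_example1_default_constant_and_values(self, example1):
        graph = build_morse_graph(example1)
        f = build_morse_function(graph, example1)
        assert f.C == 4.0
        assert all(f.edge_values[e] == 4.0 for e in graph.e2)
        assert f.vertex_values["111"] == -3.0
        assert f.edge_values[("000", "001")] == (0.0 + -3.0) / 2

    def test_e1_values_lie_strictly_between_endpoints(self):
        landscape = house_of_cards(4, 3)
        graph = build_morse_graph(landscape)
        f = build_morse_function(graph, landscape)
        for u, v in graph.e1:
            lo, hi = sorted((f.vertex_values[u], f.vertex_values[v]))
            assert lo < f.edge_values[(u, v)] < hi

    def test_too_small_constant_rejected(self, example1):
        from morsescape import LandscapeError

        graph = build_morse_graph(example1)
        with pytest.raises(LandscapeError):
            build_morse_function(graph, example1, C=3.0)

    def test_non_integral_default_constant(self):
        landscape = house_of_cards(3, 0)  # fitnesses in (0,1)
        graph = build_morse_graph(landscape)
        f = build_morse_function(graph, landscape)
        assert f.C == landscape.max_abs_fitness() + 1.0


class TestCriticalCells:
    def test_example1_critical_cells(self, example1):
        graph = build_morse_graph(example1)
        f = build_morse_function(graph, example1)
        crit = critical_cells(graph, f)
        assert crit.critical_vertices == frozenset({"100", "001", "111"})
        assert crit.critical_edges == graph.e2
        assert (crit.m0, crit.m1) == (3, 3)

    def test_additive_single_critical_vertex(self):
        landscape = additive_landscape(3, [1.0, 0.5, 0.25])
        graph = build_morse_graph(landscape)
        f = build_morse_function(graph, landscape)
        crit = critical_cells(graph, f)
        assert (crit.m0, crit.m1) == (1, 0)

    def test_isolated_vertex_is_vacuously_critical(self):
        graph = MorseGraph(vertices=("0", "1"), e1=frozenset(), e2=frozenset())
        from morsescape import MorseFunction

        f = MorseFunction(vertex_values={"0": 0.0, "1": 1.0}, edge_values={}, C=2.0)
        crit = critical_cells(graph, f)
        assert crit.critical_vertices == frozenset({"0", "1"})

    def test_constructed_cells_match_peaks_and_e2(self):
        for seed in range(25):
            landscape = house_of_cards(5, seed)
            graph = build_morse_graph(landscape)
            f = build_morse_function(graph, landscape)
            crit = critical_cells(graph, f)
            assert crit.critical_vertices == frozenset(find_peaks(landscape))
            assert crit.critical_edges == graph.e2


class TestStrongMorse:
    def test_example1_equality(self, example1):
        graph = build_morse_graph(example1)
        f = build_morse_function(graph, example1)
        check = strong_morse_check(graph, f)
        assert check["holds"]
        assert check["m1"] - check["m0"] == check["b1"] - check["b0"] == 0

    def test_nk_landscape_equality(self):
        landscape = nk_landscape(6, 2, 7)
        graph = build_morse_graph(landscape)
        f = build_morse_function(graph, landscape)
        check = strong_morse_check(graph, f)
        assert check["holds"]
        assert check["m1"] - check["m0"] == check["b1"] - check["b0"]


class TestAnalyze:
    def test_example1_report(self, example1):
        report = analyze(example1)
        assert report.to_dict() == {
            "n_peaks": 3,
            "n_rse": 3,
            "b0": 1,
            "b1": 1,
            "m0": 3,
            "m1": 3,
            "morse_slack": 0,
            "bound_slack": 1,
            "bound_holds": True,
            "tie_break": "lex",
            "C": 4.0,
        }

    def test_intro_rse_bound_tight(self, intro_rse):
        report = analyze(intro_rse)
        assert (report.n_peaks, report.n_rse, report.bound_slack) == (2, 1, 0)

    def test_additive_bound_tight(self):
        report = analyze(additive_landscape(5, [1, -2, 3, -4, 5]))
        assert (report.n_peaks, report.n_rse, report.bound_slack) == (1, 0, 0)

    @pytest.mark.parametrize(
        "make",
        [
            lambda s: house_of_cards(5, s),
            lambda s: nk_landscape(6, 2, s),
            lambda s: rough_mount_fuji(5, 1.0, 1.0, s),
        ],
        ids=["hoc", "nk", "rmf"],
    )
    def test_construction_identities_across_models(self, make):
        for seed in range(15):
            landscape = make(seed)
            report = analyze(landscape)
            assert report.b0 == 1
            assert report.m0 == report.n_peaks
            assert report.m1 == report.n_rse
            assert report.morse_slack == 0
            assert report.bound_slack == report.b1 >= 0

    def test_tie_break_independence_of_counts(self):
        for seed in range(10):
            landscape = house_of_cards(4, seed)
            a = analyze(landscape, tie_break="lex")
            b = analyze(landscape, tie_break="lex_last")
            assert a.to_dict() | {"tie_break": ""} == b.to_dict() | {"tie_break": ""}


class TestEdgeListExport:
    def test_format(self, example1, tmp_path):
        graph = build_morse_graph(example1)
        f = build_morse_function(graph, example1)
        out = tmp_path / "edges.tsv"
        write_edge_list(graph, f, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 8
        kinds = {line.split("\t")[2] for line in lines}
        assert kinds == {"E1", "E2"}
        u, v, kind, value = lines[-1].split("\t")
        assert kind == "E2" and float(value) == 4.0
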