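"""The Morse graph, discrete Morse function, critical cells, and the bound.

The construction that links landscape ruggedness to graph topology:

* **Graph** ``G = (V, E1 ∪ E2)`` on all genotypes.  ``E1`` holds, for each
  non-peak genotype, one edge to a fittest strictly-better neighbor (an
  adaptive "steepest-ascent" step; ties between equally-fit neighbors are
  broken by a pluggable policy).  ``E2`` holds one distance-2 edge per RSE
  instance, joining its high diagonal — both common neighbors of an E2
  edge's endpoints lie strictly below both endpoints.
* **Function** ``f``: on vertices ``f(v) = -W(v)``; on E1 edges the midpoint
  of the endpoint values; on E2 edges a constant ``C`` exceeding
  ``max|W|``.
* **Criticality**: a vertex is critical when every incident edge carries a
  larger ``f``; an edge is critical when it exceeds both endpoints.  By
  construction the critical vertices are exactly the peaks and the critical
  edges exactly ``E2``, so the strong Morse inequality
  ``m1 - m0 >= b1 - b0`` on the connected graph ``G`` yields
  ``#RSE >= #peaks - 1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx

from .core import (
    FitnessLandscape,
    NeutralityError,
    LandscapeError,
    TheoremViolationError,
    neighbors,
)
from .epistasis import enumerate_rse, find_peaks

__all__ = [
    "MorseGraph",
    "MorseFunction",
    "CriticalSet",
    "MorseReport",
    "build_morse_graph",
    "betti_numbers",
    "assert_connected",
    "build_morse_function",
    "critical_cells",
    "strong_morse_check",
    "analyze",
    "write_edge_list",
]

Edge = tuple[str, str]  # canonical form: (u, v) with u < v


def _edge(u: str, v: str) -> Edge:
    return (u, v) if u < v else (v, u)


#: Tie-break policies for choosing among equally-fit best neighbors.
TIE_BREAKS: dict[str, Callable[[list[str]], str]] = {
    "lex": min,
    "lex_last": max,
}


@dataclass(frozen=True)
class MorseGraph:
    """The graph ``(V, E1 ∪ E2)``: ascent edges plus RSE high diagonals."""

    vertices: tuple[str, ...]
    e1: frozenset[Edge]  # distance-1: one fittest-improving edge per non-peak
    e2: frozenset[Edge]  # distance-2: high diagonals of RSE instances
    tie_break: str = "lex"

    @property
    def edges(self) -> frozenset[Edge]:
        return self.e1 | self.e2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.e1, kind="E1")
        g.add_edges_from(self.e2, kind="E2")
        return g


@dataclass(frozen=True)
class MorseFunction:
    """``f`` on vertices and edges: ``-W`` on vertices, midpoints on E1, ``C`` on E2."""

    vertex_values: dict[str, float]
    edge_values: dict[Edge, float]
    C: float


@dataclass(frozen=True)
class CriticalSet:
    critical_vertices: frozenset[str]
    critical_edges: frozenset[Edge]

    @property
    def m0(self) -> int:
        return len(self.critical_vertices)

    @property
    def m1(self) -> int:
        return len(self.critical_edges)


@dataclass(frozen=True)
class MorseReport:
    """Complete ruggedness report for one landscape.

    ``bound_slack = n_rse - (n_peaks - 1)`` is the margin of the
    peaks-vs-RSE bound; ``morse_slack = (m1 - m0) - (b1 - b0)`` is the
    margin of the strong Morse inequality (zero for this construction).
    """

    n_peaks: int
    n_rse: int
    b0: int
    b1: int
    m0: int
    m1: int
    morse_slack: int
    bound_slack: int
    bound_holds: bool
    tie_break: str
    C: float

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_rse": self.n_rse,
            "b0": self.b0,
            "b1": self.b1,
            "m0": self.m0,
            "m1": self.m1,
            "morse_slack": self.morse_slack,
            "bound_slack": self.bound_slack,
            "bound_holds": self.bound_holds,
            "tie_break": self.tie_break,
            "C": self.C,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def build_morse_graph(
    landscape: FitnessLandscape, tie_break: str = "lex"
) -> MorseGraph:
    """Construct ``(V, E1 ∪ E2)`` from a strict landscape.

    Each non-peak genotype contributes exactly one E1 edge, to its
    maximum-fitness neighbor (necessarily strictly fitter); equally-fit
    candidates are resolved by the named policy (default: lexicographically
    smallest).  E2 edges are the high diagonals of all RSE instances.
    """
    if not landscape.strict:
        raise NeutralityError("build_morse_graph requires a strict landscape")
    if tie_break not in TIE_BREAKS:
        raise LandscapeError(f"unknown tie-break policy {tie_break!r}")
    pick = TIE_BREAKS[tie_break]
    W = landscape.fitness
    e1: set[Edge] = set()
    for g in landscape.space.genotypes():
        nbrs = neighbors(landscape.space, g)
        best_w = max(W[h] for h in nbrs)
        if best_w < W[g]:
            continue  # peak: no beneficial mutation
        best = pick([h for h in nbrs if W[h] == best_w])
        e1.add(_edge(g, best))
    e2 = frozenset(
        _edge(*inst.high_diagonal) for inst in enumerate_rse(landscape)
    )
    return MorseGraph(
        vertices=tuple(landscape.space.genotypes()),
        e1=frozenset(e1),
        e2=e2,
        tie_break=tie_break,
    )


def betti_numbers(graph: MorseGraph) -> tuple[int, int]:
    """(b0, b1): connected components and cyclomatic number |E| + b0 - |V|."""
    g = graph.to_networkx()
    b0 = nx.number_connected_components(g)
    b1 = g.number_of_edges() + b0 - g.number_of_nodes()
    return b0, b1


def assert_connected(graph: MorseGraph) -> bool:
    """Tripwire: the constructed graph is provably connected; raise otherwise."""
    if nx.is_connected(graph.to_networkx()):
        return True
    raise TheoremViolationError(
        "Morse graph is disconnected — this contradicts a proven property "
        "of the construction and signals an implementation bug"
    )


def build_morse_function(
    graph: MorseGraph, landscape: FitnessLandscape, C: float | None = None
) -> MorseFunction:
    """Attach ``f`` to the graph: ``-W`` on vertices, midpoints on E1, ``C`` on E2.

    The default ``C`` is ``floor(max|W|) + 1`` for integral fitness values,
    else ``max|W| + 1`` — the smallest convenient constant exceeding
    ``max|W|``.
    """
    w_max = landscape.max_abs_fitness()
    if C is None:
        C = math.floor(w_max) + 1.0 if landscape.is_integral() else w_max + 1.0
    if not C > w_max:
        raise LandscapeError(f"C={C} must strictly exceed max|W|={w_max}")
    vertex_values = {g: -landscape.fitness[g] for g in graph.vertices}
    edge_values: dict[Edge, float] = {}
    for u, v in graph.e1:
        edge_values[(u, v)] = (vertex_values[u] + vertex_values[v]) / 2.0
    for u, v in graph.e2:
        edge_values[(u, v)] = float(C)
    return MorseFunction(vertex_values=vertex_values, edge_values=edge_values, C=float(C))


def critical_cells(graph: MorseGraph, f: MorseFunction) -> CriticalSet:
    """Evaluate the criticality definitions directly on (graph, f).

    A vertex with no incident edges is vacuously critical.  For graphs and
    functions built by this module, the critical vertices come out as
    exactly the peak set and the critical edges as exactly E2.
    """
    incident: dict[str, list[Edge]] = {v: [] for v in graph.vertices}
    for e in graph.edges:
        for end in e:
            incident[end].append(e)
    try:
        critical_vertices = frozenset(
            v
            for v in graph.vertices
            if all(f.edge_values[e] > f.vertex_values[v] for e in incident[v])
        )
        critical_edges = frozenset(
            e
            for e in graph.edges
            if f.edge_values[e] > max(f.vertex_values[e[0]], f.vertex_values[e[1]])
        )
    except KeyError as exc:
        raise LandscapeError(f"Morse function not total on cells: missing {exc}") from exc
    return CriticalSet(critical_vertices, critical_edges)


def strong_morse_check(graph: MorseGraph, f: MorseFunction) -> dict:
    """Evaluate the strong Morse inequality m1 - m0 >= b1 - b0 on (graph, f)."""
    crit = critical_cells(graph, f)
    b0, b1 = betti_numbers(graph)
    return {
        "m0": crit.m0,
        "m1": crit.m1,
        "b0": b0,
        "b1": b1,
        "holds": crit.m1 - crit.m0 >= b1 - b0,
    }


def analyze(
    landscape: FitnessLandscape, tie_break: str = "lex", C: float | None = None
) -> MorseReport:
    """Full ruggedness analysis of a strict landscape.

    Runs peak finding, RSE enumeration, the Morse construction and the
    criticality/Betti accounting, and verifies both inequalities.  A failed
    bound or a disconnected graph raises: both would contradict proven
    statements, so they indicate a bug, never a property of the data.
    """
    peaks = find_peaks(landscape)
    instances = enumerate_rse(landscape)
    graph = build_morse_graph(landscape, tie_break=tie_break)
    assert_connected(graph)
    b0, b1 = betti_numbers(graph)
    f = build_morse_function(graph, landscape, C=C)
    crit = critical_cells(graph, f)
    check = strong_morse_check(graph, f)
    bound_slack = len(instances) - (len(peaks) - 1)
    report = MorseReport(
        n_peaks=len(peaks),
        n_rse=len(instances),
        b0=b0,
        b1=b1,
        m0=crit.m0,
        m1=crit.m1,
        morse_slack=(crit.m1 - crit.m0) - (b1 - b0),
        bound_slack=bound_slack,
        bound_holds=bound_slack >= 0,
        tie_break=tie_break,
        C=f.C,
    )
    if not check["holds"] or not report.bound_holds:
        raise TheoremViolationError(
            f"provable inequality failed: {report.to_dict()} — implementation bug"
        )
    return report


def write_edge_list(graph: MorseGraph, f: MorseFunction, destination) -> None:
    """Edge-list export: one line per edge, ``u<TAB>v<TAB>{E1|E2}<TAB>f_value``."""

    def _emit(fh) -> None:
        for u, v in sorted(graph.e1):
            fh.write(f"{u}\t{v}\tE1\t{f.edge_values[(u, v)]!r}\n")
        for u, v in sorted(graph.e2):
            fh.write(f"{u}\t{v}\tE2\t{f.edge_values[(u, v)]!r}\n")

    if hasattr(destination, "write"):
        _emit(destination)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            _emit(fh)
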