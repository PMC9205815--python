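"""Shared fixtures and independent brute-force oracles.

The oracles recompute quantities by exhaustive search, deliberately avoiding
the code paths they are used to check: RSE instances by scanning raw
genotype tuples/pairs instead of the square enumerator, bottleneck values by
scoring every simple path of the Hamming graph instead of threshold
descent.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from morsescape import (
    FitnessLandscape,
    GenotypeSpace,
    fixture,
    hamming,
)


@pytest.fixture
def example1() -> FitnessLandscape:
    """The 3-cube worked example: 3 peaks, 3 RSE instances."""
    return fixture("example1")


@pytest.fixture
def intro_rse() -> FitnessLandscape:
    """Two-locus reciprocal-sign-epistasis square (1, -1, -1, 1)."""
    return fixture("intro_rse")


@pytest.fixture
def intro_sign() -> FitnessLandscape:
    """Two-locus sign-epistasis square (1, -1, 1, 1); non-strict."""
    return fixture("intro_sign")


def square_landscape(w00: float, w01: float, w10: float, w11: float) -> FitnessLandscape:
    """Arbitrary two-locus landscape from its four fitness values."""
    from morsescape import validate_no_neutral

    landscape = FitnessLandscape(
        GenotypeSpace.binary(2),
        {"00": w00, "01": w01, "10": w10, "11": w11},
    )
    validate_no_neutral(landscape)
    return landscape


def hamming_graph(space: GenotypeSpace) -> nx.Graph:
    """The plain single-mutation graph of the space."""
    from morsescape import neighbors

    g = nx.Graph()
    genotypes = list(space.genotypes())
    g.add_nodes_from(genotypes)
    for u in genotypes:
        for v in neighbors(space, u):
            g.add_edge(u, v)
    return g


def brute_rse_high_diagonals_pairs(landscape: FitnessLandscape) -> set[frozenset[str]]:
    """RSE high diagonals by scanning all unordered distance-2 genotype pairs.

    For each pair, the candidate low diagonal is the set of common
    single-mutation neighbors; the pair is a high diagonal iff every common
    neighbor sits strictly below both endpoints.  Independent of the square
    enumerator.
    """
    W = landscape.fitness
    genotypes = list(landscape.space.genotypes())
    out: set[frozenset[str]] = set()
    for u, v in itertools.combinations(genotypes, 2):
        if hamming(u, v) != 2:
            continue
        common = [
            y for y in genotypes if hamming(u, y) == 1 and hamming(v, y) == 1
        ]
        assert len(common) == 2  # two free loci -> exactly two mixed corners
        if all(W[y] < W[u] and W[y] < W[v] for y in common):
            out.add(frozenset((u, v)))
    return out


def brute_rse_high_diagonals_4subsets(landscape: FitnessLandscape) -> set[frozenset[str]]:
    """RSE high diagonals by the literal scan over all 4-element genotype subsets.

    Only feasible for small spaces (<= 32 genotypes or so).  Checks the
    distance pattern and the diagonal-dominance inequality for every
    labeling of the subset.
    """
    W = landscape.fitness
    genotypes = list(landscape.space.genotypes())
    out: set[frozenset[str]] = set()
    for quad in itertools.combinations(genotypes, 4):
        for s1, s4 in itertools.combinations(quad, 2):
            s2, s3 = (g for g in quad if g not in (s1, s4))
            if hamming(s1, s4) != 2 or hamming(s2, s3) != 2:
                continue
            if not all(
                hamming(a, b) == 1 for a in (s1, s4) for b in (s2, s3)
            ):
                continue
            if max(W[s2], W[s3]) < min(W[s1], W[s4]):
                out.add(frozenset((s1, s4)))
    return out


def brute_bottleneck_value(landscape: FitnessLandscape, a: str, b: str) -> float:
    """Maximin over every simple single-mutation path from a to b."""
    W = landscape.fitness
    g = hamming_graph(landscape.space)
    return max(
        min(W[v] for v in path) for path in nx.all_simple_paths(g, a, b)
    )
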