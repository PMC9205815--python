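"""Genotype spaces, fitness landscapes, and the strictness contract.

A fitness landscape is a total map ``W`` from fixed-length genotype strings
(one character per locus) to real fitness.  The combinatorial structure used
throughout the package is the Hamming graph of the space: genotypes are
adjacent when they differ at exactly one locus.  The central validity
contract is *strictness* — no pair of adjacent genotypes may share a fitness
value (no strictly neutral mutations).  Every downstream quantity (peaks,
reciprocal-sign-epistasis instances, the Morse graph) is defined only on
strict landscapes; :func:`break_neutrality` repairs a non-strict landscape
with an arbitrarily small seeded perturbation that preserves every existing
strict fitness comparison.
"""

from __future__ import annotations

import io
import itertools
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO, Union

import numpy as np
import pandas as pd

__all__ = [
    "ENUMERATION_CAP",
    "LandscapeError",
    "NeutralityError",
    "SpaceTooLargeError",
    "TheoremViolationError",
    "GenotypeSpace",
    "FitnessLandscape",
    "NeutralPair",
    "hamming",
    "neighbors",
    "hypercube_edges",
    "validate_no_neutral",
    "break_neutrality",
    "load_landscape",
    "write_landscape",
    "landscape_to_json",
    "landscape_from_json",
]

#: Default refusal threshold for exhaustive whole-space operations.
ENUMERATION_CAP = 2**22


class LandscapeError(ValueError):
    """Invalid landscape data or an operation precondition violation."""


class NeutralityError(LandscapeError):
    """A strictly neutral mutation was found where strictness is required."""


class SpaceTooLargeError(LandscapeError):
    """The genotype space exceeds the exhaustive-enumeration cap."""


class TheoremViolationError(RuntimeError):
    """Internal tripwire: a provably-true invariant failed, signalling a bug."""


@dataclass(frozen=True)
class GenotypeSpace:
    """A product space of per-locus alphabets.

    Parameters
    ----------
    alphabets
        One string per locus giving that locus's allowed symbols in sorted
        order, e.g. ``("01", "01", "01")`` for the binary 3-cube or
        ``("01", "012")`` for a 2-locus space with a tri-allelic second
        locus.
    """

    alphabets: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alphabets) < 1:
            raise LandscapeError("a genotype space needs at least one locus")
        for i, a in enumerate(self.alphabets):
            if len(a) < 2:
                raise LandscapeError(
                    f"locus {i}: alphabet {a!r} has fewer than 2 symbols"
                )
            if len(set(a)) != len(a) or "".join(sorted(a)) != a:
                raise LandscapeError(
                    f"locus {i}: alphabet {a!r} must be sorted and duplicate-free"
                )

    @classmethod
    def binary(cls, n_loci: int) -> "GenotypeSpace":
        """The binary hypercube {0,1}^n."""
        if n_loci < 1:
            raise LandscapeError("n_loci must be >= 1")
        return cls(("01",) * n_loci)

    @property
    def n_loci(self) -> int:
        return len(self.alphabets)

    @property
    def alphabet_sizes(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.alphabets)

    @property
    def size(self) -> int:
        return math.prod(self.alphabet_sizes)

    @property
    def degree(self) -> int:
        """Number of single-mutation neighbors of any genotype."""
        return sum(len(a) - 1 for a in self.alphabets)

    def check_cap(self, cap: int = ENUMERATION_CAP) -> None:
        if self.size > cap:
            raise SpaceTooLargeError(
                f"space has {self.size} genotypes, exceeding the cap of {cap}"
            )

    def __contains__(self, genotype: object) -> bool:
        if not isinstance(genotype, str) or len(genotype) != self.n_loci:
            return False
        return all(s in a for s, a in zip(genotype, self.alphabets))

    def genotypes(self) -> Iterator[str]:
        """All genotypes in lexicographic order."""
        for tup in itertools.product(*self.alphabets):
            yield "".join(tup)


def hamming(u: str, v: str) -> int:
    """Number of loci at which two equal-length genotypes differ."""
    if len(u) != len(v):
        raise LandscapeError(f"length mismatch: {u!r} vs {v!r}")
    return sum(a != b for a, b in zip(u, v))


def neighbors(space: GenotypeSpace, genotype: str) -> list[str]:
    """All genotypes at Hamming distance 1 from ``genotype``.

    Order is deterministic: locus-major, then symbol-sorted within a locus.
    """
    if genotype not in space:
        raise LandscapeError(f"genotype {genotype!r} not in space")
    out: list[str] = []
    for i, alphabet in enumerate(space.alphabets):
        for s in alphabet:
            if s != genotype[i]:
                out.append(genotype[:i] + s + genotype[i + 1 :])
    return out


def hypercube_edges(space: GenotypeSpace) -> Iterator[tuple[str, str]]:
    """All unordered single-mutation pairs, as (u, v) with u < v."""
    for g in space.genotypes():
        for h in neighbors(space, g):
            if g < h:
                yield (g, h)


@dataclass(frozen=True)
class NeutralPair:
    """A strictly neutral mutation: adjacent genotypes of equal fitness."""

    u: str
    v: str
    fitness: float


@dataclass
class FitnessLandscape:
    """A total fitness map over a genotype space.

    Attributes
    ----------
    space
        The underlying :class:`GenotypeSpace`.
    fitness
        Mapping genotype -> finite real fitness; total on the space.
    strict
        True once the no-neutral-neighbor check has passed.  Operations that
        require strictness (peak finding, RSE enumeration, the Morse
        construction) refuse non-strict landscapes.
    """

    space: GenotypeSpace
    fitness: dict[str, float]
    strict: bool = False

    def __post_init__(self) -> None:
        expected = self.space.size
        if len(self.fitness) != expected:
            missing = [g for g in self.space.genotypes() if g not in self.fitness]
            raise LandscapeError(
                f"landscape not total: {len(self.fitness)} of {expected} genotypes; "
                f"first missing: {missing[:5]}"
            )
        for g, w in self.fitness.items():
            if g not in self.space:
                raise LandscapeError(f"genotype {g!r} not in space")
            if not math.isfinite(w):
                raise LandscapeError(f"non-finite fitness for {g!r}: {w}")

    def __getitem__(self, genotype: str) -> float:
        return self.fitness[genotype]

    @property
    def n_genotypes(self) -> int:
        return self.space.size

    def genotypes(self) -> Iterator[str]:
        return self.space.genotypes()

    def max_abs_fitness(self) -> float:
        return max(abs(w) for w in self.fitness.values())

    def is_integral(self) -> bool:
        return all(float(w).is_integer() for w in self.fitness.values())


def validate_no_neutral(landscape: FitnessLandscape) -> list[NeutralPair]:
    """Find every adjacent pair with exactly equal fitness.

    Returns the (possibly empty) list of violations and records the result
    in ``landscape.strict``.  An empty list certifies the no-neutral-mutation
    hypothesis that the peak/RSE bound requires.
    """
    violations = [
        NeutralPair(u, v, landscape.fitness[u])
        for u, v in hypercube_edges(landscape.space)
        if landscape.fitness[u] == landscape.fitness[v]
    ]
    landscape.strict = not violations
    return violations


def _min_nonzero_gap(values: Iterable[float]) -> float:
    distinct = sorted(set(values))
    if len(distinct) < 2:
        return math.inf
    return min(b - a for a, b in zip(distinct, distinct[1:]))


def break_neutrality(
    landscape: FitnessLandscape, epsilon: float, seed: int
) -> FitnessLandscape:
    """Lift fitness ties with a small seeded jitter, preserving all strict orderings.

    Each genotype receives an independent uniform(0, epsilon) addition.  Because
    ``epsilon`` must be smaller than half the smallest nonzero fitness gap,
    every strict inequality ``W(a) < W(b)`` of the input survives, so peak
    sets and RSE sets of already-strict comparisons are unchanged.  The same
    seed reproduces the same output exactly.
    """
    if epsilon <= 0:
        raise LandscapeError("epsilon must be > 0")
    gap = _min_nonzero_gap(landscape.fitness.values())
    if not (epsilon < gap / 2):
        raise LandscapeError(
            f"epsilon={epsilon} too large: must be < half the minimum nonzero "
            f"fitness gap ({gap})"
        )
    order = list(landscape.space.genotypes())
    attempt_seed = seed
    for _ in range(16):  # ties after jitter are measure-zero; retry advances the seed
        rng = np.random.default_rng(attempt_seed)
        jitter = rng.uniform(0.0, epsilon, size=len(order))
        # strict open interval (0, epsilon): redraw exact zeros, vanishing probability
        while np.any(jitter == 0.0):
            jitter[jitter == 0.0] = rng.uniform(0.0, epsilon, size=int((jitter == 0.0).sum()))
        new_fitness = {g: landscape.fitness[g] + j for g, j in zip(order, jitter)}
        out = FitnessLandscape(landscape.space, new_fitness, strict=False)
        if not validate_no_neutral(out):
            return out
        attempt_seed += 1
    raise TheoremViolationError(
        "break_neutrality failed to produce a strict landscape after 16 attempts"
    )


# ---------------------------------------------------------------------------
# I/O: genotype-fitness tables (TSV/CSV) and JSON
# ---------------------------------------------------------------------------


def _infer_space(genotypes: list[str]) -> GenotypeSpace:
    lengths = {len(g) for g in genotypes}
    if len(lengths) != 1:
        raise LandscapeError(f"ragged genotype lengths: {sorted(lengths)}")
    n = lengths.pop()
    alphabets = []
    for i in range(n):
        symbols = "".join(sorted({g[i] for g in genotypes}))
        if len(symbols) < 2:
            raise LandscapeError(
                f"locus {i} is constant (only symbol {symbols!r} observed); "
                "declare the space explicitly if this is intended"
            )
        alphabets.append(symbols)
    return GenotypeSpace(tuple(alphabets))


def load_landscape(
    source: Union[str, os.PathLike, TextIO],
    delimiter: str = "\t",
    space: GenotypeSpace | None = None,
) -> FitnessLandscape:
    """Read a genotype→fitness table into a landscape.

    The table has two columns (genotype string, numeric fitness), with an
    optional header row.  The space is inferred from the observed symbols at
    each locus unless ``space`` is given explicitly.  Totality is enforced;
    duplicate rows are accepted only when their fitness values agree.  The
    strictness flag is set by running the neutrality check.
    """
    df = pd.read_csv(source, sep=delimiter, header=None, dtype=str,
                     comment=None, skip_blank_lines=True)
    if df.shape[1] != 2:
        raise LandscapeError(f"expected 2 columns, found {df.shape[1]}")
    df.columns = ["genotype", "fitness"]
    # optional header: first row whose fitness field is non-numeric
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
        if df.empty:
            raise LandscapeError("table contains a header but no data rows")
    try:
        values = df["fitness"].astype(float)
    except ValueError as exc:
        raise LandscapeError(f"non-numeric fitness value: {exc}") from exc
    fitness: dict[str, float] = {}
    for g, w in zip(df["genotype"], values):
        g = str(g)
        if g in fitness:
            if fitness[g] != w:
                raise LandscapeError(
                    f"duplicate genotype {g!r} with conflicting fitness "
                    f"({fitness[g]} vs {w})"
                )
            continue
        fitness[g] = float(w)
    if space is None:
        space = _infer_space(list(fitness))
    landscape = FitnessLandscape(space, fitness, strict=False)
    validate_no_neutral(landscape)
    return landscape


def write_landscape(
    landscape: FitnessLandscape,
    destination: Union[str, os.PathLike, TextIO],
    delimiter: str = "\t",
) -> None:
    """Write the landscape as a two-column table in lexicographic genotype order."""

    def _emit(fh: TextIO) -> None:
        fh.write(f"genotype{delimiter}fitness\n")
        for g in landscape.space.genotypes():
            fh.write(f"{g}{delimiter}{landscape.fitness[g]!r}\n")

    if hasattr(destination, "write"):
        _emit(destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            _emit(fh)


def landscape_to_json(landscape: FitnessLandscape) -> str:
    obj = {
        "n_loci": landscape.space.n_loci,
        "alphabet_sizes": list(landscape.space.alphabet_sizes),
        "alphabets": list(landscape.space.alphabets),
        "fitness": {g: landscape.fitness[g] for g in landscape.space.genotypes()},
    }
    return json.dumps(obj, indent=1)


def landscape_from_json(text: str) -> FitnessLandscape:
    obj = json.loads(text)
    space = GenotypeSpace(tuple(obj["alphabets"]))
    landscape = FitnessLandscape(space, {g: float(w) for g, w in obj["fitness"].items()})
    validate_no_neutral(landscape)
    return landscape
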