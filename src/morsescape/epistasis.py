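"""Peaks, 2-faces (squares), epistasis classification, and RSE enumeration.

A *square* is the 2-face of the genotype space obtained by fixing all loci
but two and choosing two alleles at each of the free loci.  On a square,
pairwise epistasis between the two free loci is read off from the fitness
effects of each allele swap on the two backgrounds provided by the other
locus: no epistasis (effects identical), magnitude epistasis (same signs,
different sizes), sign epistasis (one locus's effect flips sign), or
reciprocal sign epistasis (both flip).  A *reciprocal-sign-epistasis (RSE)
instance* is a square in which one diagonal pair of corners is strictly
fitter than both corners of the other diagonal — the local motif that any
multi-peaked landscape must contain.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterator

from .core import (
    ENUMERATION_CAP,
    FitnessLandscape,
    GenotypeSpace,
    LandscapeError,
    NeutralityError,
    neighbors,
)

__all__ = [
    "Square",
    "RSEInstance",
    "EpistasisClass",
    "find_peaks",
    "enumerate_squares",
    "classify_square",
    "enumerate_rse",
]


class EpistasisClass(enum.Enum):
    """Pairwise epistasis type of one square."""

    NONE = "none"
    MAGNITUDE = "magnitude"
    SIGN = "sign"
    RECIPROCAL_SIGN = "reciprocal_sign"
    #: some single-mutation effect on the square is exactly zero; the sign
    #: trichotomy is undefined and strict pipelines never encounter this.
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class Square:
    """One 2-face of the genotype space.

    Corners are laid out so that ``(corner_aa, corner_bb)`` and
    ``(corner_ab, corner_ba)`` are the two diagonals: ``corner_aa`` carries
    allele ``a`` at both free loci, ``corner_bb`` allele ``b`` at both, and
    the two mixed corners are their common single-mutation neighbors.
    """

    locus_pair: tuple[int, int]  # (i, j) with i < j
    background: str  # symbols at all loci except i and j, in locus order
    alleles_i: tuple[str, str]  # two distinct sorted symbols at locus i
    alleles_j: tuple[str, str]
    corner_aa: str
    corner_ab: str
    corner_ba: str
    corner_bb: str

    @property
    def corners(self) -> tuple[str, str, str, str]:
        return (self.corner_aa, self.corner_ab, self.corner_ba, self.corner_bb)

    @property
    def diagonals(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return ((self.corner_aa, self.corner_bb), (self.corner_ab, self.corner_ba))


@dataclass(frozen=True)
class RSEInstance:
    """A square whose ``high_diagonal`` strictly dominates the other diagonal:
    max(W(low)) < min(W(high))."""

    square: Square
    high_diagonal: tuple[str, str]
    low_diagonal: tuple[str, str]


def find_peaks(landscape: FitnessLandscape) -> set[str]:
    """Strict local maxima: genotypes fitter than every single-mutation neighbor.

    Requires a strict landscape (ties with a neighbor would make the notion
    ambiguous).  Never empty: the global maximum always qualifies.
    """
    if not landscape.strict:
        raise NeutralityError("find_peaks requires a strict landscape")
    W = landscape.fitness
    return {
        g
        for g in landscape.space.genotypes()
        if all(W[h] < W[g] for h in neighbors(landscape.space, g))
    }


def enumerate_squares(space: GenotypeSpace, cap: int = ENUMERATION_CAP) -> Iterator[Square]:
    """Yield every 2-face exactly once, in deterministic order.

    Order: locus pairs (i<j) lexicographic, then background lexicographic,
    then sorted allele pairs at locus i, then at locus j.  The total count is
    sum over i<j of C(a_i,2)*C(a_j,2)*prod of the remaining alphabet sizes.
    """
    space.check_cap(cap)
    n = space.n_loci
    for i, j in itertools.combinations(range(n), 2):
        other_loci = [k for k in range(n) if k not in (i, j)]
        other_alphabets = [space.alphabets[k] for k in other_loci]
        for bg in itertools.product(*other_alphabets):
            for a_i, b_i in itertools.combinations(space.alphabets[i], 2):
                for a_j, b_j in itertools.combinations(space.alphabets[j], 2):
                    symbols = [""] * n
                    for k, s in zip(other_loci, bg):
                        symbols[k] = s

                    def corner(si: str, sj: str) -> str:
                        symbols[i], symbols[j] = si, sj
                        return "".join(symbols)

                    yield Square(
                        locus_pair=(i, j),
                        background="".join(bg),
                        alleles_i=(a_i, b_i),
                        alleles_j=(a_j, b_j),
                        corner_aa=corner(a_i, a_j),
                        corner_ab=corner(a_i, b_j),
                        corner_ba=corner(b_i, a_j),
                        corner_bb=corner(b_i, b_j),
                    )


def classify_square(landscape: FitnessLandscape, square: Square) -> EpistasisClass:
    """Classify the pairwise epistasis type of one square.

    The locus-i allele swap has one fitness effect on each locus-j
    background, and vice versa.  Identical effects at both loci mean no
    epistasis; preserved signs with changed magnitude mean magnitude
    epistasis; a sign flip at exactly one locus is sign epistasis; flips at
    both are reciprocal sign epistasis.  Any exactly-zero single-edge effect
    is reported as degenerate rather than forced into the trichotomy.
    """
    W = landscape.fitness
    try:
        w_aa, w_ab = W[square.corner_aa], W[square.corner_ab]
        w_ba, w_bb = W[square.corner_ba], W[square.corner_bb]
    except KeyError as exc:
        raise LandscapeError(f"square corner {exc} not in landscape") from exc
    # effect of the locus-i swap a->b on each locus-j background, and conversely
    eff_i = (w_ba - w_aa, w_bb - w_ab)
    eff_j = (w_ab - w_aa, w_bb - w_ba)
    if any(e == 0 for e in eff_i + eff_j):
        return EpistasisClass.DEGENERATE
    flips_i = (eff_i[0] > 0) != (eff_i[1] > 0)
    flips_j = (eff_j[0] > 0) != (eff_j[1] > 0)
    if flips_i and flips_j:
        return EpistasisClass.RECIPROCAL_SIGN
    if flips_i or flips_j:
        return EpistasisClass.SIGN
    if eff_i[0] == eff_i[1] and eff_j[0] == eff_j[1]:
        return EpistasisClass.NONE
    return EpistasisClass.MAGNITUDE


def _rse_from_square(landscape: FitnessLandscape, square: Square) -> RSEInstance | None:
    W = landscape.fitness
    d1, d2 = square.diagonals
    for high, low in ((d1, d2), (d2, d1)):
        if max(W[low[0]], W[low[1]]) < min(W[high[0]], W[high[1]]):
            return RSEInstance(square=square, high_diagonal=high, low_diagonal=low)
    return None


def enumerate_rse(landscape: FitnessLandscape) -> list[RSEInstance]:
    """All RSE instances of a strict landscape, in square-enumeration order.

    At most one instance arises per square: diagonal dominance can hold in
    only one orientation.
    """
    if not landscape.strict:
        raise NeutralityError("enumerate_rse requires a strict landscape")
    out = []
    for square in enumerate_squares(landscape.space):
        inst = _rse_from_square(landscape, square)
        if inst is not None:
            out.append(inst)
    return out


def rse_report(landscape: FitnessLandscape) -> dict:
    """JSON-ready summary of peaks and RSE instances."""
    peaks = sorted(find_peaks(landscape))
    instances = enumerate_rse(landscape)
    return {
        "n_peaks": len(peaks),
        "peaks": peaks,
        "n_rse": len(instances),
        "rse": [
            {
                "corners": {
                    "high": list(inst.high_diagonal),
                    "low": list(inst.low_diagonal),
                },
                "loci": list(inst.square.locus_pair),
                "background": inst.square.background,
            }
            for inst in instances
        ],
    }
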