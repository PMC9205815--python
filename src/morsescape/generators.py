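"""Random-landscape models and in-package fixtures.

Four standard nulls spanning the smooth-to-rugged spectrum:

* **additive** — independent per-locus effects; no epistasis, a single
  peak, and no RSE anywhere.  The smooth extreme.
* **house of cards (HoC)** — i.i.d. uniform fitness per genotype; maximal
  ruggedness, the classical null for peak counts.
* **rough Mount Fuji (RMF)** — an additive slope toward a reference
  genotype plus i.i.d. Gaussian noise; interpolates between the two
  extremes as noise/slope varies.
* **NK** — each locus contributes a random table value depending on itself
  and its k successors on a circle (contributions averaged); k tunes
  ruggedness from additive-like (k=0) to HoC-like (k=n-1).

Continuous models produce strictly neutral ties only on a measure-zero
event; if one occurs the draw is regenerated with an advanced seed so the
strictness contract always holds.  Identical parameters and seed give a
byte-identical landscape.

The ``fixture`` loader provides the small worked examples used throughout
the docs and tests: the 3-cube table with three peaks and three RSE
instances (``example1``), the two-locus RSE square (``intro_rse``), and the
two-locus sign-epistasis square with a neutral edge (``intro_sign``).
"""

from __future__ import annotations

import numpy as np

from .core import (
    ENUMERATION_CAP,
    FitnessLandscape,
    GenotypeSpace,
    LandscapeError,
    TheoremViolationError,
    hamming,
    validate_no_neutral,
)

__all__ = [
    "additive_landscape",
    "house_of_cards",
    "rough_mount_fuji",
    "nk_landscape",
    "fixture",
    "FIXTURES",
]

_MAX_REGENERATIONS = 16


def _finalize_random(
    make: "callable", seed: int, require_strict: bool = True
) -> FitnessLandscape:
    """Build a random landscape, regenerating on measure-zero neutral ties."""
    attempt = seed
    for _ in range(_MAX_REGENERATIONS):
        landscape = make(np.random.default_rng(attempt))
        if not require_strict or not validate_no_neutral(landscape):
            return landscape
        attempt += 1
    raise TheoremViolationError(
        "random generator repeatedly produced neutral ties — "
        "this has probability ~0 and signals a bug"
    )


def additive_landscape(n: int, effects: list[float]) -> FitnessLandscape:
    """Additive landscape W(g) = sum of effects[i] over loci carrying allele '1'.

    All effects must be nonzero (a zero effect would create neutral
    neighbor pairs).  The result is strict, has exactly one peak — the
    genotype carrying allele '1' precisely at the positive-effect loci —
    and contains no RSE instance.
    """
    if len(effects) != n:
        raise LandscapeError(f"need {n} effects, got {len(effects)}")
    if any(e == 0 for e in effects):
        raise LandscapeError("zero effects are disallowed (they create neutrality)")
    space = GenotypeSpace.binary(n)
    fitness = {
        g: sum(e for s, e in zip(g, effects) if s == "1") for g in space.genotypes()
    }
    landscape = FitnessLandscape(space, fitness)
    validate_no_neutral(landscape)
    if not landscape.strict:
        # possible for adversarial effect combinations summing to zero
        raise LandscapeError(
            "effects produce neutral neighbor pairs; perturb them slightly"
        )
    return landscape


def house_of_cards(n: int, seed: int) -> FitnessLandscape:
    """i.i.d. uniform(0,1) fitness per genotype (maximal-ruggedness null)."""
    space = GenotypeSpace.binary(n)
    space.check_cap(ENUMERATION_CAP)
    order = list(space.genotypes())

    def make(rng: np.random.Generator) -> FitnessLandscape:
        values = rng.uniform(0.0, 1.0, size=len(order))
        return FitnessLandscape(space, dict(zip(order, map(float, values))))

    return _finalize_random(make, seed)


def rough_mount_fuji(
    n: int, slope: float, noise_scale: float, seed: int
) -> FitnessLandscape:
    """Additive slope toward the all-'1' reference genotype plus Gaussian noise.

    ``W(g) = -slope * d(g, 1...1) + eps_g`` with ``eps_g`` i.i.d. centered
    Gaussian of scale ``noise_scale``.  ``noise_scale = 0`` recovers a
    smooth single-peak landscape (requires ``slope != 0`` for strictness);
    ``slope = 0`` behaves like a house-of-cards draw.
    """
    if noise_scale < 0:
        raise LandscapeError("noise_scale must be >= 0")
    if noise_scale == 0 and slope == 0:
        raise LandscapeError("slope and noise_scale cannot both be zero (flat landscape)")
    space = GenotypeSpace.binary(n)
    space.check_cap(ENUMERATION_CAP)
    order = list(space.genotypes())
    reference = "1" * n
    base = {g: -slope * hamming(g, reference) for g in order}

    def make(rng: np.random.Generator) -> FitnessLandscape:
        eps = (
            rng.normal(0.0, noise_scale, size=len(order))
            if noise_scale > 0
            else np.zeros(len(order))
        )
        return FitnessLandscape(
            space, {g: float(base[g] + e) for g, e in zip(order, eps)}
        )

    return _finalize_random(make, seed)


def nk_landscape(n: int, k: int, seed: int) -> FitnessLandscape:
    """NK model with circular neighborhoods and mean-of-contributions fitness.

    Locus i's contribution is a uniform(0,1) table value indexed by the
    alleles at loci i, i+1, ..., i+k (mod n); W is the mean over loci.
    k=0 is additive-like (single peak); k=n-1 makes every contribution
    depend on the whole genotype (house-of-cards-like ruggedness).
    """
    if not (0 <= k <= n - 1):
        raise LandscapeError(f"k must satisfy 0 <= k <= n-1, got k={k}, n={n}")
    space = GenotypeSpace.binary(n)
    space.check_cap(ENUMERATION_CAP)
    order = list(space.genotypes())
    hoods = [[(i + j) % n for j in range(k + 1)] for i in range(n)]

    def make(rng: np.random.Generator) -> FitnessLandscape:
        tables = rng.uniform(0.0, 1.0, size=(n, 2 ** (k + 1)))
        fitness = {}
        for g in order:
            total = 0.0
            for i, hood in enumerate(hoods):
                idx = 0
                for locus in hood:
                    idx = (idx << 1) | (g[locus] == "1")
                total += tables[i, idx]
            fitness[g] = total / n
        return FitnessLandscape(space, fitness)

    return _finalize_random(make, seed)


#: Worked-example landscapes: genotype -> fitness tables.
FIXTURES: dict[str, dict[str, float]] = {
    # 3-cube with peaks {100, 001, 111} and three RSE instances
    "example1": {
        "000": 0.0,
        "100": 3.0,
        "010": 1.0,
        "001": 3.0,
        "110": 2.0,
        "101": 2.0,
        "111": 3.0,
        "011": 2.0,
    },
    # two-locus reciprocal sign epistasis, peaks {00, 11}
    "intro_rse": {"00": 1.0, "01": -1.0, "10": -1.0, "11": 1.0},
    # two-locus (single) sign epistasis; the 10-11 edge is neutral, so this
    # fixture is non-strict and needs break_neutrality before analysis
    "intro_sign": {"00": 1.0, "01": -1.0, "10": 1.0, "11": 1.0},
}


def fixture(name: str) -> FitnessLandscape:
    """Load one of the packaged worked-example landscapes by name."""
    try:
        table = FIXTURES[name]
    except KeyError:
        raise LandscapeError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    n = len(next(iter(table)))
    landscape = FitnessLandscape(GenotypeSpace.binary(n), dict(table))
    validate_no_neutral(landscape)
    return landscape
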