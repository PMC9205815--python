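# Methods

## Model and scope

A landscape is a total map `W : S → R` on a product space
`S = A_1 × … × A_n` of per-locus alphabets (all `A_i = {0,1}` in the binary
case). Genotypes are fixed-length strings, loci ordered left to right;
single mutations are Hamming-distance-1 steps. Everything the package
computes is exhaustive over the space, so whole-space operations refuse
spaces larger than 2^22 genotypes (configurable via the `cap` arguments).

The central hypothesis is **strictness**: no two adjacent genotypes share a
fitness value. Peaks (strict local maxima) and RSE instances are only
well-defined under it, so `find_peaks`, `enumerate_rse`, the Morse
construction and the certificates all refuse non-strict input.
`validate_no_neutral` returns the complete list of neutral neighbor pairs
as witnesses; `break_neutrality(landscape, epsilon, seed)` adds an
independent uniform(0, ε) offset per genotype. Requiring
`epsilon < gap/2`, where `gap` is the smallest nonzero difference between
any two fitness values in the table, guarantees that every pre-existing
strict comparison — hence every peak and every RSE instance already implied
by strict comparisons — survives the jitter. Ties after jitter are a
measure-zero event; if one occurs the draw is repeated with the seed
advanced by one (bounded retries, then a hard error).

## Squares, epistasis classes, RSE

A square fixes two loci `i < j`, two alleles at each, and a background at
the remaining loci; its four corners split into two diagonals. For
classification, the allele swap at locus `i` has one fitness effect per
locus-`j` background (and symmetrically): identical effects at both loci →
`none`; signs preserved, magnitudes not → `magnitude`; a sign flip at
exactly one locus → `sign`; flips at both → `reciprocal_sign`. An
exactly-zero edge effect gets a fifth label, `degenerate`, rather than a
forced call — the trichotomy is undefined at zero, and strict pipelines
never see the label. On strict squares, `reciprocal_sign` coincides exactly
with the diagonal-dominance test `max(W(low)) < min(W(high))` used by
`enumerate_rse`; the test suite checks the equivalence exhaustively over
all 4! orderings of a square and against brute-force oracles on random
landscapes.

Multi-allele spaces use the allelic notion of a square (two chosen alleles
per locus), under which the peak bound carries over unchanged; the
per-locus-pair instance counts simply acquire binomial multiplicities.

## The Morse construction

Given a strict landscape:

* `E1`: every non-peak genotype contributes one edge to its maximum-fitness
  neighbor. Distinct neighbors may tie in fitness (they are distance 2
  apart, so strictness does not forbid it); any choice is valid for the
  theory, and for reproducibility the default policy picks the
  lexicographically smallest candidate (`tie_break="lex"`; `"lex_last"` is
  provided to demonstrate that all reported counts are policy-invariant —
  only the edge set itself can differ).
* `E2`: one distance-2 edge per RSE instance, joining its high diagonal.
  `E2` is derived from the RSE enumeration (they are in bijection); an
  independent scan of all distance-2 pairs is kept in the test suite as an
  oracle.
* `f`: `−W` on vertices; on an E1 edge the midpoint of its endpoint values
  (strictly between them, by strictness); on every E2 edge the constant
  `C`. Default `C = floor(max|W|) + 1` when all fitness values are
  integral, else `max|W| + 1` — the smallest convenient value satisfying
  the required `C > max|W|` (the worked example gets `C = 4`).

With this `f`, a vertex is critical (all incident edges carry larger `f`)
iff it is a peak, and an edge is critical (larger `f` than both endpoints)
iff it lies in `E2`; `critical_cells` evaluates the definitions directly
rather than assuming this, and the test suite asserts the coincidence.
Betti numbers come from the component count of `E1 ∪ E2` (networkx) plus
the cyclomatic formula `b1 = |E| + b0 − |V|`. The graph is provably
connected and the bound `n_rse ≥ n_peaks − 1` provably true, so
`assert_connected` and `analyze` treat their failure as an internal error
(`TheoremViolationError`, CLI exit code 4) — a tripwire that converts any
enumeration bug into a loud failure, never a silent "result".

Accounting identities that hold for every constructed graph, asserted per
run in the property tests: `|E1| = |V| − n_peaks`, `m0 = n_peaks`,
`m1 = n_rse`, `b0 = 1`, and `m1 − m0 = b1 − b0` (the strong Morse
inequality met with equality), whence `bound_slack = b1 ≥ 0`.

## Bottleneck certificates

`max_bottleneck_path` maximizes, over all single-mutation paths between two
genotypes, the minimum fitness along the path. The implementation descends
through the sorted distinct fitness values and runs a breadth-first search
on the subgraph induced by genotypes at or above the threshold; the first
threshold that connects the endpoints is optimal, and the BFS (expanding
neighbors in canonical locus-major order) returns a deterministic shortest
optimal path. Complexity is O(#distinct values · |V| · degree), ample at
desk scale. The certificate records the path, its minimum-fitness vertex
(first occurrence on ties) and the bottleneck value; a brute-force maximin
over all simple paths serves as the test oracle on 3- and 4-cubes.
`rse_existence_witness` returns the first RSE instance in enumeration order
whenever the landscape has ≥ 2 peaks (guaranteed to exist; its absence
trips the internal-error wire) and `None` for single-peak landscapes.

## Random models

The generators are standard nulls spanning smooth to maximally rugged;
identical parameters and seed give byte-identical landscapes (numpy
`default_rng`).

| model | fitness | parameters / defaults |
|---|---|---|
| additive | `Σ_i e_i · [g_i = 1]` | nonzero effects, one per locus |
| house of cards | i.i.d. uniform(0,1) per genotype | n, seed |
| rough Mount Fuji | `−slope · d(g, 1…1) + N(0, noise²)` | slope, noise scale |
| NK | mean over loci of uniform(0,1) tables on locus + k circular successors | 0 ≤ k ≤ n−1 |

Conventions fixed once: NK neighborhoods are circular and contributions are
averaged (not summed); the RMF reference genotype is all-`1`. Continuous
models regenerate with an advanced seed on the measure-zero event of a
neutral tie, preserving the strictness contract without materially biasing
the ensembles.

What these ensembles do and do not show: they exercise every landscape
topology the theory speaks to (single-peak smooth through HoC-maximal
ruggedness) and so give the bound and the construction identities a broad
adversarial sweep; they do not emulate measurement noise, missing
genotypes, or the correlated fitness structure of real mutational-scan
data, so passing tests certify the combinatorics, not data-cleaning
behavior. Real tables with exact ties must go through `break_neutrality`
explicitly.

## Problem sizes and numerical choices

The test suite and the acceptance script run exhaustively at desk scale:
binary n ≤ 8 (≤ 256 genotypes) for oracle comparisons, a 1,000-landscape
ensemble (HoC n = 4–8, NK n = 6, RMF n = 6) for the bound sweep — the full
suite completes in well under a minute. All fitness comparisons are exact
floating-point comparisons; no tolerance is applied anywhere, which is
correct here because strictness is validated on exactly the same values the
enumerations compare, and generated fitnesses are either exact table values
or single arithmetic expressions.

## Known limitations

* Exhaustive algorithms only; no sampling mode for spaces beyond the cap.
* Peaks are strict local maxima — plateau/neutral-network analysis is out
  of scope (the strictness contract excludes plateaus by construction).
* Only graph-level Morse theory (b0, b1, vertex/edge criticality); no
  higher-dimensional complexes or gradient vector fields.
* The degenerate epistasis label records zero-effect squares without
  interpreting them.
* Locus-level (as opposed to allelic) multi-allele epistasis definitions
  are not implemented; the bound is not guaranteed under them.
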