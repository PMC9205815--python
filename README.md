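# morsescape

Ruggedness analysis of fitness landscapes on genotype hypercubes: peak
enumeration, reciprocal sign epistasis (RSE) detection, and a discrete-Morse
certificate that ties the two together.

## The problem

A fitness landscape assigns a real fitness `W(g)` to every genotype `g` of a
combinatorial space — binary strings `{0,1}^n`, or multi-allelic strings with
a small alphabet per locus. Experimentalists doing deep mutational scans want
to know how *rugged* such a landscape is: how many local fitness peaks it
has, and what local interaction structure makes multiple peaks possible. The
answer is pairwise **reciprocal sign epistasis**: a 2-face (square) of the
space on which one diagonal pair of genotypes is strictly fitter than both
genotypes of the other diagonal. For any landscape with no strictly neutral
single mutations,

```
#RSE instances  ≥  #peaks − 1 ,
```

so an observed peak count puts a floor under the number of reciprocal
sign-epistatic interactions hiding in the data. `morsescape` enumerates both
sides of this inequality exactly, and also builds the graph-theoretic
construction behind it:

* a graph `G = (V, E1 ∪ E2)` on all genotypes, where `E1` holds one edge
  from each non-peak genotype to a fittest better neighbor (a steepest-ascent
  step) and `E2` joins the high diagonal of every RSE instance;
* a discrete Morse function `f` (`−W` on vertices, endpoint midpoints on E1
  edges, a large constant `C > max|W|` on E2 edges);
* Betti numbers `b0` (components) and `b1 = |E| + b0 − |V|` (independent
  cycles), and critical-cell counts `m0`, `m1`. For this construction the
  critical vertices are exactly the peaks, the critical edges exactly `E2`,
  `G` is connected, and the strong Morse inequality `m1 − m0 ≥ b1 − b0`
  holds with equality — which is precisely the bound above.

The package also provides maximum-bottleneck ("widest") path certificates
between peaks — the single-mutation path whose minimum fitness is as high as
possible — and random-landscape generators (additive, house of cards, rough
Mount Fuji, NK) for ensemble stress-testing.

## Worked example

The packaged `example1` landscape is a 3-cube with three peaks:

| g | 000 | 100 | 010 | 001 | 110 | 101 | 111 | 011 |
|---|-----|-----|-----|-----|-----|-----|-----|-----|
| W |  0  |  3  |  1  |  3  |  2  |  2  |  3  |  2  |

```sh
morsescape generate --model fixture --name example1 -o example1.tsv
morsescape analyze example1.tsv
```

prints

```json
{
 "n_peaks": 3,
 "n_rse": 3,
 "b0": 1,
 "b1": 1,
 "m0": 3,
 "m1": 3,
 "morse_slack": 0,
 "bound_slack": 1,
 "bound_holds": true,
 "tie_break": "lex",
 "C": 4.0
}
```

Reading: the cube has 3 peaks (100, 001, 111) and 3 RSE instances (the three
squares whose high diagonals pair up those peaks). The Morse graph is
connected (`b0 = 1`) with one independent cycle (`b1 = 1`); its 3 critical
vertices are the peaks and its 3 critical edges the RSE diagonals, so the
strong Morse inequality is met with equality (`morse_slack = 0`) and the
peak bound holds with one instance to spare (`bound_slack = 3 − (3−1) = 1`).

Bottleneck certificates between the peaks:

```sh
morsescape certify example1.tsv
```

reports, for each of the three peak pairs, an optimal ridge path and its
valley floor — e.g. from `001` to `100` via `101`, with
`bottleneck_value = 2.0`: no single-mutation path between those peaks can
stay above fitness 2.

The same analyses are available as library calls (`morsescape.analyze`,
`morsescape.max_bottleneck_path`, …) on a `FitnessLandscape` loaded with
`morsescape.load_landscape` or built by a generator. Landscapes with neutral
ties are refused by default; `break_neutrality` (CLI: `--permissive
--epsilon E --seed S`) lifts ties with a seeded jitter smaller than any real
fitness difference.

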