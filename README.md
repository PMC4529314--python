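# fluxspace

Exhaustive genotype–phenotype mapping of metabolic reaction networks.

A metabolic **genotype** is a presence/absence pattern over a fixed
universe of internal biochemical reactions — a point in a hypercube with
2^N corners. Its **phenotype** is the set of carbon sources on which flux
balance analysis (FBA) predicts viable growth: the genotype is viable in an
environment when the linear-programming optimum of its biomass flux exceeds
1 % of the full universe's optimum there. `fluxspace` builds such
universes, phenotypes genotypes by LP, enumerates complete viable sets
exhaustively with monotone pruning, and analyses the resulting **genotype
networks**: same-size viable genotypes connected by single reaction swaps.
Questions it answers include how large and connected these networks are,
how far apart the networks of different carbon-usage phenotypes sit, and
whether distant regions of a network open up different evolutionary
innovations (different novel phenotypes in their mutational neighborhoods).

The package ships two models:

- a curated **central-carbon-metabolism universe** (51 internal reactions,
  ten single-carbon-source environments, derived from the published
  *E. coli* core reconstruction; see `docs/methods.md` and
  `scripts/build_ccm_fixture.py` for provenance), and
- a **synthetic generator** of layered directed-acyclic universes on which
  FBA viability provably equals graph reachability, giving an LP-free
  ground-truth oracle for testing every pipeline stage.

## Worked example

The toy universe in `fluxspace.toy_a()` has four internal reactions —
r1: A→B, r2: B→P, r3: A→C, r4: C→B — one biomass precursor P, and two
environments supplying A or C. Running
`python examples/01_toy_walkthrough.py` prints:

```
== viability of single genotypes ==
{r1, r2} on A: biomass=10.00 viable=True
{r1} on A: biomass=0.00 viable=False
{r2, r3, r4} on A: biomass=10.00 viable=True

== phenotype vectors (A, C) ==
n=2 mask=3: (1, 0)
n=3 mask=b: (1, 1)
n=4 mask=f: (1, 1)

== exhaustive enumeration: viable on at least A ==
members=5 counts by size={2: 1, 3: 3, 4: 1} n_min=2

== the size-3 genotype network ==
members=3 edges=3 components=1 diameter=1

== disconnected reactions ==
['r1', 'r2', 'r3'] on A: disconnected={'r3'}
['r1', 'r2', 'r4'] on A: disconnected={'r4'}

== neighborhood innovation ==
focal 3 phenotype=(1, 0) novel phenotypes=[(1, 1)] (4 neighbors)
```

Reading the output: exactly five of the 2^4 genotypes grow on A; the
smallest ({r1, r2}) has two reactions; the three size-3 viable genotypes
form a triangle in swap space; {r1, r2, r3} carries r3 as dead weight (its
product C feeds nothing); and a single mutation away from {r1, r2} lies a
genotype with the novel phenotype "grows on A *and* C".

The same API runs on the bundled central-carbon universe
(`python examples/02_ccm_anchors.py`, ~7 s):

```
universe: 51 internal reactions, 10 environments, hash 1014ceade19c03a8

full-universe phenotype: (1, 1, 1, 1, 1, 1, 1, 1, 1, 1)

always-essential reactions (6): ['ENO', 'GAPD', 'GLNS', 'PGK', 'PGM', 'RPI']
n_min(glucose) = 23  witness verified: True
n_min(acetate) = 30  witness verified: True
n_min(all ten) = 34  witness verified: True
```

`examples/03_synthetic_survey.py` enumerates a generated universe with the
divide-and-merge engine (175 LP tests instead of 256 genotypes on an
8-reaction example), checks its closed-form minimal sizes, and traces mean
neighborhood diversity u against genotype distance.

## Command-line interface

All operations are available as `fluxspace` subcommands:

```
fluxspace synth --out /tmp/uni                 # generate a ground-truth universe
fluxspace viability -m ccm --env glucose --genotype 7ffffffffffff
fluxspace essential -m ccm                     # always-essential reactions
fluxspace nmin -m ccm --carbon glucose         # MILP minimal metabolism size
fluxspace enumerate -m toy-a --criterion at-least:A-inlet --out /tmp/enum
fluxspace components --set /tmp/enum/genotypes.txt --n 3
fluxspace diameter   --set /tmp/enum/genotypes.txt --n 3
fluxspace neighborhood -m toy-a --set /tmp/enum/genotypes.txt --n 3
fluxspace netdist --sets results/ --n 3        # D_min matrix between networks
fluxspace dgdp -m toy-a --set /tmp/enum/genotypes.txt --n 3
fluxspace run --out results/                   # full pipeline from a JSON config
```

`fluxspace run` executes enumeration → size histogram → phenotype table →
components/diameter → disconnected fractions → neighborhood diversity →
inter-network distances, writing TSV/JSON artifacts plus a manifest with a
config hash; reruns under an unchanged config reuse cached stages, and
outputs are byte-identical for a fixed config and seed.

## Reproduction

```sh
pip install --no-build-isolation -e .
python -m pytest -o addopts= -p no:cacheprovider -q tests/   # full suite, ~1 min
python scripts/acceptance.py --seed 42 --out acceptance.json # anchors, ~30 s
```

`tests/test_acceptance.py` contains one test per release criterion:
enumeration-engine equivalence against brute force on seeded synthetic
universes, FBA–reachability equivalence over entire genotype spaces,
viability monotonicity, counting lower bounds, graph-algorithm
cross-checks, statistic anchors, analytic values, and the fixture's desk
targets (six always-essential reactions; n_min 23 on glucose and 34 on all
ten sources). Full-scale counts over the 2^51 genotype space are
documented, flagged targets in `docs/methods.md`, not CI checks.

`scripts/acceptance.py` recomputes every reported quantity from scratch
(the seed controls the synthetic universes and random sampling) and writes
them as JSON.

## Layout

```
src/fluxspace/        library (universe I/O, FBA, enumeration, networks,
                      neighborhoods, distances, synthetic data, CLI, pipeline)
src/fluxspace/data/   central-carbon fixture (TSV, text-only)
scripts/              fixture provenance + acceptance recomputation
examples/             narrative walkthroughs (this README's outputs)
tests/                pytest suite incl. test_acceptance.py
docs/methods.md       models, parameters, numerical choices, limitations
```
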