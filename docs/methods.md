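# Methods

This document records the models, parameters, numerical choices, and scope
limits behind `fluxspace`. The package maps metabolic *genotypes* —
presence/absence patterns over a fixed universe of internal reactions — to
*phenotypes* — the set of carbon sources on which flux balance analysis
(FBA) predicts viable growth — and analyses the structure of the resulting
genotype networks.

## 1. The central-carbon reaction universe

The bundled fixture (`src/fluxspace/data/ccm_universe.tsv`,
`ccm_environments.tsv`) is a curated central-carbon-metabolism universe
derived from the published *E. coli* core reconstruction that ships with
COBRApy (`textbook` model, BiGG identifiers). The curation script is
`scripts/build_ccm_fixture.py`; it applies, in order:

1. **Removal** of the ethanol branch (`ALCD2x`, `ETOHt2r`, `EX_etoh_e`) and
   of the non-growth ATP maintenance pseudo-reaction `ATPM`, so that biomass
   is the only flux forced through the network.
2. **Merging** the two aconitase half-reactions `ACONTa` + `ACONTb` into a
   single reversible `ACONT` (cit ↔ icit).
3. **Splitting** the reversible ATP synthase `ATPS4r` into an irreversible
   synthase `ATPS4` and an irreversible hydrolysis direction `ATPase`,
   declared as a cofactor-recycling pair. The other declared pairs are the
   malic-enzyme isoforms (`ME1`, `ME2`) and the transhydrogenases
   (`NADTRHD`, `THD2`).
4. **Classification**: the biomass reaction is the objective; boundary
   reactions are exchanges; reactions touching an external metabolite other
   than `h_e` are transport; the remaining **51 reactions are the internal
   universe** over which genotypes are defined (bit order = fixture row
   order). Transport (20 reactions) and exchange reactions are present in
   every genotype.
5. **Biomass precursors**: the 12 substrates of the biomass reaction after
   excluding the recycled cofactors `atp_c`, `h2o_c`, `nad_c`, `nadph_c`.
6. **Environments**: ten minimal environments, one per carbon source
   (acetate, α-ketoglutarate, fructose, fumarate, glucose, glutamate,
   glutamine, lactate, malate, pyruvate), carbon uptake bound 10
   mmol·gDW⁻¹·h⁻¹, with shared nutrients (CO₂, H⁺, H₂O, NH₄⁺, O₂,
   phosphate) open at 1000.

The fixture's 16-hex-digit model hash (`1014ceade19c03a8`) is embedded in
every artifact header so results are traceable to the exact universe.

## 2. Viability phenotyping

Given a genotype `g`, the LP is: maximize biomass flux subject to
steady-state mass balance `S v = 0` and bounds, with absent internal
reactions clamped to zero. LPs are solved with `scipy.optimize.linprog`
(HiGHS). A genotype is **viable** in an environment when its biomass optimum
strictly exceeds **1 %** of the full universe's optimum in that environment
(`DEFAULT_THRESHOLD = 0.01`). Infeasible LPs are reported as biomass 0.0,
not as errors. Per-environment solver contexts are memoized on the universe
object, so repeated queries for the same genotype cost nothing.

Numerical constants: flux activity epsilon `FLUX_EPS = 1e-6` (used by the
FVA-based blocked-reaction test); viability threshold as above.

## 3. Minimal metabolism size (n_min)

`minimal_viable_size` solves a mixed-integer program
(`scipy.optimize.milp`): binary indicator per internal reaction, big-M
coupling of fluxes to indicators, biomass required to exceed the viability
threshold in every required environment, minimizing the indicator sum.
Because MILP tolerances can return supports that sit numerically *at* the
strict threshold, the biomass constraint carries a margin of `1e-4` above
the threshold and the returned witness is re-verified by a plain strict LP;
the MILP is re-solved with the offending support excluded if verification
fails. Desk anchors on the fixture: n_min = 23 (glucose), 23 (fructose),
30 (acetate), 34 (all ten sources jointly).

## 4. Exhaustive enumeration

`enumerate_divide_merge` enumerates all genotypes satisfying a viability
criterion (`at-least:` a set of sources, or `excl:` exactly a set) without
testing all 2^N subsets: reactions essential in every required environment
are pre-fixed to present; the remaining bits are split into contiguous
blocks; within each block, a bit pattern whose *most permissive completion*
(all other bits present) is inviable is pruned together with its entire
sub-cube — FBA viability is monotone under reaction addition — and blocks
are merged pairwise left to right. Exclusive criteria are enumerated as the
monotone `at-least` superset and filtered by complement environments.
Equivalence with brute force is enforced property-based in the acceptance
suite.

## 5. Genotype networks

Vertices are same-size viable genotypes; edges connect genotypes at **swap
distance 1** (Hamming distance 2 at equal size). Neighbor lookup uses
(n−1)-subset buckets, components use streaming BFS over bit masks. The
**diameter** is the metric diameter — the maximum pairwise swap distance
within the giant component — computed exactly by vectorized popcount when
the component is small enough, otherwise lower-bounded by sampling; it is
bounded by `min(n, N−n)`. The path diameter (longest BFS shortest-path) is
available separately. Connectivity of the size-(n+1) class can often be
inherited from a connected size-n class (every member of a connected
superset class that contains some member's superset is reachable); the
implementation falls back to direct BFS whenever the precondition fails and
is tested never to contradict BFS.

A present reaction is **disconnected** in `(g, e)` when its products feed
no present consumer and are not biomass precursors, or when one of its
substrates is neither produced by another present reaction nor supplied by
the environment. The test is a single topological pass over reaction
orientations; orientations that would consume an external metabolite whose
exchange is closed are not counted as producers. An optional fixed-point
mode iterates the test.

## 6. Neighborhood innovation and distances

The novelty set of a genotype is the set of distinct phenotype vectors of
its one-mutation neighbors (additions and deletions by default; swap
neighbors optionally) that strictly gain at least one source over the focal
phenotype. For two genotypes the **u statistic** is one minus the Jaccard
index of their novelty sets; it is undefined (NaN, flagged and excluded
from means) when both sets are empty. Diversity curves sample genotype
pairs at fixed swap distance by rejection sampling within the giant
component. Randomization nulls redraw novelty sets from the pooled
phenotype collection.

`D_min` between two genotype networks is the minimum cross-pair swap
distance: 0 on overlap, 1 when their (n−1)-subset indexes intersect, else a
vectorized brute-force cross-pair minimum (optionally restricted to giant
components).

## 7. Synthetic universes with ground truth

`make_layered_universe` generates layered directed-acyclic universes of
irreversible unit 1:1 conversions: each carbon source reaches a hub
metabolite through parallel branches of random length, and the hub feeds
each biomass precursor. On such universes FBA viability is provably
equivalent to graph reachability, so an LP-free oracle
(`reachability_oracle`) and closed-form n_min are available; the oracle is
mode-guarded and refuses non-layered universes. A second generator
(`make_random_massbalanced`) emits mass-balanced universes with non-unit
stoichiometry and optional cofactor pairs for stress testing. **Scope**:
the layered oracle is valid only for irreversible, unit-stoichiometry,
acyclic universes — it is a test harness, not a model of real metabolism.

## 8. Full-scale targets (documented, not CI)

The genotype space of the fixture has 2^51 ≈ 2.25 × 10^15 members. A
full-scale exhaustive survey of this space yields the reference values
below; reproducing them requires cluster-scale enumeration, so they are
recorded here as flagged targets rather than recomputed in CI:

| quantity | value |
|---|---|
| genotypes viable on glucose | 1,549,771,520 |
| genotypes viable on acetate | 10,850,304 |
| genotypes viable on all ten sources | 1,029,375 |
| disconnected fraction f_d, pyruvate | 0.517 |
| disconnected fraction f_d, acetate | 0.307 |
| realized phenotype vectors (of 2^10 = 1024) | 84 |

What *is* recomputed from scratch (tests and `scripts/acceptance.py`): the
six always-essential internal reactions {ENO, GAPD, GLNS, PGK, PGM, RPI},
the n_min anchors above, enumeration/oracle equivalences on synthetic
universes, and all analytic values (256 forbidden phenotypes per two-source
implication over the ten-source panel, space size 2^51, the
`min(n, N−n)` diameter bound).

## 9. Limitations

- The 1 % viability threshold is a convention; biological viability is not
  a strict threshold phenomenon.
- Enumeration cost is exponential in the non-essential bit count; the
  divide-and-merge engine defers but does not remove this, so full-scale
  counts over the 51-reaction universe are out of scope for a single CPU.
- The MILP margin (1e-4) trades a vanishing chance of overestimating n_min
  by rejecting razor-edge supports against solver-tolerance false
  positives; all desk anchors are unaffected.
- The disconnectedness test is topological, not flux-based: it cannot see
  reactions disabled by cofactor imbalance (those appear in the FVA-based
  blocked-reaction test instead).
- Uptake bounds scale the biomass optimum linearly; viability (a ratio
  test) is insensitive to the carbon uptake magnitude, which is why the
  fixture's value of 10 is a convention rather than a fitted parameter.
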