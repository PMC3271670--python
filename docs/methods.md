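# Methods

## Model

Two genomes `A` and `B` are sets of linear and circular chromosomes
over signed markers, with no marker occurring twice in a genome.
Markers present in both genomes are *common*; the others are *unique*
to their genome.  Two operation families sort `A` into `B`:

* **DCJ** — cut the genome at two positions and rejoin the four open
  ends differently (covers inversion, translocation, fusion, fission;
  a single cut whose ends become telomeres, and the fusion of two
  telomeres, are the degenerate cases);
* **substitution** — replace a contiguous block of unique markers
  inside one adjacency by another block of unique markers; either
  block may be empty, so insertions and deletions are special cases.
  A whole chromosome may be substituted at once, but never a linear
  chromosome by a circular one or vice versa.

Both operation kinds cost 1.  The distance is the minimum number of
operations.  Only unique markers can be substituted, which avoids the
degenerate shortcut of substituting one genome's whole content by the
other's.  The distance is a parsimony measure — in practice a lower
bound on the number of historical events — and deliberately interprets
a deletion plus an insertion at the same position as one substitution,
i.e. as a region under continuous mutation.

## Computation

The implementation follows the adjacency-graph route
(`adjacency_graph`, `potentials`, `recombination`):

1. `d_DCJ = n − (c + b/2)` over the `n` common markers, with `c` cycles
   and `b` AB-paths of `AG(A,B)` (`b` is always even; the code asserts
   this rather than rounding).
2. Each component's labels are read in canonical order (paths from the
   A-side endpoint when one exists, AB-paths therefore from A to B;
   cycles cyclically, which makes the run count independent of the
   storage rotation).  Maximal stretches of one genome's unique markers
   are runs; `Λ(C)` counts them.  A path may have any number of runs, a
   cycle zero, one, or an even number.
3. Indel-potential `λ(C) = ⌈(Λ+1)/2⌉` and substitution-potential
   `σ(C) = ⌈λ(C)/2⌉` for labeled components, both zero for clean ones.
   `σ` is computed from `λ` rather than independently; the brute-force
   oracle guards the composition.  Singletons (whole chromosomes of
   unique markers) have `σ = 1`; disjoint same-topology pairs
   (`P_L`, `P_C`, one singleton per genome) are sorted by a single
   whole-chromosome substitution, saving one step per pair.
4. The upper bound `d_DCJ + Σσ − P_L − P_C` is exact for co-tailed
   genomes (equal sets of linear-chromosome tail extremities over the
   common markers, including two fully circular genomes).
5. For non-co-tailed genomes, *recombinations* — DCJs cutting two
   different path components — can save more.  The final distance
   subtracts the deduction `2U + 3V + 2W + X + 2Y + Z` obtained from an
   optimal plan of recombinations over the labeled paths.

## The recombination catalogue

Labeled paths are classified by endpoint kinds (`AA`, `BB`, `AB`) and
run structure `4i+k` (`k` in 1..4) plus the first run's genome; since
AA-/BB-paths read in either direction, even `k` loses its chirality,
while AB-paths read from A to B and keep it.  `σ` of a path is `i+1`
for `k ≤ 3` and `i+2` for `k = 4`, so rule applicability depends only
on `k` and the chirality — never on `i`.

The catalogue of useful recombinations was **derived by exhaustive
enumeration at the run-word level**: a cut on genome X splits a path's
run word between runs, inside an X-run, or at an extreme (legal in
general position, where optimal accumulation DCJs can always place
clean buffer vertices around runs), and rejoining concatenates pieces,
merging equal boundary letters.  Enumerating all splits and rejoinings
over all type pairs, for `i = 0` and `1`, yields:

* all recombinations with `Δd ≤ −1` (table 1 in the data file), where
  `Δd = Δ_dcj + Δσ`, `Δ_dcj` is 0/+1/+2 for optimal/neutral/
  counter-optimal DCJs and `Δσ ≥ −2` always;
* all neutral recombinations (`Δd = 0`, `Δσ < 0`) that create a source
  for the first kind (table 2).

The derivation is frozen into
`src/dcjsub/data/recombination_rules.tsv` with a checksum.  Three
independent guards protect it: `load_rule_table` re-checks the delta
arithmetic, the `Δσ ≥ −2` bound and closure under swapping the two
genomes; a test regenerates the table from the enumerator and compares
byte-for-byte; and the end-to-end test suite compares distances
computed through the table with a brute-force scenario search on
hundreds of random small genome pairs.

**Linear singletons** are degenerate k=1 paths with vertices in only
one genome: a DCJ can only inject their whole content into a cut of a
partner path (the freed end becoming a telomere), which supports the
plain `Δd = −1` pairings but not the piece-structured splits that
create reusable resultants.  They carry distinct restricted types
(`sAA.a1`, `sBB.b1`) with their own derived rules; only singletons left
over after the `P_L` pairing enter the pool (pairing first is never
worse: each singleton saves at most one step either way, and pairing
spares a partner path).  Circular singletons never recombine usefully
— probed directly against the oracle — and are handled by `P_C` alone.

## The deduction and the group counts

The deduction is computed as the **exact optimum** over sequences of
catalogued recombinations, by memoized search over the multiset of
path-type tokens (`recombination._optimal_plan`).  Every applicable
rule strictly reduces the total substitution-potential, so the search
terminates; memoization keys on the remaining type counts, and the
result provably depends only on the initial counts per type.  Group
counts `U..Z` are read off the optimal plan by chain classification:
ops consuming an earlier op's resultant join its chain; a lone
`Δd = −2` op is `U`, a lone `−1` op is `X`, pure chains of
distance-reducing ops count `V` (−3) and `W` (−2), and chains routed
through a neutral source-creating op count `Y` (−2) and `Z` (−1).
This reproduces the per-group savings (scores −1, −3/4, −2/3, −1/2,
−1/2, −1/3 per consumed path) while guaranteeing optimality by
construction: a fixed greedy tier order interacts subtly
with type chirality (a pair of small paths may serve either as a
direct `−1` recombination or as the partners of a `Y`-chain, with
different totals), and the exhaustive plan sidesteps that fragility.
The search is exponential only in the number of *distinct* labeled
path types with large multiplicities; on realistic comparisons the
labeled-path count is small and the computation is instantaneous,
though the worst case forfeits the strict linear-time guarantee of a
tier greedy.

## Brute-force oracle

`oracle_sim.oracle_distance` is the independent ground truth at small
scale: breadth-first search over all DCJs (in the standard extremity-
matching formalism, so every cut position between markers is available)
plus restricted substitutions — removed blocks are maximal contiguous
blocks of markers absent from the target, inserted blocks occur
contiguously in the target (either orientation) and are not yet
present; whole target chromosomes may be inserted, whole absent
chromosomes deleted, and whole-chromosome replacements preserve
topology.  Every move sequence is a valid scenario, so the search
yields an upper bound; it is run in **both directions** (the operations
are closed under inversion) because a scenario that first accumulates
markers with DCJs and then deletes them in one block is visible only
from one side.  Agreement with the closed formula on hundreds of
seeded random instances certifies both.  The oracle refuses instances
with more than 7 distinct markers; breadth-first depth is capped by
the planted operation count plus one.

## Synthetic pairs

`random_genome_pair(n_common, n_unique_a, n_unique_b, n_dcj, n_subst,
seed)` plants a known scenario: a random ancestor genome over the
common markers plus the A-unique markers grouped into at most
`n_subst` contiguous blocks (random signs, one to three chromosomes,
circular with probability 0.3 — small multichromosomal genomes with a
mix of topologies, exercising every component kind); `B` results from
substituting each A-unique block by a B-unique block (block-removing
substitutions before pure insertions, so an insertion cannot split a
block that is yet to be replaced) and then applying `n_dcj` uniformly
random DCJs.  The planted count `n_dcj + n_subst` upper-bounds the true
distance.  All randomness flows through one seeded generator.  The
generator emulates marker-level rearrangement and region replacement
only: real data complications — orthology-assignment errors, duplicated
markers, unequal block sizes, missing assembly segments — are out of
its vocabulary, so passing tests certify the combinatorial machinery,
not robustness to annotation noise.

## Sizes and tolerances

Validation sweeps use instances with at most 4–6 common and 3 unique
markers (the brute-force search grows exponentially beyond that), 200
instances for oracle equivalence and 500 for the formula-level checks;
all comparisons are exact integer equalities, so no numerical
tolerances arise anywhere in the package.  Empty genomes, genomes with
no common markers, and single-marker circular chromosomes are all
legal inputs covered by tests.

## Known limitations

* Duplicated markers are rejected, not modeled.
* The distance is computed, not a sorting scenario; no operation list
  is emitted.
* The triangle inequality can fail (verified constructively in the
  tests); the distance is not a metric without post-hoc correction.
* The oracle's restricted substitution moves are certified only
  through their agreement with the formula; at sizes beyond the cap
  they are unverified.
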