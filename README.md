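# dcjsub

Genomic distance between two genomes with unequal marker content under
the **DCJ-substitution model**: double-cut-and-join operations (which
cover inversions, translocations, fusions and fissions) plus
**substitutions** of contiguous blocks of unique markers.  Because a
substitution subsumes a deletion and an insertion at the same position,
it counts as a single step where indel-only models count two — giving a
more parsimonious distance and, as a by-product, candidate pairs of
regions with a common evolutionary origin (including potential
unannotated orthologs).

The package is for comparative genomicists working with signed
gene-order data (synteny blocks or single-copy genes) in two genomes
that share part of their marker content.  Duplicated markers are not
supported — the model is undefined for them.

## The distance

Write `G` for the markers common to genomes `A` and `B` (`n = |G|`) and
build the adjacency graph `AG(A,B)`: one vertex per adjacency of each
genome (a pair of common-marker extremities or telomeres, labeled with
the unique markers lying between them), one edge per common-marker
extremity.  The graph decomposes into cycles, `AA`-/`BB`-/`AB`-paths
and singletons, giving the classic DCJ distance over the common markers

    d_DCJ(A,B) = n − (c + b/2)

with `c` cycles and `b` AB-paths.  Reading the labels of a component in
order yields alternating **runs** of A-unique and B-unique markers;
with `Λ(C)` runs a component has indel-potential `λ(C) = ⌈(Λ+1)/2⌉` and
substitution-potential `σ(C) = ⌈λ(C)/2⌉` (both 0 for clean components).
With `P_L`/`P_C` the maximum numbers of disjoint pairs of linear and
circular singletons, the distance is

    d(A,B) = d_DCJ + Σ_C σ(C) − P_L − P_C − (2U + 3V + 2W + X + 2Y + Z)

where `U..Z` count groups of *recombinations* — DCJs acting on two
labeled paths whose combined effect saves extra substitutions.  The
complete recombination catalogue ships as a validated plain-text table
(`src/dcjsub/data/recombination_rules.tsv`), and the group counts are
read off an optimal recombination plan computed over the multiset of
labeled path types.

## Worked example

Two linear chromosomes that differ by one substituted block
(`s u` in A versus `x y` in B):

```
$ cat A.genome            $ cat B.genome
>A                        >B
a s u b $                 a x y b $

$ dcjsub distance A.genome B.genome
n 2
c 1
b 2
d_dcj 0
sum_lambda 2
sum_sigma 1
p_l 0
p_c 0
U 0
V 0
W 0
X 0
Y 0
Z 0
deduction 0
d_upper 1
d_dcjsub 1
co_tailed True
```

The two common markers `a`, `b` are already in order (`d_dcj 0`).  The
2-edge cycle holding the labels has two runs (`s u` from A, `x y` from
B), so one substitution sorts it: `d_dcjsub 1`.  An indel-only model
would pay `d_dcj + sum_lambda = 2` (one deletion plus one insertion).

Simulation with a planted scenario, and verification against the
brute-force oracle:

```
$ dcjsub simulate --common 6 --unique-a 2 --unique-b 2 --dcj 3 --subst 2 \
      --seed 42 --out sim/
$ dcjsub distance sim/A.genome sim/B.genome | tail -2
d_dcjsub 4
co_tailed True

$ dcjsub verify --instances 50 --seed 2
instances 50
mismatches 0
```

The computed distance 4 is at most the five planted operations — the
generator's scenario need not be parsimonious.

Genome files are GRIMM-compatible: an optional `>name` header, then one
chromosome per line, whitespace-separated signed markers ending with
`$` (linear) or `@` (circular).

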