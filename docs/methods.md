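# Methods

## The simulation model

`gsped` simulates admixed diploid genotypes by *gene dropping* through a
genomic simulation pedigree (GSP) and then painting observed alleles onto
the inherited segments.  The two stages are deliberately separated:

1. **Segregation** works purely on intervals.  Each founder contributes two
   haploid genomes ("founder slots"), each labelled with a population of
   origin.  A meiosis recombines a pair of genomes into a gamete *and its
   complement* (the second product carries the other parental haplotype at
   every base pair).  At each non-founder node, gametes arriving on the two
   parent edges are paired in uniformly random order; a prescribed number
   of pairs is set aside as simulated individuals (the sample node), and
   every remaining pair is recombined again and dealt, in random order, to
   the outgoing edges according to their gamete counts.  Nodes are
   processed in topological order (parents before children).
2. **Painting** fills in alleles afterwards.  The input genotype matrix is
   permuted within populations, permuted individuals are assigned in order
   to founders, and each simulated marker copies the allele found on the
   founder haplotype that the marker's segment derives from.  Individuals
   not consumed as founders are returned as the retained reference.

Because each meiosis emits complement pairs and the pedigree's gamete
counts balance, the segments delivered to the samples tile every founder
haplotype exactly once — no base pair is duplicated or lost.  This is the
property that avoids resampling-induced spurious power inflation: simulated
data never contain more information about the source populations than the
input panels do.  The test suite asserts exact tiling on every run
(random pedigrees included).

A corollary worth knowing when designing pedigrees: since *all* founder
material reaches the samples, the mean admixture fraction over one
replicate's samples equals the founder population fraction exactly.  A
pedigree producing only second-generation backcrosses (expected 1/8
ancestry from the donor population) therefore needs 8 founders — 7
recurrent, 1 donor — and 8 samples; in general the BCg-only builder uses
2^(g+1) founders and samples.  Mean admixture is pinned by conservation;
only the between-individual spread is stochastic.

### Validity conditions

`validate_gsp` checks, and reports together rather than failing fast:
samples = founders (c1); each founder segregates exactly two gametes over
at most two edges (c2); the two parent edges of a non-founder carry equal
counts (c3); gametes out equal gametes in at non-founders without samples
(c4); gametes in equal twice the sample count at sample-only non-founders
(c5), plus the outgoing gametes when the node has both (c6); and the two
parents of every non-founder have disjoint ancestries in a DAG (no
inbreeding loops — a shared ancestor would let one founder gene copy reach
a descendant twice, which is sampling with replacement by the back door).
Conditions c5/c6 are stated as "gametes entering = 2·S (+ gametes
leaving)", the form consistent with the worked four-sample F2 pedigree
(8 gametes enter the node that delivers 4 samples).

### Preset pedigrees

Single-category presets are minimal: F1 (2 founders), F2 (the classic
4-founder, two-F1-node pedigree), BCg as above.  The four-category preset
delivers 1 F1, 2 F2, 1 BC1 and 2 BC2 from six founders; its gamete counts
were solved from the validity conditions.  Any other combination of the
four flags returns the disjoint union of the single presets — every
validity condition is local to a node or sums over the pedigree, so a
disjoint union of valid GSPs is valid.  Two compound builders exist for
experiments: `bc1xbc2_gsp` (offspring of a BC1 and a BC2 parent; an
incidental F1 sample balances its nine founders) and `f2xbc1_gsp`
(offspring of a BC1 and an F2 parent, expected admixture 5/8; an F2 gamete
has the same 1/2 ancestry marginal as an F1 gamete, and this variant
balances with 8 founders where a literal BC1 × F1 pedigree cannot).

The compound BC1 × BC2 category has expected ancestry-genotype triplet
(21/32, 10/32, 1/32) ≈ (0.656, 0.313, 0.031): a BC1 gamete carries
recurrent ancestry with probability 3/4 and a BC2 gamete with 7/8, and the
offspring genotype is the product of the two.  Note this differs from
(9/16, 6/16, 1/16) = (0.5625, 0.375, 0.0625), which is the product of two
3/4 gametes — i.e. a BC1 × BC1 cross — a value sometimes quoted for this
category.  The simulator reproduces the pedigree-correct product, and the
unit tests pin it against the closed form.

## Recombination model

Crossovers follow the Haldane model: the probability that ancestry
switches parental haplotype across an interval of genetic length d Morgans
is r = ½(1 − e^(−2d)); switches at distinct boundaries are independent (no
interference), and each chromosome starts on either parental haplotype
with probability ½ (independent assortment).  Maps are built either from
marker genetic positions or from physical positions under a uniform rate
(default **1 cM/Mb** — the standard rough genome-wide average used when no
map is available).  Boundaries sit at marker positions (`spacing=
"markers"`) or on a regular bp grid; crossovers occur exactly at boundary
positions, since markers are the only observation points and this keeps
segment arithmetic exact.  Chromosome length defaults to (last marker bp +
1) when only a marker map is given.  All coordinates are 0-based,
half-open; a marker at a boundary belongs to the right-hand segment.

The bundled pig-like genome has 18 autosomes in the proportions of the pig
reference assembly, rescaled to total exactly 2.35 Gb; at 1 cM/Mb it
yields ≈ 23.2 expected crossovers per meiosis.

## Permutation schemes

Permutation is always within populations, so per-population per-locus
allele counts are exactly invariant (asserted property-based).  The unit
that moves is controlled by two options:

- `preserve_individuals=True` — whole individuals (the default posture;
  keeps individual-level structure such as inbreeding intact);
- `"BY_CHROM"` — an individual's homologous chromosome pair moves intact
  but chromosomes permute independently (preserves within-chromosome LD);
- `False` — single gene copies shuffle freely per locus (maximal
  scrambling); with `preserve_haplotypes=True` the shuffled units are
  whole per-chromosome haplotype blocks instead (sensible only for phased
  data — unphased input draws a warning, not an error, since phase is a
  user-asserted flag).

Missing alleles (PLINK `"0"`) permute as ordinary values: they are data,
and excising them would distort counts.  Every permutation records a
destination→source provenance bijection; applying its inverse recovers the
input exactly, and painting commutes with provenance.

Founder assignment is deterministic given the seed: founders are taken in
(replicate, founder id, haplotype) order and consume whole individuals in
permuted matrix order; painting refuses founders whose two haplotypes
carry different population labels (segregation supports them, but painting
them would consume half-individuals and break the no-reuse accounting at
the individual level).

## Synthetic reference panels and the experiments

The panel generator draws one allele-frequency vector from Beta(1, 8) — a
low-frequency-skewed SNP site-frequency shape — and simulates two
Hardy–Weinberg panels of N diploids from the *same* frequencies, with loci
placed uniformly over a supplied genome.  It emulates unstructured,
unlinked, fully called biallelic data; it does not emulate LD within the
panels, genotyping error, missingness patterns, allele-frequency
divergence (the two panels are one population by construction), or
ascertainment bias.  Passing experiments therefore demonstrate estimator
behaviour under the null of no differentiation, not robustness to real
data pathologies.

**RISPI arm.**  New individuals are simulated at each nominal q by drawing
each gene copy's origin Bernoulli(q) and its allele *with replacement*
from the corresponding panel's copies at that locus; the supervised
estimator is handed the very panel frequencies the data were simulated
from.  This reproduces the spurious recovery of q (strongest at many loci
and small N).

**Pedigree arm.**  The same nominal q grid is realised exactly by
pedigrees (0, 1 pure; 1/2 F1; 1/4, 3/4 BC1; 1/8, 7/8 BC2; 3/8, 5/8
BC1 × F2), painted with whole-individual permutation; the estimator uses
frequencies from the retained individuals — the cross-validation structure
in which reference material and test material are disjoint.

**Supervised estimator.**  Per individual, an EM maximum-likelihood fit of
the admixture model q̂ = argmax Σ log(q·p_A + (1−q)·p_B) over gene copies,
with panel frequencies treated as known, clamped to
[1/(2N+1), 1 − 1/(2N+1)] to keep the likelihood finite at fixed loci;
tolerance 10⁻⁶, ≤ 500 iterations; a flat likelihood stays at the 0.5
starting point (tie-break), and an all-missing individual returns 0.5 with
a warning.  Two design points matter for unbiasedness under the null, both
found by measurement during development and fixed by design rather than
tuning:

- *Whole-individual permutation* for painting: free gene-copy scrambling
  makes a simulated individual's alleles the within-locus complement of
  the retained panel, anti-correlating test material with the reference
  and biasing q̂ away from the nominal value.  With whole individuals,
  founders and retained individuals are disjoint iid draws, hence
  independent.
- *Balanced references*: founder consumption leaves the two retained
  panels unequal in size (a BC2 pedigree takes 7 founders from one panel,
  1 from the other), and a fixed-frequency MLE is pulled toward the
  larger, less noisy reference.  The estimator is therefore fed
  frequencies from equal-size retained subsets (the larger panel
  subsampled to the smaller's size; the retained matrix is already in
  permuted random order).  An alternative joint EM that re-estimates
  frequencies from the test individuals' responsibilities was prototyped;
  it is approximately unbiased but boundary-attracted (per-individual SD
  ≈ 0.3 at 10⁴ loci) and far slower, so the fixed-frequency MLE with
  balanced references is used.

**Linkage arm.**  Unlinked-hybrid admixture fractions at L loci are drawn
per locus from the category triplet (a multinomial shortcut reproduces the
exact distribution of the genotype-level simulation and is used at large
L); segment-based fractions come from segregating the category's pedigree
on the genome-scale map.  The unlinked spread collapses as 1/√L while the
linked spread is L-free — the linked one is the truth.

## Problem sizes and randomness

Distributional checks use 2,000 simulated individuals per hybrid category
for ancestry-genotype triplets (tolerance ±0.02) and 1,000 for admixture
means (±0.01); the null-panel experiment pools 40 replicates of the full
q grid at L = 1,000, N = 50; the direction contrast runs at L = 10⁴,
N = 25 with 16 pedigree replicates (per-cell Monte Carlo SE < 0.01,
chosen so the ±0.03 cell-mean band sits beyond 3 SE) and the linkage
contrast uses 2,000 unlinked draws at L = 10⁵ against ~500 segregated BC2
genomes.  The full default experiment grid (L ∈ {10², 10³, 10⁴},
N ∈ {25, 50}, n = 12, R = 8, i.e. 96 individuals per cell) is a
scaled-down version of the original balanced design (480 per cell); pass a
larger `ExperimentConfig` to approach it.

All randomness derives from a single user seed through named
`SeedSequence` sub-streams — one per (replicate, pedigree node) in
segregation, one per population (and chromosome, where applicable) in
permutation — so results are reproducible regardless of evaluation order,
and node-level draws do not shift when unrelated parts of a pedigree
change.

## Known limitations

- No mutation, gene conversion, crossover interference, or sex
  chromosomes; no sex-specific maps.
- Pedigrees with inbreeding loops are rejected by design (use related
  founders to emulate inbreeding instead); repeated mating of *fixed*
  founders across replicates would expose the antithetic-gamete
  correlation, so each replicate instantiates fresh founders.
- Painting requires called genotypes (missing data allowed); genotype
  likelihoods are unsupported.
- Painting consumes whole individuals, so founders with mixed-population
  haplotypes segregate but cannot be painted.
- Text PLINK only (.ped/.map); binary .bed and VCF are out of scope.
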