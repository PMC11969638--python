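# gsped — simulate admixed genotypes without resampling genetic material

`gsped` creates admixed individual genotypes (F1, F2, backcrosses and
arbitrary compound hybrids) from empirical reference panels, for power
analyses of genetic clustering and hybrid-classification workflows.

Two design principles set it apart from frequency-resampling simulators:

1. **No sampling with replacement.**  Simulating genotypes by drawing
   alleles from the *sample* allele frequencies implicitly treats those
   frequencies as the population's, which inflates apparent divergence and
   therefore the perceived power to assign individuals — *resampling-induced
   spurious power inflation* (RISPI).  `gsped` instead permutes the observed
   alleles within populations and segregates them through a pedigree, so the
   simulated data carry exactly the genetic material of the input panels,
   each gene copy used exactly once.
2. **Physical linkage.**  Genomes are inherited in segments, not locus by
   locus.  Crossovers are drawn from a recombination map (Haldane model,
   r = ½(1 − e^(−2d)), no interference; independent assortment between
   chromosomes), so simulated hybrids show the true, large
   between-individual variance in admixture fraction that unlinked-locus
   simulation erases.

The simulation blueprint is a **genomic simulation pedigree (GSP)**: a
loop-free pedigree of founder, non-founder and sample nodes whose edges
carry gamete counts.  Validity conditions (samples = founders; two gametes
per founder; gamete balance at every node; no inbreeding loops) guarantee
that the segments delivered to the samples tile every founder haplotype
exactly once.  Each meiosis also emits the *complement* of its gamete
(antithetic sampling), which is what makes exact conservation possible.

## Worked example

Segregate F2 and second-generation backcross (BC2) genomes on an
18-chromosome, 2.35-Gb pig-like genome at 1 cM/Mb
(`examples/02_segregate_hybrids.py`):

```
genome: 18 chromosomes, 2.35 Gb; expected crossovers per meiosis: 23.2
F2: 160 samples from 320 founder haplotypes
  admixture from A: mean=0.5000 sd=0.0572
  mean (2,1,0)-copy genome fractions: (0.248, 0.503, 0.248)
BC2: 320 samples from 640 founder haplotypes
  admixture from A: mean=0.8750 sd=0.0323
  mean (2,1,0)-copy genome fractions: (0.750, 0.250, 0.000)
```

The F2 mean admixture is 0.5000 *exactly* and the BC2 mean 0.8750 exactly:
conservation pins the mean to the founder population fraction, while the
standard deviations (0.057, 0.032) are the genuine between-individual
spread caused by Mendelian segregation of whole segments.  The genome
fractions carrying 2/1/0 copies of population-A ancestry match the
expected hybrid-category triplets, (¼, ½, ¼) for F2 and (¾, ¼, 0) for BC2.

Other narrative scripts in `examples/` cover pedigree construction and
validation (`01`), permutation painting onto empirical panels (`03`), the
RISPI demonstration (`04`) and the linked-vs-unlinked comparison (`05`).

## Library tour

- `gsped.genetic_map` — PLINK `.map` reading, recombination maps from
  genetic positions or a uniform cM/Mb rate, per-meiosis crossover masks.
- `gsped.gsp` — GSP node/edge tables (CSV dialect), `create_gsp` presets up
  to BC2, generic builders (`backcross_gsp(g, ...)`, `bc1xbc2_gsp`, ...),
  and `validate_gsp` reporting every violated condition.
- `gsped.segregate` — gene dropping: `segregate`, `meiosis`,
  `admixture_fraction`, `ancestry_genotype_fractions`; segment tables in
  0-based half-open coordinates.
- `gsped.permute` — within-population permutation (whole individuals, by
  chromosome, or free gene copies; optional phased-haplotype units), with a
  provenance bijection.
- `gsped.markers` — `segments2markers` (founder assignment + allele
  painting), PLINK `.ped`/`.map` IO.
- `gsped.demo_experiments` — Beta/HWE panel generator, the supervised EM
  admixture estimator, and the RISPI and linkage experiments.

A thin CLI mirrors these steps (`gsped map2rates | validate | preset |
segregate | permute | paint | rispi | linkage-demo`); run `gsped --help`.

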