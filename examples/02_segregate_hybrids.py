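"""Segregate hybrid genomes on a pig-like map and measure their ancestry.

Simulates F2 and BC2 individuals on an 18-chromosome, 2.35-Gb genome at
1 cM/Mb and reports segment-based admixture fractions and ancestry-genotype
triplets.  The mean admixture of a pedigree's samples equals the founder
population fraction exactly (conservation); the spread is the biologically
real between-individual variation that unlinked simulation misses.
"""

import numpy as np

from gsped import (admixture_fraction, ancestry_genotype_fractions,
                   backcross_gsp, build_rec_map, f2_gsp, pig_genome,
                   segregate)

genome = pig_genome()
rec = build_rec_map(genome, cM_per_Mb=1.0, spacing=1_000_000)
print(f"genome: {len(genome.chroms)} chromosomes, {genome.total_length/1e9:.2f} Gb;"
      f" expected crossovers per meiosis: {rec.expected_crossovers():.1f}")

for name, gsp in [("F2", f2_gsp("A", "B")), ("BC2", backcross_gsp(2, "A", "B"))]:
    samples, ledger = segregate(gsp, rec, n_reps=40, seed=42)
    qs = np.array([admixture_fraction(s, "A", genome) for s in samples])
    tr = np.array([ancestry_genotype_fractions(s, "A", genome) for s in samples])
    print(f"{name}: {len(samples)} samples from {len(ledger)} founder haplotypes")
    print(f"  admixture from A: mean={qs.mean():.4f} sd={qs.std():.4f}")
    print(f"  mean (2,1,0)-copy genome fractions: "
          f"({tr[:,0].mean():.3f}, {tr[:,1].mean():.3f}, {tr[:,2].mean():.3f})")
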