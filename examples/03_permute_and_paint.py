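"""Paint empirical alleles onto simulated segments by permutation.

Two small reference panels are permuted within populations (allele
frequencies are exactly conserved — nothing is resampled), assigned to the
founders of an F1 pedigree, and the simulated F1s receive the alleles that
their inherited segments carry.  Individuals not used as founders are
returned as the retained reference.
"""

import numpy as np

from gsped import (PermutationPlan, build_rec_map, f1_gsp, segments2markers,
                   segregate, sim_reference_panels)
from gsped.demo_experiments import PanelConfig
from gsped.permute import concat_genotypes

panel_a, panel_b, freqs = sim_reference_panels(
    PanelConfig(L=200, N=12), rng=np.random.default_rng(5)
)
geno = concat_genotypes([panel_a, panel_b])
print("input:", geno)

rec = build_rec_map(geno.markers, cM_per_Mb=1.0)
samples, ledger = segregate(f1_gsp("A", "B"), rec, n_reps=2, seed=9)

plan = PermutationPlan(preserve_individuals=True, seed=11)
out = segments2markers(samples, ledger, geno, plan=plan)
print("simulated:", out.simulated)
print("retained:", out.retained)
print("founder assignments:")
print(out.assignments.to_string(index=False))

# every input gene copy appears exactly once across simulated + retained
pooled = np.concatenate([out.simulated.alleles.ravel(), out.retained.alleles.ravel()])
same = sorted(pooled.tolist()) == sorted(geno.alleles.ravel().tolist())
print("allele multiset conserved across outputs:", same)
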