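"""Build genomic simulation pedigrees and check their validity conditions.

A valid pedigree delivers every founder gene copy to exactly one sample:
samples = founders, each founder segregates exactly two gametes, gamete
counts balance at every internal node, and there are no inbreeding loops.
"""

from gsped import create_gsp, validate_gsp
from gsped.gsp import GspEdge, backcross_gsp, load_gsp

f2 = create_gsp("A", "B", F2=True)
print("F2 preset:", f2)
print("  validation:", validate_gsp(f2))

combo = create_gsp("A", "B", F1=True, F2=True, BC1=True, BC2=True)
print("four-category preset:", combo)
print("  samples per category:",
      {combo.categories[s]: combo.sample_nodes[s].n_samples
       for s in combo.sample_nodes})

bc2 = backcross_gsp(2, "A", "B")
pops = [f.hap_pops[0] for f in bc2.founders.values()]
print(f"BC2 preset: {bc2.n_founders} founders "
      f"({pops.count('A')} A, {pops.count('B')} B) -> mean admixture from A "
      f"is pinned at {pops.count('A') / len(pops):.3f} by conservation")

# break the accounting on purpose: a founder may only segregate two gametes
nodes, edges = f2.node_table(), f2.edge_table()
edges.loc[0, "gametes"] = 3
report = validate_gsp(load_gsp(nodes, edges))
print("after inflating a founder edge to 3 gametes:")
print(report)
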