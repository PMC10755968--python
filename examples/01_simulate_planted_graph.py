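"""Generate a planted-community association graph and inspect its structure.

The generator is a bipartite stochastic block model: miRNAs and diseases
are assigned round-robin to shared communities, and an association is drawn
with probability p_in inside a community and p_out across communities.
"""

import numpy as np

from mdacl import PlantedGraphSpec, generate_planted_graph, sparsify

spec = PlantedGraphSpec(n_mirna=200, n_disease=150, n_blocks=2,
                        p_in=0.25, p_out=0.02, seed=0)
graph, blocks_m, blocks_d = generate_planted_graph(spec)

A = graph.matrix().astype(bool)
same = blocks_m[:, None] == blocks_d[None, :]
print(f"graph: {graph.n_mirna} miRNAs x {graph.n_disease} diseases, "
      f"{graph.n_edges} associations")
print(f"within-community density : {A[same].mean():.4f}  (planted p_in  = {spec.p_in})")
print(f"cross-community density  : {A[~same].mean():.4f}  (planted p_out = {spec.p_out})")

sparse = sparsify(graph, keep_fraction=0.3, seed=0)
deg = sparse.degrees()[0]
print(f"after keeping 30% of edges: {sparse.n_edges} associations, "
      f"{np.sum(deg == 0)} miRNAs left with no neighbor")
print("The sparse regime is where the contrastive objectives are meant to help.")
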