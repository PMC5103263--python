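"""Graphlet correlation matrix of one network and vertex similarity.

The GCM is the 16 x 16 Pearson matrix between signature columns across all
vertices: it summarises a network's local direction patterns independently
of its size.  Entries with |r| > 0.7 are called significant.
"""

import numpy as np

from digraphlets import (
    GeneratorConfig,
    cluster_vertices,
    graphlet_correlation_matrix,
    random_digraph,
    significance_mask,
    signature_matrix,
    vertex_similarity,
)

g = random_digraph(GeneratorConfig(seed=42, n=80, p_arc=0.15, p_rec=0.3))
s = signature_matrix(g)
c = graphlet_correlation_matrix(s)
mask = significance_mask(c, threshold=0.7)

print(f"network: n={g.n}, pure arcs={g.n_pure_arcs}, dyads={g.n_reciprocal_dyads}")
print(f"GCM defined entries: {int(c.defined.to_numpy().sum())} of 256")
pos = int((mask.to_numpy() == 1).sum() - 16) // 2  # off-diagonal pairs
neg = int((mask.to_numpy() == -1).sum()) // 2
print(f"significant pairs: {pos} positive, {neg} negative (|r| > 0.7)")

r = vertex_similarity(s, "v0", "v1")
print(f"signature similarity of v0 and v1: r = {r:.3f}")

order, labels = cluster_vertices(s, k=3)
print(f"Ward clustering into 3 groups, sizes: {np.bincount(labels)[1:].tolist()}")
print(
    "\nReading: in a homogeneous random digraph signature columns rise and "
    "fall together with degree, so the significant correlations are positive "
    "and the clusters simply stratify vertices by local density."
)
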