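"""Full cohort pipeline on synthetic effective-connectivity matrices.

Signed dense weight matrices (Granger-causality-like, 116 regions) are split
into excitatory (positive) and inhibitory (negative) networks, pruned to the
minimal strongest-weight proportion keeping 99% of regions connected with
minimum degree 2 ln N, and summarised per subject by a graphlet correlation
matrix; the consensus matrix then reports how many subjects share each
significant (anti-)correlation, and the regional comparison asks which
regions have more W_out wedges in the inhibitory than the excitatory network.
"""

import numpy as np

from digraphlets import (
    CohortRecord,
    GeneratorConfig,
    consensus,
    consensus_mask,
    gca_cohort,
    graphlet_correlation_matrix,
    prune,
    regional_class_comparison,
    signature_matrix,
    split_by_sign,
)

cfg = GeneratorConfig(seed=11, n=116, subjects=10)
records = []
for k, wm in enumerate(gca_cohort(cfg)):
    exc, inh = split_by_sign(wm)
    rexc, rinh = prune(exc), prune(inh)
    records.append(CohortRecord(f"sub{k:02d}", rexc.network, rinh.network))
print(
    f"subject 0 excitatory: kept {rexc.n_arcs} arcs "
    f"(proportion {rexc.proportion:.3f}), "
    f"component {rexc.criteria['largest_component']}/116, "
    f"min degree {rexc.criteria['min_degree_in_component']}"
)

gcms = [graphlet_correlation_matrix(signature_matrix(r.excitatory)) for r in records]
m = consensus(gcms, threshold=0.7)
cm = consensus_mask(m, min_percent=60)
n_pos = (np.triu(cm.to_numpy(), 1) == 1).sum()
n_neg = (np.triu(cm.to_numpy(), 1) == -1).sum()
print(f"excitatory consensus (>60% of {m.n_subjects} subjects): "
      f"{n_pos} positive, {n_neg} negative column pairs")
print(f"d_out vs d_in: positive in {m.positive_pct.loc['d_out', 'd_in']:.0f}%, "
      f"negative in {m.negative_pct.loc['d_out', 'd_in']:.0f}% of subjects")

res = regional_class_comparison(records, klass="W_out", alpha=0.05)
print(
    f"regions with more W_out in inhibitory: {res.pct_greater_inhibitory:.1f}%, "
    f"in excitatory: {res.pct_greater_excitatory:.1f}% "
    f"(CI of the mean delta: [{res.ci[0]:.2f}, {res.ci[1]:.2f}])"
)
print(
    "\nReading: shared base structure across subjects yields strong consensus "
    "entries; the regional comparison flags regions whose inhibitory-minus-"
    "excitatory wedge-count difference falls outside the 95% CI of the "
    "cohort-average difference."
)
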