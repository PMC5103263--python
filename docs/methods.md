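# Methods

## Model and definitions

The package analyses simple directed graphs *G = (V, E)* with no self-arcs.
A pair of opposite arcs {(i, j), (j, i)} is treated as a single *reciprocal*
edge, so each adjacent ordered pair has exactly one of three types relative
to its first vertex: out (+), in (−), reciprocal (∘).  The typed indicator
matrices A⁺, A⁻ = (A⁺)ᵀ and the symmetric A∘ partition the adjacency
structure; all counting is done with dense products of these matrices.

Graphlets are *induced*, weakly connected subgraphs.  On 2 and 3 nodes the
inventory is fixed: 2 two-node classes, 6 wedge classes (two adjacent pairs)
and 7 triangle classes (all three pairs adjacent), 13 connected 3-node
classes in all.  The package derives this inventory at run time by
enumerating all 4³ pair-state assignments and canonicalising over the 3!
vertex permutations (`oracle.enumerate_connected_digraphs`), rather than
hard-coding it.

Per vertex *i*, the typed counts are:

* degrees dᵅ(i) = |N_α(i)| for the three disjoint neighbour sets;
* wedges W_i(α, β) = ordered pairs (h, j) with h ∈ N_α(i), j ∈ N_β(i) and
  h, j non-adjacent.  Induced-ness matters: a closed pair is a triangle, not
  a wedge, so the raw product d_α d_β is corrected by the number of closed
  pairs (one matrix product against the undirected skeleton);
* triangles T_i(α, β, γ) = Σ_{j ∈ N_γ(i)} |N_α(i) ∩ N_β(j)|.  The i–h and
  i–j edges are typed with respect to i, the h–j edge with respect to j;
  the intersection is one entry of A_α A_βᵀ.

The 39 typed quantities reduce to the 16-dimensional signature
[d⁺, d⁻, d∘ | W_out, W_in, W_path, W_out_rec, W_in_rec, W_rec | T_acyclic,
T_cycle, T_out_rec, T_in_rec, T_cycle_rec, T_cycle_rec2, T_rec].  Class
counts are counts of *distinct* subgraphs: each wedge is counted once, at its
centre; each triangle once per incident vertex.  Since every unordered
neighbour pair appears exactly twice among the ordered typed counts, the
reduction is "sum the typed counts in each class, halve" — evenness is
asserted, and the typed-label → class mapping is itself computed by decoding
each label into a concrete 3-node graph and classifying it structurally, so
the reduction cannot drift from the isomorphism classes.  The naming of the
two single-dyad acyclic triangle classes follows the convention that
T_out_rec has the third vertex *sending* to both dyad members and T_in_rec
*receiving* from both; swapping the two names would permute two signature
coordinates and change no count.

Correctness is pinned by a brute-force oracle (exhaustive enumeration of all
vertex pairs per vertex, O(n²), capped at n = 50) that classifies every
induced 3-subgraph independently of the matrix fast path; the suite checks
exact equality on >200 seeded random digraphs across the full arc- and
reciprocity-probability grid.

## Graphlet correlation and cohort consensus

The GCM is the 16 × 16 Pearson matrix between signature columns (needs ≥ 3
vertices).  Zero-variance columns — common in sparse networks, where e.g. no
directed 3-cycle exists — make Pearson undefined; such entries are stored as
NaN with an explicit defined-mask and are *excluded* from significance,
because imputing 0 would fabricate "confidently non-significant" entries.
Significance uses strict inequalities (r > 0.7 or r < −0.7 by default), and
the cohort consensus mask keeps entries present in strictly more than 60% of
subjects; subjects with undefined entries count as not-significant there, so
the denominator stays the cohort size.

Vertex similarity is the Pearson correlation of two signature rows (scale
free, undefined for constant rows).  Heat-map ordering and flat clusters come
from Ward agglomerative clustering (scipy) on Euclidean distances of
log1p-transformed signatures; log scaling is the default because raw counts
are heavy-tailed and the degree block would otherwise dominate, and a
raw-count mode is available.

## Regional excitatory-vs-inhibitory comparison

For a chosen signature coordinate (default W_out) the per-region,
across-subject mean difference Δ_r = mean(inhibitory − excitatory) is
computed; regions are labelled by where Δ_r falls relative to a two-sided
95% confidence interval.  Two readings of "the confidence interval" are
implemented behind a strategy switch:

* `mean_ci` (default): CI of the across-region **mean**,
  mean(Δ) ± z·sd(Δ)/√R.  A region is flagged when its difference is
  inconsistent with the cohort-average difference; most regions can be
  flagged, on one side or the other.
* `population`: mean(Δ) ± z·sd(Δ), the across-region spread; only
  extreme-tail regions are flagged.

`mean_ci` is the default on statistical grounds: a planted subpopulation of
any effect size occupying ~30% of regions can never exceed mean + 1.96·sd of
the mixture distribution (its standardised distance is
(1 − p)/√(p(1 − p)) ≈ 1.53 at p = 0.3), so the population reading cannot
recover such structure, while the mean-CI reading does and also matches the
regime in which a large majority of regions end up outside the interval.

## Direction-randomisation null

`flip_directions` independently resets every connected pair to out, in or
reciprocal with probability ⅓, preserving the undirected skeleton exactly
(hence edge density, induced-ness of wedges, and all per-vertex denominators
of the normalised signature, which are skeleton quantities).  The normalised
expectation blocks — (1,1,1)/3 for degrees, (1,1,2,2,2,1)/9 for wedges,
(6,2,3,3,6,6,1)/27 for triangles — are derived in code by enumerating the 3²
and 3³ equiprobable orientation assignments and classifying each outcome.
`convergence_check` treats each flip's across-vertex mean as one independent
sample (vertices within a flip are correlated, so per-vertex samples would
understate the standard error) and reports deviations in SE units; blocks
that are degenerate everywhere (e.g. a triangle-free skeleton) are reported
with zero samples instead of being compared.

## Preprocessing of signed weight matrices

Sign splitting keeps positive entries as the excitatory network and the
magnitudes of negative entries as the inhibitory network (exc − inh
reconstructs the input).  Pruning ranks entries by descending magnitude (ties
broken by row, then column index, for determinism) and retains the minimal
top-k such that (i) the largest weakly connected component holds at least
⌈0.99·N⌉ vertices and (ii) every vertex inside it has ≥ 2 ln N distinct
neighbours.  "Connected" is read as membership in the largest weak component
and "degree" as undirected skeleton degree; vertices outside the component
(≤ 1% of N) are exempt from the degree criterion, since otherwise any
disconnected vertex would make the criteria jointly unsatisfiable.  Adding
arcs can only grow the component and the degrees, so minimal k is found by
binary search over the ranking and re-verified post hoc; infeasibility (even
at full retention) raises an error carrying the best achievable criteria.

## Synthetic data

`random_digraph(n, p_arc, p_rec)` connects each unordered pair with
probability p_arc and makes connected pairs reciprocal with probability
p_rec, else uniformly oriented — the three-parameter family over which the
counting oracle equivalence is tested.

`gca_cohort` emulates the *output shape* of a Granger-causality analysis of
resting-state fMRI: dense signed weight matrices over 116 regions (the size
of the AAL parcellation) for 40 subjects by default.  Magnitudes are
log-normal (σ = 1), signs i.i.d. positive with probability 0.5, eight hub
rows are boosted ×2 for degree heterogeneity, and each subject is the shared
base matrix plus Gaussian noise at 0.25 × the median magnitude, so cohort
consensus has common structure to find.  What it does **not** emulate:
autocorrelated BOLD time series, spatially smooth parcel covariance,
hemispheric symmetry, or any biophysics of coupling — so passing tests
demonstrate that the *procedures* (counting, correlation, consensus,
comparison, pruning) behave as specified, not that real brain cohorts would
show any particular consensus pattern.

## Numerical choices and problem sizes

All class-count arithmetic is integer; halving steps assert evenness.
Pearson values are clipped to [−1, 1] against rounding.  GCM comparisons in
tests are checked to 1e-12 against the direct formula.  Monte-Carlo checks
use 4σ/4SE bands; planted-fraction recovery uses 3σ binomial bands.  Default
test and acceptance problem sizes — random digraphs with n ≤ 12 for oracle
pinning (O(n²)-per-vertex enumeration stays instant there), n = 60 skeletons
with 2000 flips for null convergence, 116-region cohorts of 10–20 subjects
for pipeline checks — were chosen so the whole suite runs in well under a
minute while each statistical band retains comfortable power.

## Known limitations

* 4-node graphlets and position-resolved (orbit-level) counting are out of
  scope; the signature is the 16 class counts.
* Dense O(n³) matrix products are the only counting path; networks beyond a
  few thousand vertices would need a sparse neighbour-intersection path.
* No multiple-comparison correction is applied across the 120 GCM entries,
  matching the analysis convention the package reproduces.
* The pruning criteria follow one defensible reading of proportional
  thresholding (weak connectivity, undirected degree); both choices are
  config-switchable but alternatives (strong connectivity, in/out degree)
  are not implemented.
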