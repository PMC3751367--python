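# Methods

## Pipeline

Input is a probes × samples matrix of log10 expression ratios with a
sample sheet assigning each sample a condition (exactly two), a replicate
and a timepoint, plus an undirected GRN edge list and an optional
probe→gene map.  The stages are:

1. **Discretization.** A value strictly above the up-threshold (+0.2)
   yields the probe's up item, strictly below the down-threshold (−0.2)
   its down item, otherwise nothing.  The thresholds correspond to
   ~1.58-fold changes, inside the 1.5–2.0-fold band conventionally used to
   call differential expression on arrays.  Boundary values produce no
   item (strict inequalities).  Values are assumed to be log10 ratios
   already; no transform is applied.  Missing cells (`NA`) produce no item
   — a missing measurement is treated as "normal", not as an error,
   because the downstream quantity is a presence count.  Non-finite values
   are rejected with the offending probe and sample named.
2. **Integration.** Within a condition, an item's quantity at a timepoint
   is the number of replicates in which it occurs (0 < q ≤ R; zero-count
   entries are never stored).  Quantities are raw counts, not proportions;
   unequal replicate counts between conditions are allowed.
3. **Differentiation.** For each item and timepoint the condition with
   the larger integrated quantity keeps |q₁ − q₂| and the other keeps 0;
   equal quantities cancel on both sides.  This is what makes the mined
   patterns *differential*: any program shared by both conditions is
   removed here.
4. **Impact degrees.** Per probe and timepoint, a two-sided
   pooled-variance two-sample t-test compares the two conditions'
   replicate values; a gene is significant if any of its probes has
   p < α (default 0.05) at any timepoint.  No multiple-testing correction
   is applied — the degree is a neighbor count, not an inference, and the
   raw-α rule keeps it interpretable; α is exposed for users who want it
   stricter.  A gene's impact degree is its number of significant GRN
   neighbors; the gene's own significance does not enter.  Genes absent
   from the GRN have degree 0.  The same degree weights the gene's up and
   down items.
5. **Mining.** Top-k itemsets by impactful value (see below), per
   condition, on the differentiated databases.
6. **Disassembly.** Each length-l itemset contributes its C(l, 2)
   unordered item pairs; duplicates across itemsets merge with combined
   provenance (source ranks, best value).  Pair identity is
   direction-aware by default ({G↑, H↓} ≠ {G↑, H↑}); a flag collapses to
   gene-level pairs.

## Impactful value and search

The impactful value of itemset S is the average utility
i(S) = (1/|S|) Σ_{T ⊇ S} Σ_{x∈S} d(x)·q(x,T), summed over transactions
containing every member.  For a singleton this is the plain weighted
quantity sum.  Because degrees and quantities are nonnegative,

    max over (l−1)-subsets S' of i(S')  ≥  i(S)

(summing the subset inequalities over all l subsets gives
Σ i(S\{x}) ≥ l·i(S)).  This subset bound drives the search:

* All 2-itemsets are scored first.  Items with identical appearance
  patterns (presence bit vectors over transactions, held as integer
  bitmasks) form clusters; within a cluster the shared pattern is the
  support and no containment check is needed, across clusters patterns
  are intersected and disjoint pairs are skipped.
* Longer itemsets grow level-wise: a candidate of length l is scored only
  if one of its (l−1)-subsets is still *competitive*, i.e. its value is at
  least the running threshold (the k-th best value so far, 0 until k
  candidates exist).  The frontier keeps all competitive (l−1)-itemsets —
  a superset of the current top-k list — so that value ties at the
  threshold cannot drop itemsets the exhaustive ranking would keep.
* Search stops at the first level that adds nothing to the list (or at
  `max_len`).  With the bound above and the length tie-break this is
  exact, which the test suite verifies against the exhaustive oracle.

Numerical choices: utilities accumulate in exact integer arithmetic and
are divided once by the itemset length (`fractions.Fraction`), so scores,
comparisons and hence rankings are exact and platform-independent.
Ranking ties break deterministically: higher value first, then shorter
itemset, then lexicographic order of sorted item identifiers with up
before down.  Exactly k itemsets are returned; only itemsets with
strictly positive value qualify, so a sparse database may yield fewer
than k (logged).  Items whose gene has degree 0 are removed before mining
by default — by the subset bound a zero-weight item can never raise an
itemset's average value — with a flag to retain them.  Up and down items
of the same probe may co-occur in one itemset (possible when replicates
disagree); nothing forbids it.

Degenerate t-test inputs: if both groups have zero variance the statistic
is taken at its limit — p = 1 for equal means, p = 0 (significant, logged)
for unequal means.  A timepoint with fewer than two replicate values in
either condition is skipped with a warning; a probe with all timepoints
skipped is not significant.

## Control modes

* `undifferentiation` — mines the *integrated* databases (no
  cross-condition differencing) with every gene weighted 1, including
  genes absent from the GRN; this is the classical frequent-pattern-style
  control.  Degree weighting is deliberately absent, so the impact table
  is not even computed.
* `constant_degree` — differentiated databases, weight 1 for every gene
  whose real impact degree is positive and 0 otherwise; isolates the
  contribution of graded degrees beyond mere GRN membership.

## Synthetic data

`toy_example()` is a fixed 5-gene, 4-timepoint, triplicate, two-condition
dataset plus a 5-node star GRN.  A specific set of cells is constrained so
that the pipeline reproduces an exact reference set of quantities
(integrated q(G5↓,T1)=3; differentiated q(G4↑,T4)=2 vs 0 and
q(G5↓,T4)=3 vs 0; significant genes {G1,G3,G4,G5}; degrees d(G1)=3,
d(G5)=1; item value i(G5↑)=3; itemset value i({G1↑,G5↑})=3.5); all other
cells are free and fixed at values that create no items.  Significance of
the free genes is pinned with zero-variance mean shifts inside the
(−0.2, 0.2) band, which trigger the degenerate t-test rule without
touching the transaction databases.  The in-source table marks which
cells are constrained.

`simulate()` generates seeded datasets with planted structure:

* **Differential modules** (default 2 modules of 4 genes): co-regulated
  gene sets, alternating up/down, each active in its own contiguous half
  of the time course, planted in the treatment condition only.  Each
  module-gene replicate crosses the threshold with probability
  `p_signal` (default 0.9) at magnitude 0.5 log10 units.
* **A shared program** (default 12 genes): co-up-regulated identically in
  *both* conditions at all timepoints.  Real two-condition experiments are
  dominated by expression common to both arms; this is the structure the
  differentiation step exists to cancel, and without it the
  undifferentiation control would see nothing but the planted modules and
  trivially tie the full method.
* **Background**: zero-mean Gaussian values (sd 0.05 log10 units — well
  inside the band) with a 0.02 per-cell probability of a spurious
  threshold crossing at ±0.35, exercising noise robustness.
* **GRN**: within-module edges with probability 0.9, all other pairs with
  probability 0.02, as a simple undirected graph over all genes.

Defaults (50 genes, 8 timepoints, 3 replicates) keep full runs under a
second while leaving all mechanisms active.  The generator emulates the
statistical skeleton of a replicated two-condition time course — it does
not emulate probe-affinity effects, batch structure, heteroscedastic
array noise or realistic GRN topology, so passing recovery tests
demonstrates correctness of the method's logic, not performance on real
microarray data.  Ground truth lists each module's genes, direction and
active timepoints plus the within-module item pairs;
`module_pair_recall()` scores a result set against it (pairs pooled over
both conditions' top-k lists).

## Design decisions at genuinely open points

* The level-wise search is reconstructed from the subset bound and the
  cluster/intersection treatment of 2-itemsets; its correctness is
  anchored to the exhaustive oracle (exact list equality across seeded
  random instances), not to any particular pseudocode.
* Tie handling at rank k: exactly k itemsets are returned under the
  deterministic tie-break above (value ties straddling the boundary could
  alternatively admit more than k; determinism was preferred).
* Equal integrated quantities differentiate to zero on both sides —
  the only reading consistent with assigning the difference to the
  dominant condition.
* Significance is computed per probe, and a gene is significant if any of
  its probes is (items are probe-level; degrees are gene-level).
* Directed or duplicated source edges collapse to simple undirected
  adjacency (neighbor counting is orientation-free); self-loops are
  dropped.
* The undifferentiation control keeps *all* items at weight 1, including
  genes outside the GRN, since it is defined by ignoring the degree
  machinery altogether.

## Limitations

* Inputs must be pre-normalized log10 ratios; no background correction,
  normalization or probe summarization is performed.
* The t-test assumes equal variances (pooled); with 2–3 replicates per
  condition this is a pragmatic, low-power screen, and the uncorrected
  per-timepoint α means the significant-gene set has a liberal false
  positive rate — tolerable because it only enters as a neighbor count.
* Runtime grows with the number of competitive itemsets; pathological
  databases with thousands of value-tied itemsets blunt the pruning
  (the exhaustive oracle is guarded at 22 items for this reason).
* Mined relationships are co-occurrence patterns, not causal regulatory
  claims; external evaluation (literature, enrichment) is out of scope.
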