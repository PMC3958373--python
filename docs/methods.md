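# Methods

## Model

`rfcluster` detects clusters in an undirected network G = (V, E) by
composing a fuzzy equivalence relation with rough-set approximations.

**Similarity relation.** The fuzzy relation R assigns each node pair a
grade in [0, 1]: 1 on the diagonal, 0 for non-adjacent pairs, and for
adjacent pairs a shared-neighbor statistic on closed neighborhoods
Γ(x) = N(x) ∪ {x}.  Three kernels are available — cosine
|Γ(u)∩Γ(v)|/√(|Γ(u)|·|Γ(v)|) (default), Jaccard
|Γ(u)∩Γ(v)|/|Γ(u)∪Γ(v)|, and min-overlap
|Γ(u)∩Γ(v)|/min(|Γ(u)|,|Γ(v)|) — all satisfying the same contract:
reflexive, symmetric, zero off the edge set, and increasing in the
number of shared neighbors at fixed degrees.  Using *closed*
neighborhoods guarantees a strictly positive grade for every adjacent
pair (the endpoints themselves are always shared), which keeps the
relation faithful to the edge set.  For weighted networks the grade of
an edge is its confidence weight; weights above 1 are rescaled by the
maximum, weights already in [0, 1] (confidence scores) pass through.

**Transitive closure and λ₁-cut.** R is reflexive and symmetric but not
max-min transitive.  Its transitive closure t(R) — computed by repeated
max-min squaring, reaching the fixpoint in at most ⌈log₂(n−1)⌉ steps —
is the smallest fuzzy equivalence relation containing R, and
t(R)(u, v) equals the max-min path capacity: the maximum over u–v paths
of the minimum grade along the path.  Cutting t(R) at level λ₁
(grade ≥ λ₁, compared with absolute tolerance 1e−12) yields a genuine
partition.  Because of the path-capacity characterization, the classes
of the cut are exactly the connected components of the graph keeping
raw-similarity edges with grade ≥ λ₁; `lambda_cut` exploits this and
runs a single sparse component search, so the O(n³ log n) closure is
never needed in the clustering pipeline (it remains available, and the
equivalence of the two routes is asserted against an independent
breadth-first-search oracle in the tests).

λ₁ defaults to a data-driven choice: with S⁺ the multiset of positive
pairwise grades (each unordered pair once), λ₁ is the mean of the
members of S⁺ that exceed mean(S⁺) — the mean of the above-mean
similarities — falling back to mean(S⁺) when all grades are equal.
Restricting to positive grades matters: in a sparse network the mean
over all n(n−1)/2 pairs is close to zero and would produce a single
giant class.  λ₁ can also be fixed explicitly.

**Rough assignment.** Each cut class X is refined into a lower
approximation (certain, exclusive members) and a boundary region
(shared members).  The node-to-set similarity S(u, X) is the mean grade
from u to the members of X other than u itself (a maximum-grade variant
is selectable); S(u, {u}) = 1 by convention.  For each node u the
similarities sᵢ to the candidate classes are computed, and with
s* = maxᵢ sᵢ the set T(u) = {i : sᵢ/s* ≥ λ₂} collects every class close
enough to the best.  |T(u)| ≥ 2 places u in the boundary of each class
in T(u) and in no lower approximation; |T(u)| = 1 places u in the lower
approximation of the argmax class, which may differ from u's own cut
class — the ratio rule overrides the cut.  The output satisfies the
three rough-set properties by construction (at most one lower
membership; lower ⊆ upper; a node in no lower approximation lies in at
least two boundaries), and `RoughCover` re-validates them on every
construction.

*Candidate classes exclude singletons.*  A singleton cut class is an
unassigned node, not a module, and treating it as a candidate breaks
the assignment in both directions: a node's own singleton always wins
the argmax (S = 1 by the convention above), stranding every bridge node
in its own class, and a foreign singleton {w} attracts its neighbors
because the single grade R(u, w) outweighs the mean grade to a genuine
multi-member class.  On 300-node planted benchmarks the literal
all-classes rule fragments the communities into over a hundred shards;
restricting candidates to classes with at least two members restores
clean recovery while leaving every multi-member class's treatment
unchanged.  A node with zero similarity to every candidate falls back
to the lower approximation of its own cut class (this covers isolated
nodes and networks whose cut is entirely singleton).

λ₂ defaults to 0.7.  The threshold is a first-class flag: λ₂ → 1 admits
boundary members only under near-exact ties, and lowering λ₂ never
shrinks any boundary region (asserted as a property test).

**Merging.** The reported clusters are the upper approximations with
fewer than `min_size` members dropped (default 2: singletons are not
complexes).  Highly redundant clusters are then merged: while any pair
has overlap score ω(A, B) = |A∩B|²/(|A|·|B|) ≥ 0.64, the
highest-scoring pair (ties: smaller union, then lexicographic) is
replaced by its union.  The 0.64 default corresponds to an intersection
of at least 80% of the size of two equal-size sets.  Each merge reduces
the cluster count by one, so the loop terminates, and on output every
pairwise ω is below the threshold.  Final output order is descending
size, then lexicographic, for diffable files.

## Evaluation metrics

Given known complexes K (n families) and predicted complexes P (m
families), the contingency table T has T_ij = |Kᵢ ∩ Pⱼ|; by the usual
convention predicted complexes are first intersected with the union of
known-complex members, so PPV reflects prediction errors rather than
annotation gaps (raw mode by flag).

* matching at ω ≥ 0.25 (half the members of two equal-size complexes):
  precision = matched predicted / m, recall = matched known / n, F1
  their harmonic mean;
* Sn = Σᵢ maxⱼ T_ij / Σᵢ |Kᵢ|, PPV = Σⱼ maxᵢ T_ij / Σᵢⱼ T_ij,
  Acc = √(Sn·PPV);
* separation: sep_ij = (T_ij/Σⱼ′T_ij′)·(T_ij/Σᵢ′T_i′j), summed and
  averaged over rows (Sep_k) and columns (Sep_p), with
  Separation = √(Sep_k·Sep_p); zero-marginal terms contribute 0.
  Note that a truth family with shared members cannot reach
  separation 1 even under perfect recovery, since a shared node
  occupies several rows and columns of T;
* partition NMI = 2·I(X;Y)/(H(X)+H(Y)) with natural logarithms (the
  ratio is base-invariant), 0·log 0 = 0, two trivial partitions → 1,
  exactly one trivial → 0.  Overlapping inputs are rejected rather than
  silently flattened; overlapping-NMI variants are out of scope.  For
  scoring an overlapping clustering at partition level,
  `RFCResults.to_partition()` assigns each node to the final cluster
  with the highest node-to-set similarity (nodes dropped by the size
  filter keep singleton classes).

All optimized implementations are cross-checked in the tests against
literal double-loop oracles on 200 random family pairs, and NMI against
scikit-learn's arithmetic-normalized implementation.

## Synthetic benchmarks

`planted_overlap_graph(sizes, p_in, p_out, n_shared, seed)` plants
communities over sum(sizes) − n_shared nodes, the shared nodes being
members of the first two communities; pairs sharing a community connect
with probability p_in, all others with p_out.  It is the desk-scale
stand-in for overlap-recovery experiments: with sizes (15, 15),
p_in = 0.9, p_out = 0.02 and one shared node, the pipeline at default
parameters reports the shared node as overlapping in ≥ 90% of seeds.

`lfr_like(n, avg_deg, max_deg, size_min, size_max, mixing, ...)`
emulates the LFR benchmark family: degrees from a truncated power law
with exponent 2 (minimum degree chosen so the expected mean matches
`avg_deg`), community sizes uniform in [size_min, size_max] (defaults
20–50; generator defaults n = 1000, avg_deg = 20, max_deg = 50), and
each node splitting its degree into an internal fraction 1 − u, shared
evenly among its communities, and an external fraction u.  Edges are
realized Chung-Lu style (probability proportional to the product of
stub counts), internally per community and externally between nodes
sharing no community, so the realized mixing tracks the requested u
closely (within ~0.02 at u = 0.3) without reproducing the published
LFR software's exact configuration-model internals.  Designated overlap
nodes receive a fixed number of distinct community memberships.

What the generators do not emulate: the degree–community-size
correlation structure of real PPI data, confidence-weight noise
models, and LFR's exact rewiring; recovery results on them demonstrate
algorithmic correctness under planted structure, not performance on
experimental interactome data, which requires externally downloaded
networks and gold standards and is supported as an ordinary
edge-list/cluster-file workflow.

Test and benchmark problem sizes (n ≤ 300 networks, n ≤ 60 for the
closure oracles, 50 seeds for the overlap-recovery rate, 10 for the
low-mixing NMI, 3 per mixing level for the trend) keep the whole suite
in a few seconds on one CPU while leaving the sampling error of each
asserted rate well inside its margin.

## Numerical and degenerate-input choices

* All grade comparisons at thresholds use absolute tolerance 1e−12 and
  closed (≥) semantics, so a cut at exactly 1.0 keeps duplicated
  neighborhoods and ties at exactly λ₂ count as overlap.
* Duplicate edges keep the maximum weight (confidences, not counts);
  self-loops are dropped with a logged count; node identifiers are
  case-sensitive opaque strings; node order is first-appearance order,
  and all pipeline stages are invariant to it (tested).
* Empty networks, empty clusters, empty sets in ω, all-zero contingency
  tables and out-of-range thresholds raise `ValueError` rather than
  returning NaN.
* An edgeless network has no positive pairwise similarity and no usable
  automatic λ₁; this is reported as a degenerate input.

## Known limitations

* The similarity matrix is dense (O(n²) memory): appropriate up to a
  few thousand nodes, which covers the intended PPI scale; the
  clustering path avoids the cubic closure but not the quadratic
  relation.
* Merging is greedy best-pair-first to a fixpoint; it is deterministic
  and order-independent, but not a global optimum over merge sequences.
* The automatic λ₁ is a summary of the similarity distribution; on
  networks whose intra-cluster similarities are strongly heterogeneous
  it can over-split a cluster into cores whose mutual overlap stays
  below the merge threshold, leaving two clusters where one was
  planted.  Lowering λ₁ or the merge threshold trades this against
  under-splitting.
* NMI is partition-level only; overlapping outputs are scored either
  through the matching/Sn/PPV/separation suite or via the induced
  partition.
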