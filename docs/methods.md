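# Methods

## Model

`complexwalk` scores candidate protein complexes for a query disease by
simulating a random walker on a three-layer heterogeneous network. Nodes
are l diseases, m proteins and n complexes, ordered (diseases, proteins,
complexes), each block sorted by identifier. The symmetric weight matrix is

    H = [ D   A   0 ]
        [ Aᵀ  P   B ]
        [ 0   Bᵀ  0 ]

Complexes carry no edges among themselves and no direct disease edges:
every disease→complex path passes through member proteins, which is what
lets the steady state divide a shared protein's outgoing mass among the
complexes it belongs to.

**Disease layer (D).** Built from a phenotype similarity profile, a
symmetric matrix with entries in [0, 1] whose diagonal is ignored. Two
strategies: k-nearest neighbours (default, k = 15) and a similarity
threshold (edge iff s ≥ δ, default δ = 0.35). The k-NN rule is the *union*
symmetrization — an edge exists when either endpoint selects the other —
which matches undirected-network edge counts between ⌈lk/2⌉ and lk; a
mutual-selection variant is available (`knn_mode="mutual"`). Neighbour
ties at the k-th similarity break by lexicographic disease id so builds
are reproducible. Edges carry the similarity value by default
(`weighted=False` gives unit weights).

**Protein layer (P).** A generic PPI network restricted to the tissue the
query disease is most associated with (argmax of the disease–tissue score
row; ties go to the first tissue in the file; diseases without tissue
scores fall back to the generic network). Node removal (NR) deletes all
edges of non-expressed proteins but keeps the nodes, so indices into H are
identical across tissues; edge reweighting (ERW, default) multiplies each
edge weight by rw per non-expressed endpoint (1, rw, rw² for 2/1/0
expressed endpoints), rw = 0.1. Expression scores are binarized at
`expr_cutoff` (default 0.5, i.e. 0/1 calls pass through unchanged).

**Connectors.** Every known disease–protein association becomes an edge of
weight α (> 0, default 1); every complex membership an edge of weight β
(> 0, default 1). Complexes with no member mappable to the protein layer
are dropped with a warning. Associations may attach to proteins that are
isolated in the tissue network; the walk then simply finds no onward PPI
edge there.

**Walk.** Rows of H are normalized to a transition matrix (t_ij = h_ij /
Σ_j h_ij). All-zero rows (isolated nodes) are left as zero rows and
reported as *dangling*: mass entering them leaks out of the system between
restarts. We deliberately add no teleportation for dangling rows — the
restart term γ·q⁽⁰⁾ re-injects mass every step, and the final score
normalization cancels any global deficit. The iteration

    q(t+1) = (1 − γ) Tᵀ q(t) + γ q(0)

starts from the indicator vector of the query disease and stops when
‖q(t+1) − q(t)‖₂ ≤ ε (ε = 1e-5, "≤" rather than "<"). Because
(1 − γ)Tᵀ is a contraction for γ > 0, the fixed point is the unique
solution of (I − (1 − γ)Tᵀ) q = γ q⁽⁰⁾; a dense direct solver of that
system is shipped as an independent oracle and is practical up to a few
thousand nodes. A cap of 10,000 iterations turns non-convergence into a
detectable error instead of a hang. With γ = 1 the walk collapses to the
restart vector and complex scoring fails loudly (no complex mass), by
design.

**Scores and ranking.** s_i = q_{l+m+i} / Σ q_{l+m+i}; scores sum to 1.
Candidates are ranked in nonincreasing score order. Tied scores receive
the mean of the positions they span (mid-rank) — unbiased for MR/MRR/AUC —
alongside a deterministic id-ordered display position.

**Naive baseline.** Protein relevance is taken from the same restart walk
on the two-layer disease–protein sub-network; a complex then scores the
plain sum of its members' mass. A protein in several complexes is counted
once per complex, whereas the three-layer walk divides its outgoing mass
among them — the aggregation rule is the only difference between the two
methods, which isolates exactly that design choice in comparisons.

## Validation harness

A complex is associated with a disease iff at least one member protein is
annotated to it. Each leave-one-out run removes *all* disease–protein
edges of the query disease, reruns the full pipeline, and records the rank
of the test complex among all n candidates (full-length lists, so that the
mean relative rank equals mean rank / list length). By default
each test complex yields one run whose query is its lexicographically
smallest associated disease; `one_run_per_complex=False` (CLI
`--pair-runs`) makes one run per (complex, disease) pair instead. If
masking disconnects the query from the complex layer entirely, the run is
kept with the test complex at the worst rank (flagged) and controls at the
tied mid-rank — conservative against the method, and N stays fixed.

Criteria: TOP and PRE (count/fraction of runs ranked first), MR and MRR,
and a rank-ROC whose sensitivity at threshold θ is the fraction of test
relative ranks ≤ θ and whose specificity is the fraction of control
relative ranks > θ. Thresholds are every distinct observed relative rank
plus {0, 1}; the area uses trapezoid integration, which makes the AUC
exactly the tie-corrected Mann–Whitney U statistic normalized by
(#tests · #controls) — an identity the tests verify exhaustively on small
inputs. The expected top-t count of a uniformly random ranker, N·t/n, is
provided for reference.

**Permutation null.** The null for the harness permutes the disease labels
of the association pairs while keeping the test cases derived from the
*true* pairs. Under this label shuffling a truly associated complex is
exchangeable with its controls and the expected AUC is 0.5. (Setting the
generator's `signal_strength` to 0 instead yields AUC systematically
*below* 0.5 at desk scale: conditioning a test complex on an annotation
that the leave-one-out mask then removes excludes it from the pool of
coincidentally boosted candidates. At a few dozen candidate complexes that
selection effect is worth several AUC points; at catalogue scale it is
negligible. Single-shuffle AUCs at N ≈ 60 runs also scatter by about
±0.06, so null checks average a few shuffles per benchmark instance.)

## Perturbation experiments

Robustness is probed by deleting a fraction of existing edges of one type
uniformly at random, or inserting the same count of uniformly random new
pairs of that type (added edges get the mean weight of their type,
preserving the layer's weight scale; a flag allows overriding). The four
types are disease–disease, disease–protein, protein–protein and
protein–complex. Disease–disease edges exist only in the *built*
similarity layer, so that type perturbs the constructed graph and is
installed into the model as an override; the other three perturb their
source tables. Ground truth is fixed: validation cases always derive from
the unperturbed associations, so noise degrades the network but never
redefines what counts as a correct answer. Each grid cell averages
metrics over seeded repeats (default 5); the per-repeat stream depends
only on (master seed, edge type, fraction, repeat index), so the first
repeat is identical whatever the repeat count, the whole table is
bit-reproducible from the master seed, and the zero-fraction cell is the
identity perturbation and reproduces the baseline bit-exactly.

## Synthetic data generator

The generator emulates the structure (not the content) of the real data
sources so the full pipeline is testable offline. Diseases fall into
clusters with within-cluster similarity ~ U(0.6, 0.9) and between-cluster
~ U(0, 0.3); complexes are partitioned among the same clusters and draw
members from a cluster-specific protein pool (complexes of one functional
module share subunits, unrelated complexes rarely do); each disease draws
`assoc_per_disease` annotated proteins from its own cluster's complexes
with probability `signal_strength`, else uniformly from all proteins; the
PPI is an Erdős–Rényi background at the configured mean degree plus
within-complex densification (edge probability 0.7); expression calls are
i.i.d. Bernoulli per (tissue, gene); disease–tissue scores peak
(U(0.7, 1.0) vs U(0, 0.5)) on one planted tissue per cluster. All
randomness flows from one master seed through named substreams, so
regeneration is byte-identical.

Default study conditions: l = 120 diseases in 6 clusters, m = 400
proteins, n = 60 complexes of 4–6 members (≈ 4.6 members per complex, the
CORUM-core ratio), PPI mean degree 8 (the HPRD ratio), 2 annotations per
disease, signal strength 0.9, expression density 0.6, 6 tissues. Cluster
size (20) deliberately exceeds the default k = 15 so that nearest-neighbour
lists stay within a phenotype cluster, which is what exercises the
information-borrowing behaviour the disease layer exists for.

What the generator does *not* emulate: realistic PPI degree distributions
(no hubs), annotation sparsity (every synthetic disease is annotated;
in real catalogues most are not), correlated expression between complex
members, and text-mining noise in disease–tissue scores. Passing tests
therefore demonstrate correct mechanics and recoverable planted signal at
desk scale, not performance on any real disease catalogue. Relative-rank
granularity at n = 60 also inflates the variance of AUC-based checks
compared to catalogue-scale lists.

## Numerical and design choices

- Duplicate undirected edges collapse to the maximum weight (strongest
  evidence wins), self-loops are dropped, and all tables are TSV with a
  header; identifiers are opaque strings and no symbol mapping is done.
- Asymmetric similarity input is symmetrized by averaging, with a warning.
- The protein universe is the union of PPI nodes, annotated proteins and
  complex members, so annotated-but-isolated proteins keep a stable index.
- Convergence uses the L2 norm; ε = 1e-5 puts the iterate within
  (1−γ)/γ · ε of the fixed point, i.e. ≤ 9ε for γ ≥ 0.1 — the oracle
  tests allow 10ε.
- Mid-rank ties everywhere; the TOP-t counters use the mid-rank value.
- Layer caches: the disease layer, per-tissue PPI layers and membership
  links are built once per model; a leave-one-out run only rebuilds the
  disease–protein connector and the block matrix, which keeps a full
  cross-validation on the default benchmark under a second.
- Problem sizes in the shipped test-suite and acceptance benchmarks
  (default generator scale, 100 oracle networks of ≤ 60 nodes, 5 benchmark
  seeds, 5 perturbation repeats) were chosen as the package's standard
  desk-scale study; all of them run in well under a minute each on one
  core.

## Known limitations

- Dense similarity matrices: the profile is held dense, fine for thousands
  of diseases, wasteful beyond that.
- Single-query walks only; no batched multi-disease propagation.
- No statistical test between methods is provided (the comparison table
  reports criteria side by side only).
- The permutation null is the only calibration device; no degree-preserving
  rewiring null is implemented.
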