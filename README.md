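# complexwalk

Prioritization of **disease-related protein complexes** by a random walk
with restart on a tissue-specific disease–protein–complex heterogeneous
network.

Many inherited diseases are caused not by a single gene but by the failure
of a protein complex — a set of proteins bound into one functional unit.
Given a query disease, `complexwalk` ranks a collection of candidate
complexes (e.g. a CORUM-like catalogue) by how strongly each is associated
with the disease, using only guilt-by-association evidence: phenotype
similarity between diseases, protein–protein interactions restricted to the
disease-relevant tissue, known disease–protein annotations, and complex
membership. It is intended for computational biologists studying disease
mechanisms at the level of functional modules rather than single genes.

## The model

A three-layer network is built with block weight matrix

```
H = | D   A   0 |        D  (l×l)  disease–disease similarity layer
    | Aᵀ  P   B |        P  (m×m)  tissue-specific PPI layer
    | 0   Bᵀ  0 |        A  (l×m)  disease–protein links, weight α
                         B  (m×n)  protein–complex links, weight β
```

The disease layer links each disease to its *k* nearest phenotype
neighbours (default *k* = 15, union rule, similarity-weighted edges), or
alternatively thresholds the similarity at δ. The PPI layer is made
tissue-specific either by removing non-expressed proteins (NR) or, by
default, by multiplying each edge weight by `rw = 0.1` per non-expressed
endpoint (ERW); the query's tissue is the one with the highest
disease–tissue association score. Complexes are connected only to their
member proteins.

Rows of `H` are normalized to a transition matrix `T` (t_ij = h_ij / Σ_j
h_ij) and the restart walk

```
q(t+1) = (1 − γ) Tᵀ q(t) + γ q(0),      γ = 0.5,
```

starting from the query disease, is iterated until ‖Δq‖₂ ≤ ε = 1e-5. The
steady-state mass on complex node *i* is renormalized into a score
`s_i = q_{l+m+i} / Σ_i q_{l+m+i}` and candidates are ranked in
nonincreasing score order.

The evaluation harness performs leave-one-out cross-validation — all
disease–protein edges of the query are removed before re-ranking the truly
associated complex — and reports TOP/PRE (runs ranked first), MR/MRR (mean
and mean relative rank), and a rank-ROC AUC in which test complexes are
compared against all control complexes by relative rank. A naive baseline
(sum of member-protein scores, double-counting shared proteins), a
label-shuffling permutation null, parameter sweeps, and edge
addition/removal robustness experiments are included, together with a
synthetic-data generator that plants a recoverable disease→complex signal
so the whole pipeline is testable without any external download.

## Worked example

```python
import complexwalk as cw

bundle = cw.worked_example()          # 4 diseases, 6 proteins, 3 complexes
model = cw.DiseaseComplexModel(bundle)
res = model.fit("d1")
print(res.summary())
```

```
Disease-protein-complex prioritization
======================================================
query disease      : d1
method             : rwr
tissue             : t1
candidates ranked  : 3
masked associations: False
strategy           : knn (k=15, delta=0.35, weighted=True), ppi=erw (rw=0.1)
walk               : gamma=0.5, alpha=1.0, beta=1.0, epsilon=1e-05
convergence        : 12 iterations, |dq| = 8.267e-06
------------------------------------------------------
top 3 candidates:
     1  c1               0.833610
     2  c3               0.117058
     3  c2               0.049332
```

Disease `d1` is annotated to protein `p1`, a member of complex `c1`, so
`c1` collects 83% of the complex-layer steady-state mass and ranks first;
`c3` comes second because `d1`'s phenotype neighbours are annotated to its
members. The walk converged in 12 iterations with a final L2 change below
the 1e-5 tolerance.

The same pipeline is scriptable from the shell:

```sh
complexwalk synth --out data --seed 1
complexwalk evaluate --inputs data --out results
complexwalk prioritize --inputs data --query d0001 --out results
complexwalk robustness --inputs data --seed 1 --repeats 5 --out results
complexwalk sweep --inputs data --param gamma --values 0.1,0.5,0.8 --out results
```

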