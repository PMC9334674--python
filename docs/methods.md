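# Methods

## Problem setting

Experimentally supported miRNA–drug interactions (MDIs) form a sparse
bipartite network: drugs D = {d₁, …}, miRNAs M = {m₁, …}, and edges
E ⊂ D × M with weight w_ij = 1 for a known interaction.  The package treats
MDI prediction as link prediction on this network: given the known edges,
rank unobserved (drug, miRNA) pairs by their probability of interacting.
Each pair is represented by two complementary feature families:

* **topological features** learned from the network itself, and
* **attribute features** computed from the entities' own descriptions —
  the drug's SMILES string and the miRNA's nucleotide sequence — which are
  available even for entities with no known interactions (cold start).

## Bipartite network embedding

The embedding assigns each drug a vector d⃗ᵢ ∈ ℝᵗ and each miRNA a vector
m⃗ⱼ ∈ ℝᵗ (t = 64 by default) by jointly maximizing

L = α·log O₂ + β·log O₃ − γ·O₁

with three terms:

* **Explicit relations** (O₁): the empirical edge distribution
  P(i,j) = w_ij / Σw is reconstructed by P̂(i,j) = σ(d⃗ᵢᵀm⃗ⱼ), σ the logistic
  function, and their KL divergence Σ P·log(P/P̂) is minimized.
* **Implicit relations** (O₂, O₃): the bipartite graph is projected onto two
  weighted homogeneous networks by the co-HITS construction
  (w^D = W·Wᵀ for drugs, w^M = Wᵀ·W for miRNAs; W the |D|×|M| weight
  matrix).  Truncated random walks on each projection produce corpora of
  same-type node sequences, and a skip-gram objective with negative sampling
  pulls frequently co-occurring nodes together via context vectors θ⃗ (drugs)
  and ϑ⃗ (miRNAs).

Walk generation is biased and self-adaptive ("richer get richer"): node v
seeds `clamp(round(maxT · centrality(v)), minT, maxT)` walks, with
centrality given by HITS on the projection (for a symmetric matrix, the
dominant eigenvector, L1-normalized).  Each walk step continues with
probability 1 − p_stop and then moves to a neighbor with probability
proportional to the off-diagonal projection weight, so sequences have
variable length ≥ 1.  Projection self-loops (Gram diagonal) are retained in
the matrix but excluded from the transition kernel: a self-transition
contributes no context information.

Optimization is stochastic gradient ascent with pure per-sample updates.
For an edge (i, j):

d⃗ᵢ ← d⃗ᵢ + λ·γ·w_ij·(1 − σ(d⃗ᵢᵀm⃗ⱼ))·m⃗ⱼ (and symmetrically for m⃗ⱼ),

and for a center node with positive context z⁺ and sampled negatives z⁻:

d⃗ᵢ ← d⃗ᵢ + λ·α·Σ_z (I(z) − σ(d⃗ᵢᵀθ⃗_z))·θ⃗_z, θ⃗_z ← θ⃗_z + λ·α·(I(z) − σ(d⃗ᵢᵀθ⃗_z))·d⃗ᵢ,

with I(z) = 1 for the positive and 0 for negatives (β and ϑ⃗ on the miRNA
side).  All gradients in one step are evaluated at the pre-update center
vector.  The test suite verifies every rule against finite-difference
gradients of its objective term.

### Hyper-parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| dim t | 64 | standard embedding size for networks of 10²–10³ nodes |
| γ (explicit) | 1.0 | the explicit term is the primary link-prediction signal |
| α, β (implicit) | 0.1 | clusters same-type nodes without overwhelming the explicit term |
| λ (learning rate) | 0.025 | conventional skip-gram step size |
| epochs | 50 | loss plateaus well before this on 10³-edge networks |
| window | 5, negatives ns | 4 | conventional skip-gram choices |
| maxT / minT | 32 / 16 | on small networks with near-uniform centrality each node must seed enough walks for the skip-gram terms to see every neighborhood; the clamp keeps the centrality bias |
| p_stop | 0.15 | mean walk length ≈ 1/p_stop ≈ 6.7 |
| init | entries ~ N(0, 1/t) | rows start near unit norm, σ(d⃗ᵀm⃗) ≈ 0.5, so early gradients are informative |

These step sizes are calibrated for interaction networks in the
10²–10³-node range: each epoch supplies few per-node SGA samples there, so
smaller classical settings (tuned on 10⁵-edge recommender graphs) leave the
objective effectively untrained.  All values are overridable per run.

Negative sampling defaults to unigram sampling with probability ∝
degree^0.75 (standard skip-gram practice; degree = off-diagonal weighted
degree in the projection).  An LSH-bucket strategy — random-hyperplane
hashing of the current embeddings, drawing negatives from buckets other
than the center's — is available behind `negative_strategy="lsh"`.

Cold-start nodes (no edges in the training graph) receive all-zero
topological vectors on output: the network carries no information about
them, and the zero block lets the classifier fall back on attributes.

## Attribute features

* **miRNAs**: normalized k-mer frequencies (k = 3 over {A, C, G, U}; 64
  entries summing to 1), computed with a stride-1 sliding window.  Input is
  case-insensitive and DNA spelling (T) is mapped to U; other characters are
  rejected rather than imputed.
* **Drugs**: the 166 defined MACCS substructure keys as a Boolean vector
  (computed with RDKit; the conventional unused bit 0 of the 167-bit layout
  is dropped).

## Classifier

A pair (dᵢ, mⱼ) is encoded as the fixed concatenation
[MACCS(166) ⊕ drug-topology(t) ⊕ k-mer(64) ⊕ miRNA-topology(t)] — 358
dimensions at t = 64 — and classified by a dense network with one hidden
layer of 256 rectified units and a sigmoid output, trained with binary
cross-entropy under Adam (scikit-learn `MLPClassifier`; learning rate 1e-3,
batch size 32, 50 epochs by default).  The network carries L2 weight decay
1.0 by default (the penalty is scaled by 1/n internally): with ~10⁵ weights
against ~10³ training pairs per fold, unregularized training memorizes fold
noise and measurably degrades held-out ranking.  The interaction label is the strict
threshold score > 0.5.  `feature_mode` masks feature blocks
(`attribute_only`, `topology_only`) for ablation runs.

## Evaluation protocol

Negatives are drawn once per dataset, uniformly from unconfirmed pairs, in
equal number to the positives; positives and negatives are then partitioned
separately into five folds.  Per fold, the embedding is retrained on the
fold's training edges only (test-fold nodes may become isolated), so no
network-derived feature ever sees a test interaction.  Metrics: accuracy,
sensitivity TP/(TP+FN), specificity, precision, MCC, trapezoidal ROC-AUC
and step-wise AUPR, reported per fold with mean and population SD.
A label-permutation control (labels shuffled after feature assembly) checks
that the pipeline sits at chance absent real signal.

Baselines on identical folds: drug-, miRNA- and neighbor-based
collaborative filtering (Pearson similarity; M′_drug = P_drug·M/n_d,
M′_miRNA = M·P_miRNAᵀ/n_m, neighbor = their mean), truncated-SVD matrix
factorization (score = rank-k reconstruction, k = 8 default), and two-way
resource diffusion.  CF/diffusion similarities are computed from
*training-fold* interaction profiles by default (attribute-based similarity
is available as an option); both choices avoid test-edge leakage.  For the
diffusion baseline the pair score combines both resource directions,
S = (R_D·A + A·R_Mᵀ)/2 with the weighted adjacency A^w defaulting to A —
the resource equations leave both the combination rule and A^w open, so
these are package choices, overridable by passing A^w explicitly.

## Synthetic benchmark and what it can show

The fixture generator emulates the regimes the method assumes: a sparse
bipartite network with recoverable structure (a planted block model: nodes
assigned round-robin to blocks, edge probability p_within = 0.3 inside a
block, p_between = 0.01 across, 60 drugs × 120 miRNAs in 2 blocks by
default), miRNA-like random sequences (20–25 nt, uniform over {A,C,G,U}),
and valid drug-like SMILES drawn from a built-in list.

Two consequences of this design matter when reading benchmark numbers:

* **Attributes are pure noise here.**  Sequences and SMILES are assigned
  independently of the planted blocks, so the attribute blocks carry no
  signal about interactions.  Attribute-only AUC is expected at chance, and
  appending attributes to topology can only add variance on this generator —
  unlike on real data, where chemistry and sequence similarity correlate
  with shared targets.
* **Recovery has a hard ceiling.**  Within a block, edges are i.i.d.
  Bernoulli, so a held-out edge is statistically indistinguishable from a
  within-block non-edge.  With uniform negatives the Bayes-optimal AUC is
  q(1−r) + ½[qr + (1−q)(1−r)], where q = p_w/(p_w+p_b) is the within-block
  fraction of positives and r = (1−p_w)/((1−p_w)+(1−p_b)) the within-block
  fraction of negatives — ≈ 0.777 at the default densities (and ≈ 0.95 at
  p_within = 0.9, which the link-prediction recovery test uses).  Every
  method, including an oracle that knows the true blocks, is capped there;
  proximity to the ceiling, the gap to the permutation null, and the
  relative ordering of methods are the meaningful readouts, not absolute
  AUC.

Passing the benchmark therefore demonstrates that the pipeline recovers
plantable topological structure without leakage and at the correct noise
floor; it says nothing about performance on real MDI data, whose attribute
signal and degree heterogeneity the generator deliberately does not model.

## Numerical choices and degenerate inputs

* Sigmoid arguments are clipped to ±35 before exponentiation.
* HITS power iteration runs on M + s·I (s = max entry): the shift leaves
  eigenvector order unchanged for a symmetric nonnegative matrix but
  prevents the period-2 oscillation of bipartite-like projections.
  All-zero projections yield uniform centrality with a warning.
* Pearson similarity of a zero-variance vector is defined as 0 (with a
  warning) so constant fingerprints do not poison similarity matrices.
* Candidate ranking breaks score ties by (drug_id, mirna_id) so results are
  reproducible.
* Duplicate edge-list rows collapse to the first occurrence; weight 0 is
  "no edge" and rejected on input.
* Metrics with zero denominators are reported as `None` rather than 0.
* Projections are computed densely up to 2000 nodes per side and sparsely
  beyond; values are identical either way.
* Every stage consumes a single integer seed; embeddings, walks, folds and
  reports are bitwise-reproducible given the same configuration.

## Known limitations

* The dense-network backend has no dropout; `dropout_rate` must be 0.
* Default problem sizes (60 × 120 fixture, 5 seeds × 5 folds) are chosen so
  a full benchmark runs in minutes on one CPU; they are not a claim about
  the scale of real MDI corpora.
* GPU training, mini-batched SGA, and re-implementations of other network
  embedders (DeepWalk, LINE, node2vec) are out of scope; external
  embeddings can be supplied via the word2vec text format instead.
* Real-data headline numbers depend on externally hosted databases and are
  not reproduced by the synthetic benchmark.
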