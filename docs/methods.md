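# Methods

## The prediction problem

`comorbnet` predicts disease–disease associations (comorbidity candidates)
by link prediction on a cross-species heterogeneous biological network.
The premise is guilt-by-association: two diseases are likely related when
their associated genes sit close together in molecular networks — sharing
genes outright, encoding interacting proteins, or (via mouse orthologs)
producing overlapping mouse phenotypes.  Mouse data enters because model
organism phenotyping covers far more gene–phenotype relationships than
human clinical genetics does, so bridging human genes to their mouse
orthologs densifies an otherwise sparse disease neighbourhood.

## Network model

Four node types — human disease (D), human gene (G), mouse gene (M), mouse
phenotype (P) — and four undirected edge layers:

| layer | joins | source table shape |
|-------|-------|--------------------|
| DG | disease – human gene | curated disease–gene report |
| GG | human gene – human gene | scored protein–protein links, mapped to coding genes |
| GM | human gene – mouse gene | ortholog report |
| MP | mouse gene – mouse phenotype | gene–phenotype report |

Protein links are kept only when their combined confidence score is at
least 400 (inclusive), the conventional "medium confidence" cut for STRING-
style scores; surviving interactions become unweighted gene–gene edges
(weight 1.0).  Identifiers are opaque strings per namespace; no ontology
traversal is attempted.  Edges are undirected, stored once, deduplicated,
and self-loops are dropped.  Construction is input-order invariant
(adjacency lists are sorted), which the suite checks by permutation.

## Meta-paths

Four disease-to-disease meta-paths define the semantic contexts that feed
the embedding:

* **M1** D–G–D: diseases sharing an associated gene.
* **M2** D–G–G–D: diseases whose genes encode interacting proteins.
* **M3** D–G–M–G–D: diseases bridged by a shared mouse ortholog.
* **M4** D–G–M–P–M–G–D: diseases bridged by a shared mouse phenotype.

An *instance* is a concrete walk matching a schema's node/edge types at
every position.  Walks may revisit nodes; in particular the degenerate
d–g–d walk back to the start keeps every connected disease inside its own
attention neighbourhood (and diseases with no walks at all receive the
activation of the zero vector, logged as starved).  M3 uses the
five-node D–G–M–G–D reading: the network has no mouse–mouse edge layer, so
a six-node reading with two consecutive mouse genes is not realizable.

Long schemas can explode combinatorially, so per (target, schema) at most
`instance_cap` instances (default 128) are kept — a seeded uniform
subsample of the full enumeration, which preserves the expectation of the
attention aggregate while bounding memory.  Enumeration itself is
breadth-first over sorted adjacency and is oracle-tested against an
exhaustive typed-walk search on random graphs.

## Embedding model

The model is a meta-path-aggregated attention network over the typed
graph.  All tensors are float64 and gradients come from a small
reverse-mode array autodiff engine built for exactly this model's
primitive set (`comorbnet._autodiff`).

1. **Node content projection.** Each node type A has features
   `x_d` (by default a learnable free vector per node, since the
   association tables ship no attributes; one-hot and user-provided modes
   exist) and a type-specific map `W_A`, giving `h'_d = W_A x_d` in a
   shared d′-dimensional space (default d′ = 64).
2. **Relational rotation encoding.** A vector in R^d′ is read as d′/2
   complex components (adjacent real pairs — exactly numpy's complex128
   layout, which the implementation exploits).  Each edge type carries a
   phase vector θ; its relation vector is the unit phasor e^{iθ}, so unit
   modulus holds *by construction* rather than by projection.  Walking an
   instance from the target end, `o_0 = h'_{t_0}`,
   `o_i = h'_{t_i} + o_{i−1} ⊙ r_i`, and the instance encoding is
   `o_n / (n+1)`.  Traversing a layer against its canonical orientation
   (e.g. gene→disease) conjugates the phasor.  With all phases zero the
   encoder reduces exactly to the mean of the node vectors — a closed form
   the tests pin down.  The two homolog hops of M3/M4 share one phase
   vector per edge type and direction.
3. **Intra-meta-path attention.** Per target disease d and schema P, a
   multi-head (default 8) additive attention scores each instance:
   `e = LeakyReLU(a_P · [h'_d ‖ h_{P(d,g)}])` on the head's feature slice
   (negative slope 0.2), coefficients are softmax-normalized over the
   target's instances per head (max-subtraction for stability), and the
   weighted instance encodings are concatenated across heads and passed
   through ELU.
4. **Inter-meta-path attention.** Each schema is summarized as
   `s_P = mean_d tanh(M_A h^P_d + b_A)` (summary dimension 128), scored by
   a query vector `q_A`, and the resulting softmax weights β (one global
   weight per schema, shared by all diseases) fuse the per-schema vectors.
5. **Output projection.** `h_d = ELU(W_o h^{P_A}_d)` with output dimension
   64.

Defaults follow the standard configuration for this model family: 8
attention heads, inter-path attention dimension 128, embedding dimension
64, dropout 0.5.  Dropout applies to projected features and attention
coefficients during training only; evaluation-mode forward passes are
bitwise deterministic.  Only disease nodes are embedded as prediction
targets; mouse genes and phenotypes participate as intermediates.

## Training objective

With embeddings h, a pair's association probability is the logistic
sigmoid of the dot product, `p(d1,d2) = σ(h_{d1}·h_{d2})` — symmetric and
in (0,1).  Training minimizes the negative-sampling loss

    L = − Σ_{(d1,d2)∈Ω} log σ(h_{d1}·h_{d2})
        − Σ_{(d1,d2)∈Ω⁻} log σ(−h_{d1}·h_{d2})

where Ω is the known positive pair set and Ω⁻ a seeded uniform sample of
non-positive unordered disease pairs, re-drawn every epoch (ratio 1:1 by
default; the full complement is available for tiny graphs).  Log-sigmoids
are computed in the stable `min(x,0) − log1p(exp(−|x|))` form.
Optimisation is full-batch Adam (lr 5e-3, 100 epochs by default) with
optional early stopping on the AUC of a validation split carved from the
training positives (patience 10; skipped when fewer than 20 positives).
Analytic gradients of the loss through the whole model are checked against
central differences to 1e-4 relative error.

## Evaluation protocol

AUC (rank-based, midranks for ties) and average precision (step-sum under
the precision–recall curve) are computed by scikit-learn behind the
module's validated surface; brute-force pair-enumeration and
precision-recall-walk oracles re-derive them in the tests.

Cross-validation partitions the *positive* pairs into 10 seeded folds;
each fold is held out in turn, the model trains on the rest (epoch-wise
negative samples exclude the held-out negatives), and the held-out
positives are scored against an equal-sized seeded negative sample
disjoint from both the positive set and the training negatives.  The whole
procedure repeats with derived seeds and averages.  Note the deliberate
protocol choice: partitioning *positives* (with matched sampled negatives)
is the standard link-prediction protocol; partitioning only the
unconnected pairs would leave nothing to train on.  Reported percentages
use two decimals.

Ranked prediction scores every unordered disease pair not in the training
positives, sorts by descending probability with lexicographic tie-breaks,
and supports top-k truncation (top 15 is the conventional report size).

## Synthetic fixtures

The generator emits the five input tables with planted community
structure: 4 communities × 8 diseases × 20 human genes, within-community
disease–gene attachment 0.35 (noise 0.01 across communities), protein
links at 0.15 within / 0.01 between communities, 60% ortholog coverage, 5
phenotypes per community with attachment 0.4, and half of each community's
disease pairs labelled positive.  Link scores are drawn uniform on
[600, 999] within and [1, 399] between communities, so the confidence-400
filter is exercised meaningfully: exactly the cross-community link noise
is discarded.  Sizes were chosen so a full repeated cross-validation
finishes in minutes on one core.

*Phenotype-only* fixtures give every disease a disjoint private gene block
(no shared genes, no cross-block protein links), with high (90%) ortholog
coverage and denser (0.5) phenotype attachment on 2-gene blocks: the only
within-community signal flows through the mouse layer, isolating what the
cross-species meta-paths contribute.  On these fixtures the gene-only
meta-path subset (M1+M2) should — and, in the paired runs, does — score
below the full four-meta-path model.

The no-signal control `shuffle_null` rewires the positive pair list by
seeded double-edge swaps: every disease keeps its positive-degree, but
partners are randomized across communities.  A mere relabeling of disease
identities would keep the positive pair graph isomorphic to the original,
and its transitive cluster structure would remain learnable through the
free node features alone; rewiring removes it.  Two residual effects keep
the null's cross-validated AUC from sitting exactly at 0.5: rewired
positives over-sample high-degree diseases (degree is preserved by
design), and the untouched graph still supports the *original*
within-community pairs, some of which land in the null run's sampled
negatives and score high.  The structural claim is therefore the paired
ordering — real positives beat the rewired null on every seed — not the
null's absolute level.

What passing on these fixtures does **not** show: real curated disease–
gene and interaction extracts have heavy-tailed degree distributions,
ontology-structured identifiers and far sparser positives than the planted
communities; absolute AUC/AP on the fixtures says nothing about absolute
performance on curated data.

## Numerical and design choices

* Rotation phases initialise uniform on [−π, π); weight matrices use
  Glorot-scaled normals; biases start at zero.
* Softmaxes subtract the per-group maximum before exponentiation.
* The instance recursion starts at the stored position 0 (the target end);
  with the conjugate-reverse convention the opposite reading differs only
  by a global rotation, which attention absorbs.
* Final embeddings are not L2-normalized: the pair score applies the
  sigmoid to the raw dot product.
* Ties in ranked output break lexicographically on the pair ids so reports
  are reproducible.
* Training-set positives are disease–disease pairs and never edges of the
  graph (edges link diseases to genes), so no edge removal is needed when
  holding pairs out.
* The CV runs driven by the test suite and the acceptance script use one
  repeat of 10-fold CV per seed with 40 epochs and no early stopping —
  the package's scaled-down study size for the planted fixtures; the
  library defaults (100 epochs, patience 10, 10 repeats) remain the
  recommendation for real data.

## Known limitations

* Full-batch training on one core; no minibatching or GPU path.  Practical
  up to a few thousand instances per schema.
* The instance cap subsamples uniformly; extremely hub-heavy graphs may
  need a larger cap for stable attention estimates.
* Negative sampling treats all non-positive pairs as negative — standard,
  but wrong wherever the positive list is incomplete (which is exactly the
  situation ranked prediction is for).
* Only disease nodes are embedded; gene/phenotype-target meta-paths are
  not enumerated.
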