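# Methods

## Problem and model

`circgat` predicts unobserved circRNA–disease associations from a known
binary association matrix **A** (nc circRNAs × nd diseases) plus two
side-information sources: circRNA nucleotide sequences and a disease
ontology. The method is a heterogeneous-graph link predictor:

1. **Similarity kernels.**
   - circRNA sequence similarity
     `SCseq(ci, cj) = 1 − LevDis(ci, cj) / (len(ci) + len(cj))`
     from unit-cost Levenshtein distance (insert/delete/substitute all
     cost 1; the exact distance is computed by the `edlib` C library and
     cross-checked against a dynamic-programming oracle in the tests).
     Two empty sequences are rejected (0/0) rather than defined as 1.
   - Disease semantic similarity by the Wang construction on the
     child→parent ontology DAG: each term contributes 1 to itself and
     `max(ψ · D(child))` to each proper ancestor, with decay ψ = 0.5;
     similarity is the shared-closure contribution sum over the summed
     total semantic values. Contributions are computed over the ancestor
     closure of the focal term only, the standard restriction.
   - Gaussian interaction profile (GIP) kernels
     `exp(−ρ ‖K_i − K_j‖²)` on rows/columns of A, with bandwidth
     ρ = 1 / (mean squared profile norm).
   - Because sequence/semantic similarity can be sparse, each is fused
     with its GIP counterpart entrywise: the primary value where it is
     nonzero (strict ≠ 0, no epsilon — the primary similarities are
     exact small rationals), otherwise the GIP value.

2. **RWR feature initialization.** Both fused matrices are
   column-normalized into transition matrices and all one-hot seeds are
   iterated jointly: `P ← (1−θ) P Ŝ + θ I`, restart probability
   θ = 0.9, tolerance 1e−6 (max absolute entry change), cap 1000
   iterations. The update contracts by (1−θ) per step, so convergence is
   fast and the iterate provably agrees with the direct linear solve
   `P (I − (1−θ)Ŝ) = θI`. The formula right-multiplies row vectors by a
   column-stochastic matrix, so row sums are *not* exactly conserved; we
   implement it as printed and do not renormalize. All-zero columns
   (isolated entities) are left unnormalized — the restart term keeps
   those rows well-defined.

3. **Heterogeneous graph.** Nodes are circRNAs first, then diseases.
   Adjacency `M = [[0, A],[Aᵀ, 0]]` carries only association edges;
   features `X = blockdiag(μ·SC, μ·SD)` carry the (RWR-propagated)
   similarities, scaled by the penalty factor μ = 0.6. X is used as a
   dense (nc+nd)-dimensional initial feature, no truncation.

4. **GNN.** Both graph layers operate on the association adjacency M
   (with self-loops); we deliberately do not route the GCN over the
   weighted similarity network instead, since the similarity signal
   already enters through X and a second, differently normalized
   propagation structure would confound the ablation comparisons.
   One multi-head GAT layer (16 heads, each with its own W and
   attention vector; logits `LeakyReLU(aᵀ[Wb_i ‖ Wb_j])`, negative slope
   0.2; softmax over the neighborhood from `M + I` — self-loops keep
   isolated nodes defined after CV masking; heads *averaged*, then
   ReLU), followed by one GCN layer
   `ReLU(D̃^{−1/2}(M+I)D̃^{−1/2} H W)`. Output width 256. The GCN input
   is the GAT output. A config switch allows stacking more layers of
   either kind.

5. **Scorer and loss.** The concatenated pair embedding `[H_c ‖ H_d]`
   (512-dim) passes through a 3-layer fully connected net with widths
   halving per layer (512→256→128→1), ReLU hidden activations and a
   sigmoid output. Training minimizes mean binary cross-entropy over
   balanced positive/negative pairs plus `(λ/2)‖Θ‖²`, by full-batch Adam.

The model is implemented directly in NumPy with hand-derived
reverse-mode gradients; the backward pass is validated against central
finite differences at 1e−4 relative tolerance in the test suite.

## Training parameters

| parameter | default | rationale |
|---|---|---|
| heads | 16 | best setting of the head-count analysis |
| GAT / GCN layers | 1 / 1 | deeper stacks over-smooth on this graph |
| embedding width | 256 | best of {64, 128, 256, 512} |
| μ (similarity penalty) | 0.6 | best of 0.1–0.9 |
| ψ (semantic decay) | 0.5 | standard Wang value |
| θ (RWR restart) | 0.9 | standard in this literature |
| λ (L2 control) | 1e−4 | see below |
| optimizer / lr / epochs | Adam / 0.005 / 100 | see below |

λ, the optimizer, learning rate and epoch count are free choices of this
package. With full-batch Adam the L2 gradient λθ competes against a BCE
gradient that is small per parameter (it is divided by the pair count);
at λ ≥ 5e−4 the decay term dominates Adam's normalized update for every
weight, the parameters collapse to zero and the predictor pins at 0.5
(training loss stuck at ln 2). λ = 1e−4 is the largest value we found
that trains stably, and it regularizes slightly better than 1e−5.
Training plateaus well before 100 full-batch epochs at lr 0.005, and
longer schedules only overfit the (desk-scale) training pairs, so the
default is 100.

## Cross-validation protocol

Positives are shuffled and partitioned into five test folds; negatives
are sampled uniformly without replacement from the zero entries,
balanced in count within train and test and disjoint across all roles.
Leakage control: within each fold the test positives are removed from A
*before* computing GIP similarity and before building the graph, so no
held-out edge influences message passing or the kernels (sequence and
semantic similarity are association-independent and computed once).
Negatives are resampled independently per repeat. Metrics: AUC in the
Mann–Whitney midrank form (ties count 1/2), AUPR as the area under the
descending-score precision–recall step curve (tied scores form one
threshold group), and accuracy/precision/recall/F1 at the sigmoid
midpoint 0.5 (the natural decision threshold; the full curves are also
emitted as CSV).

Ablation variants: *no-RWR* feeds the fused similarities directly into
X; *no-GAT* / *no-GCN* drop that layer (at least one must remain);
*no-FC* scores by the sigmoid of the embedding inner product.

Case-study ranking treats every association of the target disease as
unknown, rebuilds the pipeline, retrains on the remaining data and ranks
all of that disease's circRNAs by score (ties broken by id).

## Synthetic data

The generator emulates the three real inputs with planted, recoverable
structure: circRNA sequences fall into `k_blocks` families obtained by
point-mutating a family ancestor at 5% per site (within-family sequence
similarity ≈ 0.9, between ≈ 0.7); disease terms form `k_blocks` subtrees
of a random rooted DAG grown by preferential attachment under a shared
root (within-subtree semantic similarity exceeds between-subtree); and
associations are Bernoulli with probability 0.5 for block-matched pairs
against a 0.02 background. Default size is 100 circRNAs × 30 diseases in
3 blocks — large enough for block recovery to be non-trivial, small
enough that a full fivefold CV run takes about a minute on one CPU.

What the generator does *not* emulate: the extreme sparsity of real
association databases (~650 associations over 590 × 88 entities, most
entities with a single link), scale-free degree distributions,
inter-block disease comorbidity, or biologically realistic sequence
divergence (real circRNAs differ by splicing structure, not uniform
point mutation). Passing the recovery experiments therefore shows the
pipeline can exploit coherent similarity-plus-topology signal, not that
it attains any particular performance on curated databases.

Note an intrinsic ceiling of the planted design: zero entries inside a
matched block are statistically identical to held-out positives, so a
perfect model scores them alike; with in-block density 0.5 roughly a
fifth of sampled negatives are in-block, bounding the achievable AUC
around 0.9.

## Numerical choices

- Attention softmax is computed with per-neighborhood max subtraction.
- Scores are clamped to [1e−7, 1 − 1e−7] inside the standalone loss;
  training itself uses the logit formulation, which needs no clamp.
- `fuse` keeps a strict ≠ 0 test; GIP diagonals are set to exactly 1.
- Seeds: every stochastic step (generator, fold shuffling, negative
  sampling, weight init) derives from an explicit integer seed;
  identical seeds give bit-identical results on one platform.
  Cross-platform floating-point drift is tolerated.
- Degenerate inputs: empty FASTA/association files, cyclic ontologies,
  all-zero association matrices, single-class metric inputs and
  unbalanced positive/negative sets are rejected with explicit errors;
  zero similarity columns and nodes isolated by CV masking are handled
  (restart term, self-loops).

## Known limitations

- Full-matrix Levenshtein is O(nc² L²); fine at desk scale, but real
  circBase-scale inputs (10⁵ sequences) would need banded or heuristic
  variants.
- RWR output is not symmetric, so X's similarity blocks are not exactly
  symmetric either; the model does not require symmetry.
- Training is full-batch on a dense graph; no minibatching or GPU path.
- The no-RWR ablation can match or exceed the full model on planted
  blocks: with θ = 0.9 the RWR features are close to scaled one-hots,
  which discards most of the similarity profile, while the fused
  similarities alone are highly informative on this synthetic geometry.
  The comparison is reported rather than asserted.
- Leave-one-disease-out ranking (the case-study protocol) is close to
  chance on the synthetic data: once *all* of a disease's edges are
  masked, the only signal left is its semantic profile, which the
  near-one-hot RWR features largely erase and which the pair scorer —
  trained exclusively on diseases that do have edges — is not forced to
  exploit. Hiding only part of a disease's associations, or computing
  similarities with the target's edges intact, makes the ranking look
  far better, but both reintroduce exactly the leakage this package
  controls for. The acceptance report therefore shows the in-block hit
  count of a fully masked disease, whatever it is.
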