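# Methods

## Problem setting

`omicstack` addresses binary drug-response prediction from multi-omics data:
each sample (a cell line, xenograft or patient tumor) carries three feature
views — standardized continuous gene expression, binary somatic mutation
status, and binary copy-number aberration (CNA) status — and a label
y ∈ {0, 1} (responder / non-responder). The panels this setting emulates are
strongly imbalanced (tens of responders among several hundred samples) and
high-dimensional (10³–10⁴ genes per view), and models trained on in-vitro
cell lines are additionally evaluated on an *external* in-vivo cohort drawn
from a shifted distribution.

## Data model and preprocessing

A `MultiOmicsDataset` is an ordered tuple of per-view sample × feature
matrices sharing one sample ordering (canonicalized to the response file's
order) plus the response vector. The only preprocessing step is a per-view
variance filter: a feature is kept iff its **population** variance (divide
by n) is **strictly greater** than the view's threshold. The filter is a
dimensionality-reduction heuristic, not an inference step, which is why the
population convention is used; thresholds default to 0.0 per view (drop
exactly-constant genes) and are configurable. The filter is idempotent and
order-preserving; emptying a view is an error naming the view.

## Synthetic study conditions

The generator plants a known class signal in data with the statistical
shape of the real panels:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 600 | cohort size (panels range 362–856) |
| `responder_fraction` | 0.1 | exact responder share (panels: 26/389 … 121/856) |
| `view_dims` | (300, 500, 500) | features per view (desk-scale stand-in for 3k–22k) |
| `n_informative` | (30, 30, 30) | signal-carrying features, always the *first* columns |
| `expression_shift` | 1.5 | responder mean shift of informative expression features, in SD units |
| `binary_rate_base` | 0.05 | Bernoulli rate of binary features |
| `binary_rate_shift` | 0.20 | responder rate increment on informative binary features |

Expression is unit-variance Gaussian (real expression arrives standardized,
so this is the natural emulation); binary features are independent
Bernoulli draws. The responder count is exactly
`round(responder_fraction · n_samples)`. `make_external_shifted` draws an
independent cohort from the same signal model with a constant expression
offset and a perturbed binary base rate (clipped to [0, 1] with a warning),
mimicking the in-vitro → in-vivo dichotomy: the label–feature association
survives, the covariates move.

What the generator does **not** emulate: gene–gene correlation / LD
structure, batch effects, view-specific missingness, or any real drug
mechanism. Passing tests therefore demonstrate that the pipeline recovers
planted signal without leaking labels and ranks architectures coherently —
not that any architecture would win on real panels.

## Architectures

All encoders are one hidden layer of width `layer_dim` (ReLU + inverted
dropout) followed by a linear map to `latent_dim`; published sources fix
only the value grid, not depths, so the depth is a design choice made for
desk-scale runtime. All training uses Adagrad with L2 weight decay
(`lr ∈ {0.001, 0.01}`), float64 arithmetic, and explicit seeded generators,
giving bit-reproducible trajectories. Binary views enter as 0/1 reals; no
resampling or class weighting is applied anywhere (AUPRC is the
imbalance-aware lens).

* **Early integration** — views concatenated into one input; encoder +
  single classifier layer; binary cross-entropy (BCE).
* **PCA integration** — per-view PCA fitted without labels, components kept
  up to cumulative explained variance ≥ `pca_variance`; concatenated
  components feed the same encoder/classifier stack.
* **MOLI** — per-view encoders, concatenated latents z, single classifier;
  loss `BCE + γ · L_triplet(z)`, end-to-end.
* **Super.FELT** — phase 1 trains each view's encoder with triplet loss on
  that view's own embeddings (supervised, no classifier); phase 2 freezes
  the encoders (their parameters are simply excluded from the phase-2
  optimizer; a snapshot equality check is kept in `extras`) and trains a
  linear classifier on the concatenated latents.
* **Omics Stacking** — per-view encoders; sigmoid classifier heads per view
  group, combined by a single fully connected meta-learner over the head
  probabilities; `BCE(meta) + γ · L_triplet(z_concat)`, end-to-end. Head
  plans for three views: standard 3+1 = 4 heads; `complete_integration`
  adds the three pair heads (7); `without_integration` keeps only the
  per-view heads (3, late integration); `without_triplet` is the standard
  plan with γ forced to 0.
* **MOMA** — each view's module encoder (two fully connected layers) emits
  K modules, each normalized to a unit 2-vector; for every view pair the
  K × K cosine-similarity matrix is softmax-normalized per row and used to
  attend the partner view's modules; a view's representation averages its
  pairwise-attended modules, is flattened and mapped to a per-view sigmoid
  output. Training minimizes the summed per-view cross-entropies; a
  logistic regression over the per-view outputs forms the combined
  prediction afterwards. With three views each view attends to its two
  partners. K is a hyperparameter drawn from the layer-dimension grid.
* **OmiEmbed** — per-view encoders feed shared μ and log σ² heads
  (`latent_dim`); z = μ + σ·ε; a shared decoder reconstructs every view
  with sigmoid outputs. Embedding loss `(1/M) Σ BCE(x_i, x_i′) + KL(N(μ,σ)‖N(0,1))`
  (KL in closed form, ½(μ² + σ² − 1 − ln σ²) summed over dimensions,
  averaged over the batch); total loss `λ·L_embed + L_CE`. Training runs in
  three phases over E epochs split ceil(E/3)/ceil(E/3)/remainder (E ≥ 3
  required): VAE alone; VAE frozen (dropout off, classifier trained on
  detached μ, with a bit-exact weight equality assertion); joint fine-tune.
  Continuous views are min–max scaled per feature into [0, 1] internally so
  the reconstruction BCE is well defined next to the binary views; test
  data is clipped into the training range. Inference uses μ.

### Triplet loss

`L_triplet = Σ_i [‖f(a_i) − f(p_i)‖² − ‖f(a_i) − f(n_i)‖² + α]₊` — squared
Euclidean distances, hinge at zero, **summed** over every ordered
(anchor, positive, negative) triple of the batch ("all-triplets" online
mining; the triple count is Σ_c n_c(n_c−1)(n−n_c)). A mean reduction exists
behind a flag but is off by default, for fidelity to the summed form.
Batches without a valid triple (fewer than two members of a class)
contribute zero, with a once-per-pattern logged warning — routine under
strong imbalance. BCE on probabilities clips at 1e-7 to avoid log(0).

### Hyperparameters

The search grid: batch size {8, 16, 32}; dropout {0.1, 0.3, 0.5, 0.7};
epochs {2..20}; γ {0.0, 0.1, 0.3, 0.5}; layer dimension {32, 64, 128, 256,
512, 1024} drawn independently for the hidden width, the latent width and
MOMA's module count; learning rate {0.001, 0.01}; margin α {0.2, 0.5, 1};
weight decay {0.0001, 0.001, 0.01, 0.05, 0.1}; PCA variance threshold
{0.9, 0.95, 0.975, 0.99}. The OmiEmbed balance weight λ has no published
search space; it is sampled from the same value set as γ, both being
loss-balancing weights.

## Comparison protocol

Stratified 5×5 nested cross-validation (scikit-learn's stratified splitter;
per-fold class counts within one sample of proportionality; an explicit
error if the minority class is smaller than k). Per outer fold, 200
hyperparameter sets are drawn uniformly with replacement (seeded as
`seed ⊕ fold`), evaluated sequentially on the inner folds with mean AUROC
as the selection metric, under an upper-bound pruning rule: after j of k
folds with scores a₁..a_j, the best attainable mean is
`(Σa + (k−j)·1.0)/k`; once that bound is ≤ the best completed mean the
candidate is abandoned. Pruning triggers on `≤` (equality cannot strictly
improve) and ties between completed means keep the first-seen candidate,
which makes the search order-deterministic; the rule is provably sound (a
pruned candidate's true mean never exceeds the eventual winner's). The
winner is retrained on the full outer-training data with its selected
epoch count unchanged, then scored on the outer test fold and — with the
same model — on the untouched external cohort (AUROC and AUPRC each).
Tests and the quick CLI profile scale this to 3×3 folds and ~20 candidates
on cohorts of one-to-a-few hundred samples; the protocol constants
themselves default to the full 5×5/200 setup.

## Rank statistics

`mean_ranks` ranks methods within each dataset (rank 1 = best, ties
averaged — the standard Friedman/Nemenyi convention), then averages across
datasets; column rank sums are m(m+1)/2. The Nemenyi critical difference is
`CD = q_α(m)·√(m(m+1)/(6N))` with Demšar's q table embedded for m = 2..10
at α = 0.05 (the only level used); for 7 methods on 7 datasets CD ≈ 3.405.
The Wilcoxon signed-rank test drops exact zeros, ranks |d|, and enumerates
the exact null distribution of W⁺ over all 2ⁿ sign assignments (n ≤ 25);
the two-sided p is `2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))` capped at 1 — for seven
positive differences out of seven, p = 2/128 ≈ 0.016. AUROC uses the
Mann–Whitney rank formulation (ties credited ½); AUPRC is step-wise average
precision (trapezoidal interpolation overstates AUPRC under imbalance), and
its expectation under random ranking carries a small positive finite-sample
bias above the prevalence, which the tests account for.

## Attribution

Shapley value sampling adds features one by one to a baseline in a random
order, records the model-output change as each feature flips to its actual
value, and averages over orders (default 50 permutations; full order
enumeration is available and exact for small d). The baseline is the
all-zeros vector: the off state of the binary views, and the mean of
standardized expression — the published analysis does not state its
baseline, so this is the package's choice. Per-feature attributions are
aggregated to views by normalizing total |attribution| to one (view shares
are then nonnegative and total exactly 1; signed normalization is available
behind a flag), reporting the per-view sum (a view's total influence) and
the per-view mean (average influence of one of its features). Attribution
is conventionally computed on the external/held-out split.

## Numerical choices and degenerate inputs

* Float64 throughout; Glorot-uniform initialization from a per-fit seeded
  generator; dropout masks and batch shuffles drawn from the same stream.
* Adagrad accumulator ε = 1e-10; weight decay added to the gradient.
* BCE from logits uses the softplus identity (no overflow); BCE on
  probabilities clips at 1e-7.
* MOMA module normalization adds 1e-12 inside the square root.
* Single-class training data, minority class < k, empty post-filter views,
  variance thresholds < 0, epochs < 3 for the three-phase schedule, K < 1
  modules, and out-of-grid PCA thresholds all raise explicit errors.
* Pruning-rule ties: prune on ≤; selection ties: first seen wins.

## Limitations

* The neural stack runs on an in-repo NumPy reverse-mode autodiff core —
  compact and reproducible, but single-threaded; the full 7-architecture ×
  5×5 × 200-candidate protocol on 10⁴-feature views is a cluster-scale job,
  and the defaults in tests use the documented desk-scale cohorts instead.
* The synthetic generator's independence assumptions make the planted
  signal easier than real panels; absolute AUROCs on it are not comparable
  to published per-drug values.
* Exact Wilcoxon enumeration is limited to n ≤ 25 pairs; the Nemenyi q
  table covers 2–10 methods.
* Gene-level attribution biology, transfer learning and multi-task OmiEmbed
  heads are out of scope.
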