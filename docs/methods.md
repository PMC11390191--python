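# Methods

## Model

`relemb` learns word vectors from two complementary sources of evidence:

* **Distributional contexts** — co-occurrence of words within a fixed
  window of ℓ tokens on either side of a target, collected into a
  symmetric matrix *M* over a single shared target/context vocabulary.
  Windows never cross document boundaries (documents are independent
  abstracts or sentences). Entries are plain co-occurrence counts; the
  reciprocal-distance weighting used by the original GloVe counting is
  available behind `distance_weighting=True` for comparison runs only.
* **Relational contexts** — triples `<head, relation, tail>` from a
  relation-extraction pipeline, associating words at arbitrary distance
  (disease–symptom pairs being the motivating case). Within a triple,
  every unordered token pair co-occurs once (times the triple weight);
  the relation word participates because it carries the semantics that
  make the repository useful, and `entity_pairs_only=True` restricts to
  head–tail pairs when that assumption is wrong for a given repository.
  Multi-word entities are split into tokens so the repository vocabulary
  𝒱 intersects the corpus vocabulary at the token level.

Counts become **PPMI** associations, PPMI(w,c) = max(ln[P(w,c)/(P(w)P(c))], 0),
with probabilities estimated from directed-pair totals (P(w,c) =
n_{(w,c)}/|D|, marginals n_w = Σ_c n_{(w,c)}). Natural logarithms are used
throughout. Whether |D| counts directed pairs or symmetric mass is
immaterial: the constant cancels inside the PMI ratio. Zero and negative
PMI cells are dropped from sparse storage.

**Initialization** is the rank-d truncated SVD of the PPMI matrix,
P ≈ U Σ Vᵀ, with target factors W = U Σ and context factors C = V Σ
(rows are word vectors — the only shape-consistent reading when both
factor matrices index the same vocabulary). The same code path produces
repository factors Ŵ, Ĉ over 𝒱.

**Merging** happens once, at initialization: every corpus token found in
𝒱 starts at w′ = ½(w + ŵ), c′ = ½(c + ĉ); all other tokens keep their
corpus vectors bitwise. Re-merging on every optimization step would
discard what training learns, so the merge is an initialization, not a
constraint. Token-level merging automatically realizes the three pair
membership cases (both/neither/exactly one word in 𝒱). Biases are
corpus-only and start at zero.

**Objective and optimization.** Training minimizes

J_a = ½ Σ_{(w,c): p>0} f(p) (w′ᵀc′ + b_w + b_c − ln p)², f(p) = min((p/p_max)^α, 1)

over the stored (positive-PPMI) pairs, with α = 0.75 and p_max the
maximum stored PPMI value. Updates are AdaGrad with η = 0.05 and 50
iterations. By default one update is applied per stored pair, in a
per-iteration order shuffled by the run seed (`batch_mode="pair"`);
`batch_mode="full"` takes one full-batch step per iteration instead. The
per-pair/full-batch choice is genuinely open — both satisfy the update
equations — and per-pair is the convention of the GloVe lineage this
objective belongs to. ε = 1e-8 is added inside the AdaGrad square root:
the update equations omit it, but the very first step on a zero-history
coordinate divides by |g| and needs the guard. To the stated first-step
law this adds a relative correction of ε/(2g²), negligible for any
appreciable gradient.

The trained outputs are WE (target rows), CE (context rows) and Merged =
(WE + CE)/2, the averaging convention GloVe reports as slightly better
than either factor alone.

## Numerical choices

* **SVD**: deterministic dense LAPACK SVD up to 600 tokens, otherwise
  `scipy.sparse.linalg.svds` with a fixed starting vector. Signs are
  fixed by making the largest-magnitude component of each left singular
  vector positive, so factorizations are reproducible across runs and
  solvers. For a symmetric input U and V agree up to column sign; W and
  C are still kept separate.
* **Repository rank deficiency**: when |𝒱| < d the repository factors are
  computed at rank min(d, |𝒱|) and zero-padded to d columns — the exact
  truncated SVD of a rank-deficient matrix has zero singular values past
  its rank. This keeps repository and corpus dimensions aligned for
  merging; small repositories simply contribute in a low-dimensional
  subspace. `svd_initialize` itself still requires d ≤ |V|.
* **Degenerate inputs**: empty corpora, empty co-occurrence or triple
  collections, constant rank inputs to Spearman, zero vectors in cosine,
  and single-class training sets all raise informative errors rather
  than returning NaNs.
* **Ties**: vocabulary ordering is descending frequency with
  lexicographic tie-break; Spearman uses average ranks.

## Intrinsic evaluation

Word similarity compares embedding cosines against human scores by
Spearman rank correlation (Pearson on average ranks). Gold pairs with an
out-of-vocabulary word are skipped and reported through a coverage
fraction; there is no zero-vector backoff, which would fabricate
similarities. Concept categorization clusters the covered concept vectors
with k-means (k = number of gold categories, 10 restarts, seeded) and
reports purity — the fraction of concepts falling in their cluster's
majority category. Benchmark readers accept tab, comma or whitespace
delimited files.

## Classification

Sentences become k × d matrices (k = 25) by stacking token vectors in
order — longer texts truncated, shorter ones zero-padded at the end,
out-of-vocabulary tokens as zero rows. The embedding layer is frozen so
measured accuracy reflects embedding quality rather than task-specific
fine-tuning. Four architectures are implemented in numpy with exact
backward passes:

* CNN: 100 filters of width 3, stride 1, ReLU, max-pool 2, dropout 0.5,
  ℓ2 = 0.03 on the convolution weights, dense softmax;
* LSTM: 256 hidden units by default (tests use fewer), final state →
  dropout → softmax;
* BiLSTM: forward and backward LSTMs combined by elementwise sum; the
  summed final states of the two directions feed the softmax;
* CNN-LSTM: the pooled convolution feature sequence feeds the LSTM.

Weights are sampled uniformly from [−0.1, 0.1] (forget-gate biases start
at 1); training uses categorical cross-entropy and AdaDelta, which adapts
per-coordinate step sizes without a tunable learning rate. Each model
runs up to 100 epochs and the best epoch is reported; an optional
`stop_at_train_acc` ends a run early once training accuracy reaches a
threshold, used for the separable-data sanity checks where the best
result is already determined. Datasets without an explicit validation
split get a stratified, seeded 80/20 hold-out.

## Synthetic data

The generator plants exactly the structure the method claims to exploit:

* 6 topics × 10 words; each document draws one topic and fills 30
  positions with topic words (probability 0.8) or shared background
  filler (150 words). Within-topic pairs co-occur densely inside a
  window of 5; cross-topic pairs never share a document.
* One distant pair (*whipple*, *fever*) placed at the first and last
  positions of every third document — a within-document gap of 29,
  verified (not assumed) to exceed every window up to 10 — and linked by
  5 relation triples with distinct relation words.
* Gold files derived from the same structure: same-topic pairs score ~9,
  cross-topic ~1, the distant pair 8.5; categories are the topics; the
  two-class sentence set draws from disjoint class vocabularies, so a
  bag-of-words majority rule is 100% accurate on it.

The scale was chosen so that d = 50 is a genuine compression of the
212-token vocabulary (d/|V| ≈ 0.24). At near-full rank the SVD
initialization reproduces the PPMI matrix essentially exactly and
training erases initialization differences — the opposite of the regime
the method targets, where d is orders of magnitude below the vocabulary
size. This is the main caveat on what passing tests show: the generator
reproduces the *mechanisms* (windowed co-occurrence, long-range triples,
separable classes), not the token statistics, polysemy, or noise of real
biomedical text, and absolute scores on it (ρ ≈ 0.75, purity 1.0,
accuracy 1.0) are far above what any method attains on real benchmarks.
Relative statements — the relational lift of distant-pair cosines, the
chance-level permutation control — are the meaningful outputs.

## Known limitations

* Per-pair AdaGrad is sequential; large corpora would need the
  full-batch mode or sharding. No negative sampling, mini-batch
  parallelism or GPU path.
* The repository consumes triples; extracting them (dependency parsing,
  concept filtering) is out of scope.
* No PPMI smoothing or shifted-PPMI variants; no subword units; no
  analogy evaluation.
* The classifiers are deliberately small and deterministic; they are
  measurement instruments for embedding quality, not competitive text
  classifiers.
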