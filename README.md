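# relemb

Relationally augmented word embeddings for biomedical (and other
domain-specific) text, with intrinsic evaluation and neural text
classification.

## The problem

Distributional embedding methods (word2vec, GloVe) learn a word's vector
from the words that co-occur with it inside a fixed context window of
ℓ = 5 or 10 tokens. That window cannot see the association between words
that are systematically mentioned far apart — in *"Whipple disease is a
rare systemic illness characterized by arthralgias, chronic diarrhea,
weight loss, fever, and abdominal pain"*, the pair (*whipple*, *fever*)
carries exactly the disease–symptom semantics a biomedical embedding
should encode, yet never falls inside the window. Relation-mining
pipelines, however, routinely extract such long-range associations as
triples `<entity_i, relation, entity_j>`.

`relemb` injects that relational signal into the embedding:

1. **Initialization.** Build the windowed co-occurrence matrix *M* over
   the corpus vocabulary, convert it to positive pointwise mutual
   information, PPMI(w, c) = max(ln [P(w,c) / (P(w)P(c))], 0), and take
   the rank-d truncated SVD, P ≈ U Σ Vᵀ. The target and context factors
   are W = U Σ and C = V Σ. The same machinery applied to the all-pairs
   matrix of a triple repository R_ℓ gives repository vectors Ŵ, Ĉ over
   the repository vocabulary 𝒱.
2. **Merging.** For every token in 𝒱, the optimized variables start at
   w′ = ½(w + ŵ) and c′ = ½(c + ĉ); all other tokens keep their corpus
   vectors. At the pair level this realizes the three membership cases
   (both words in 𝒱, neither, exactly one).
3. **Optimization.** Minimize the GloVe-style weighted least squares

   J_a = ½ Σ_{(w,c): p_{w,c}>0} f(p_{w,c}) (w′ᵀc′ + b_w + b_c − ln p_{w,c})²,
   f(p) = min((p / max p)^α, 1), α = 0.75,

   with per-pair AdaGrad updates (η = 0.05, 50 iterations): each
   coordinate's step is η g_t / √(Σ_τ g_τ²), so rare words take larger
   steps than frequent ones.

The trained target vectors (WE), context vectors (CE) and their per-token
average (Merged) are evaluated by word similarity (Spearman correlation of
cosine similarities against human scores), concept categorization
(k-means purity) and four frozen-embedding neural classifiers (CNN, LSTM,
BiLSTM, CNN-LSTM) implemented in numpy with AdaDelta training.

A synthetic-data module generates corpora with planted topic structure,
distant pairs that never co-occur within any window, matching triples and
gold files, so the whole pipeline runs and is tested without downloads.

## Worked example

```python
import relemb
from relemb.synthetic_data import PRESETS, generate_corpus, generate_triples, generate_gold
from relemb.eval_intrinsic import cosine, eval_similarity, eval_categorization

spec = PRESETS["default"]                      # 6 topics, |V| = 212, planted pair (whipple, fever)
corpus, _ = generate_corpus(spec)
triples = generate_triples(spec)               # 5 triples linking whipple <-> fever

model = relemb.RelationalWordEmbedding(dim=50, window=5, n_iter=50, random_state=0)
model.fit(corpus, triples=triples)

baseline = relemb.RelationalWordEmbedding(dim=50, window=5, n_iter=50, random_state=0)
baseline.fit(corpus)

print(f"loss: {model.loss_trace_[0]:.1f} -> {model.loss_trace_[-1]:.1f}")
print(f"cosine(whipple, fever) with repository:    {cosine(model.get_vector('whipple'), model.get_vector('fever')):.4f}")
print(f"cosine(whipple, fever) without repository: {cosine(baseline.get_vector('whipple'), baseline.get_vector('fever')):.4f}")

sim_gold, cat_gold, (texts, labels) = generate_gold(spec)
rho, coverage = eval_similarity(model.embeddings_.Merged, sim_gold)
purity, _ = eval_categorization(model.embeddings_.Merged, cat_gold, seed=0)
print(f"word-similarity Spearman rho = {rho:.4f} (coverage {coverage:.0%})")
print(f"concept-categorization purity = {purity:.4f}")

from relemb.classify import SentenceClassifier
clf = SentenceClassifier(embeddings=model.embeddings_.Merged, arch="cnn",
                         epochs=100, random_state=0)
clf.fit(texts, labels, stop_at_train_acc=1.0)
print(f"CNN best train/validation accuracy = {clf.best_train_accuracy_:.3f} / {clf.best_val_accuracy_:.3f}")
```

Output:

```
loss: 1680063.5 -> 11121.9
cosine(whipple, fever) with repository:    0.7797
cosine(whipple, fever) without repository: 0.7070
word-similarity Spearman rho = 0.7538 (coverage 100%)
concept-categorization purity = 1.0000
CNN best train/validation accuracy = 1.000 / 1.000
```

The loss drops by over 99% across the 50 AdaGrad iterations. The planted
distant pair (*whipple*, *fever*) never co-occurs within a window of 10
tokens, yet its Merged-vector cosine rises from 0.707 to 0.780 once the
five relation triples are merged into the initialization — the relational
signal survives training. Trained vectors rank the planted similarity gold
at ρ ≈ 0.75 and recover the six topic categories perfectly; the separable
two-class sentence set is classified perfectly by the frozen-embedding
CNN.

The same workflow is available from the shell:

```bash
relemb synth --preset default --seed 0 --out data/
relemb train --corpus data/corpus.txt --triples data/triples.tsv \
             --dim 50 --window 5 --iters 50 --seed 0 --out model/
relemb eval-sim --vectors model/Merged.txt --gold data/sim_gold.tsv
relemb eval-cat --vectors model/Merged.txt --gold data/cat_gold.tsv --seed 0
relemb classify --vectors model/Merged.txt --data data/labels.tsv --arch cnn --seed 0
```

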