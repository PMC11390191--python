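"""Scikit-learn estimator facade over the embedding pipeline.

``RelationalWordEmbedding`` chains corpus preprocessing, windowed
co-occurrence counting, PPMI weighting, SVD initialization, repository
merging and AdaGrad optimization behind a ``fit``/``transform`` interface,
so the learner composes with sklearn pipelines (``transform`` yields
mean-pooled document vectors).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus_io import (
    TokenizedCorpus,
    build_cooccurrence,
    build_vocabulary,
    preprocess,
)
from .ppmi_svd import ppmi, svd_initialize
from .relational import RelationTriple, build_repository_vectors
from .augment_train import train

__all__ = ["RelationalWordEmbedding"]


class RelationalWordEmbedding(BaseEstimator, TransformerMixin):
    """Word-embedding learner over distributional and relational contexts.

    Parameters
    ----------
    dim : embedding dimensionality d (the reference configurations use 100
        or 200; anything >= 1 and <= |vocabulary| works).
    window : context window size in tokens on each side (typically 5 or 10).
    min_count : minimum corpus frequency for a token to enter the vocabulary.
    eta : AdaGrad initial learning rate.
    n_iter : number of optimization passes over the stored pairs.
    alpha : exponent of the co-occurrence weight function.
    batch_mode : "pair" for per-pair stochastic updates, "full" for one
        full-batch AdaGrad step per iteration.
    stopwords : iterable of stopwords; None uses the packaged English list.
    entity_pairs_only : pair only head/tail tokens of each triple, dropping
        the relation word from the repository matrix.
    binary_triples : count each token pair at most once per triple instead
        of weighting by triple frequency.
    distance_weighting : populate the co-occurrence matrix with reciprocal
        distances (original GloVe counting) instead of plain counts.
    random_state : seed for the per-iteration pair shuffle.

    Attributes
    ----------
    vocabulary_ : fitted :class:`~relemb.corpus_io.Vocabulary`.
    repository_ : fitted :class:`~relemb.relational.RelationalRepository`
        or None when no triples were supplied.
    embeddings_ : :class:`~relemb.vectors.EmbeddingSet` with WE/CE/Merged
        views.
    state_ : final :class:`~relemb.augment_train.TrainingState`.
    loss_trace_ : list of J_a values, entry 0 before training.
    """

    def __init__(
        self,
        dim: int = 100,
        window: int = 5,
        min_count: int = 1,
        eta: float = 0.05,
        n_iter: int = 50,
        alpha: float = 0.75,
        batch_mode: str = "pair",
        stopwords: Iterable[str] | None = None,
        entity_pairs_only: bool = False,
        binary_triples: bool = False,
        distance_weighting: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.eta = eta
        self.n_iter = n_iter
        self.alpha = alpha
        self.batch_mode = batch_mode
        self.stopwords = stopwords
        self.entity_pairs_only = entity_pairs_only
        self.binary_triples = binary_triples
        self.distance_weighting = distance_weighting
        self.random_state = random_state

    def _tokenize(self, X) -> TokenizedCorpus:
        if isinstance(X, TokenizedCorpus):
            return X
        docs = []
        for doc in X:
            if isinstance(doc, str):
                docs.append(preprocess(doc, self.stopwords))
            else:
                docs.append(list(doc))
        return TokenizedCorpus(docs)

    def fit(
        self,
        X: Iterable[str] | Iterable[Sequence[str]] | TokenizedCorpus,
        y=None,
        triples: Sequence[RelationTriple] | None = None,
    ) -> "RelationalWordEmbedding":
        """Learn embeddings from documents and an optional triple collection.

        ``X`` may be raw strings (preprocessed here) or pre-tokenized
        sequences (used as given).
        """
        corpus = self._tokenize(X)
        self.vocabulary_ = build_vocabulary(corpus, self.min_count)
        self.cooccurrence_ = build_cooccurrence(
            corpus,
            self.vocabulary_,
            self.window,
            distance_weighting=self.distance_weighting,
        )
        self.ppmi_ = ppmi(self.cooccurrence_)
        if triples:
            self.repository_ = build_repository_vectors(
                triples,
                self.dim,
                stopwords=self.stopwords,
                entity_pairs_only=self.entity_pairs_only,
                binary=self.binary_triples,
            )
        else:
            self.repository_ = None
        initial = svd_initialize(self.ppmi_, self.dim)
        self.embeddings_, self.state_ = train(
            self.ppmi_,
            repository=self.repository_,
            d=self.dim,
            eta=self.eta,
            iterations=self.n_iter,
            alpha=self.alpha,
            seed=self.random_state,
            batch_mode=self.batch_mode,
            initial=initial,
        )
        self.loss_trace_ = self.state_.loss_trace
        return self

    def transform(self, X) -> np.ndarray:
        """Mean-pooled Merged vectors per document (zeros when no token is
        in vocabulary)."""
        check_is_fitted(self, "embeddings_")
        corpus = self._tokenize(X)
        view = self.embeddings_.Merged
        out = np.zeros((len(corpus.documents), self.dim))
        for k, doc in enumerate(corpus.documents):
            rows = [view[t] for t in doc if t in view]
            if rows:
                out[k] = np.mean(rows, axis=0)
        return out

    def get_vector(self, token: str, view: str = "merged") -> np.ndarray:
        check_is_fitted(self, "embeddings_")
        return self.embeddings_.view(view)[token]
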