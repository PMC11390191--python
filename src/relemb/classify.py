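"""Neural sentence classification on frozen embedding matrices.

Each sentence becomes a fixed-size k x d matrix by stacking its tokens'
embedding vectors (k = 25 by default): longer sentences are truncated,
shorter ones zero-padded at the end, and out-of-vocabulary tokens map to
zero rows.  The embedding layer is frozen — classification accuracy then
reflects the quality of the supplied vectors, not of task-specific
fine-tuning.  Four architectures are available (CNN, LSTM, BiLSTM,
CNN-LSTM), trained with categorical cross-entropy and AdaDelta.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .corpus_io import preprocess
from .nn import make_network
from .nn.layers import AdaDelta, softmax, softmax_cross_entropy
from .vectors import WordVectors

__all__ = [
    "ClassifierSpec",
    "SentenceClassifier",
    "text_to_matrix",
    "build_model",
    "train_classifier",
    "read_labeled",
    "write_labeled",
]


@dataclass
class ClassifierSpec:
    """Architecture and hyperparameters of a sentence classifier."""

    arch: str = "cnn"
    n_classes: int = 2
    k: int = 25
    n_filters: int = 100
    filter_width: int = 3
    stride: int = 1
    pool: int = 2
    dropout: float = 0.5
    l2: float = 0.03
    lstm_units: int = 256
    epochs: int = 100

    def __post_init__(self) -> None:
        for name in ("n_classes", "k", "n_filters", "filter_width", "stride", "pool", "lstm_units", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _as_vectors(embeddings) -> WordVectors:
    if isinstance(embeddings, WordVectors):
        return embeddings
    if isinstance(embeddings, Mapping):
        tokens = list(embeddings)
        return WordVectors(tokens, np.stack([np.asarray(embeddings[t], float) for t in tokens]))
    raise TypeError("embeddings must be WordVectors or a token->vector mapping")


def text_to_matrix(
    tokens: Sequence[str], embeddings: WordVectors | Mapping, k: int = 25
) -> np.ndarray:
    """Stack token vectors into a k x d matrix (truncate / zero-pad)."""
    vecs = _as_vectors(embeddings)
    out = np.zeros((k, vecs.dim))
    for i, tok in enumerate(tokens[:k]):
        v = vecs.get(tok)
        if v is not None:
            out[i] = v
    return out


def build_model(spec: ClassifierSpec, d: int, seed: int | None = None):
    """Instantiate a trainable network for ``spec`` over d-dim embeddings."""
    return make_network(spec, d, np.random.default_rng(seed))


class SentenceClassifier(BaseEstimator, ClassifierMixin):
    """Frozen-embedding neural text classifier (sklearn interface).

    Parameters mirror :class:`ClassifierSpec`; ``embeddings`` supplies the
    frozen word vectors.  ``fit`` accepts raw strings (preprocessed with the
    packaged pipeline) or pre-tokenized sequences.

    Attributes
    ----------
    classes_ : sorted class labels.
    history_ : dict with per-epoch ``train_accuracy``, ``val_accuracy``
        (when validation data exists) and ``loss``.
    best_train_accuracy_, best_val_accuracy_, best_epoch_ : best-epoch
        summary, following the run-N-epochs-report-the-best protocol.
    """

    def __init__(
        self,
        embeddings=None,
        arch: str = "cnn",
        k: int = 25,
        n_filters: int = 100,
        filter_width: int = 3,
        stride: int = 1,
        pool: int = 2,
        dropout: float = 0.5,
        l2: float = 0.03,
        lstm_units: int = 256,
        epochs: int = 100,
        batch_size: int = 32,
        validation_fraction: float = 0.2,
        random_state: int | None = None,
    ) -> None:
        self.embeddings = embeddings
        self.arch = arch
        self.k = k
        self.n_filters = n_filters
        self.filter_width = filter_width
        self.stride = stride
        self.pool = pool
        self.dropout = dropout
        self.l2 = l2
        self.lstm_units = lstm_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- data wrangling ----------------------------------------------------
    def _tokenize(self, X) -> list[list[str]]:
        return [preprocess(x) if isinstance(x, str) else list(x) for x in X]

    def _matrices(self, X) -> np.ndarray:
        vecs = _as_vectors(self.embeddings)
        return np.stack(
            [text_to_matrix(toks, vecs, self.k) for toks in self._tokenize(X)]
        )

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X,
        y,
        validation_data: tuple | None = None,
        stop_at_train_acc: float | None = None,
    ) -> "SentenceClassifier":
        """Train up to ``epochs`` passes, recording per-epoch accuracies.

        Without explicit ``validation_data`` a stratified hold-out of
        ``validation_fraction`` is split off (seeded).  Optional
        ``stop_at_train_acc`` ends training once training accuracy reaches
        the threshold (the best epoch is then already known).
        """
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        Xm = self._matrices(X)
        d = Xm.shape[2]
        spec = ClassifierSpec(
            arch=self.arch,
            n_classes=len(self.classes_),
            k=self.k,
            n_filters=self.n_filters,
            filter_width=self.filter_width,
            stride=self.stride,
            pool=self.pool,
            dropout=self.dropout,
            l2=self.l2,
            lstm_units=self.lstm_units,
            epochs=self.epochs,
        )
        self.spec_ = spec

        if validation_data is not None:
            Xv = self._matrices(validation_data[0])
            yv = np.asarray(validation_data[1])
            yv_idx = np.searchsorted(self.classes_, yv)
            Xt, yt = Xm, y_idx
        elif self.validation_fraction and len(np.unique(y_idx)) > 1:
            Xt, Xv, yt, yv_idx = train_test_split(
                Xm,
                y_idx,
                test_size=self.validation_fraction,
                stratify=y_idx,
                random_state=self.random_state,
            )
        else:
            Xt, yt = Xm, y_idx
            Xv = yv_idx = None

        rng = np.random.default_rng(self.random_state)
        self.network_ = make_network(spec, d, rng)
        opt = AdaDelta()
        n = Xt.shape[0]
        history = {"loss": [], "train_accuracy": [], "val_accuracy": []}
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                scores, cache = self.network_.forward(Xt[idx], train=True, rng=rng)
                loss, dscores = softmax_cross_entropy(scores, yt[idx])
                loss += self.network_.l2_penalty()
                grads = self.network_.backward(dscores, cache)
                opt.update(self.network_.params, grads)
                epoch_loss += loss * len(idx)
            history["loss"].append(epoch_loss / n)
            history["train_accuracy"].append(self._accuracy(Xt, yt))
            if Xv is not None:
                history["val_accuracy"].append(self._accuracy(Xv, yv_idx))
            if (
                stop_at_train_acc is not None
                and history["train_accuracy"][-1] >= stop_at_train_acc
            ):
                break
        self.history_ = history
        self.best_train_accuracy_ = max(history["train_accuracy"])
        if history["val_accuracy"]:
            self.best_val_accuracy_ = max(history["val_accuracy"])
            self.best_epoch_ = int(np.argmax(history["val_accuracy"])) + 1
        else:
            self.best_val_accuracy_ = None
            self.best_epoch_ = int(np.argmax(history["train_accuracy"])) + 1
        return self

    def _accuracy(self, Xm: np.ndarray, y_idx: np.ndarray) -> float:
        scores, _ = self.network_.forward(Xm, train=False)
        return float((scores.argmax(axis=1) == y_idx).mean())

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        scores, _ = self.network_.forward(self._matrices(X), train=False)
        return softmax(scores)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train_classifier(
    model: SentenceClassifier,
    train_set: tuple,
    val_set: tuple | None = None,
    epochs: int | None = None,
    seed: int | None = None,
    stop_at_train_acc: float | None = None,
) -> dict[str, list[float]]:
    """Train ``model`` on ``(texts, labels)`` and return its epoch history."""
    if epochs is not None:
        model.epochs = epochs
    if seed is not None:
        model.random_state = seed
    model.fit(
        train_set[0],
        train_set[1],
        validation_data=val_set,
        stop_at_train_acc=stop_at_train_acc,
    )
    return model.history_


def read_labeled(path: str | Path) -> tuple[list[str], list[str]]:
    """Read TSV ``label <TAB> text`` into (texts, labels)."""
    texts, labels = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'label<TAB>text'")
            labels.append(parts[0])
            texts.append(parts[1])
    return texts, labels


def write_labeled(texts: Sequence[str], labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab, txt in zip(labels, texts):
            fh.write(f"{lab}\t{txt}\n")
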