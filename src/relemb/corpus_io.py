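"""Corpus reading, preprocessing, vocabulary and windowed co-occurrence counts.

The distributional side of the model starts from a symmetric co-occurrence
matrix ``M`` over a shared target/context vocabulary: for every occurrence of
an in-vocabulary token, each in-vocabulary token within ``window`` positions
on either side (windows never cross document boundaries) contributes one
directed pair.  ``M[i, j]`` stores the directed count of context ``j`` around
target ``i``; by construction the matrix is exactly symmetric.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "DEFAULT_STOPWORDS",
    "TokenizedCorpus",
    "Vocabulary",
    "CooccurrenceMatrix",
    "preprocess",
    "read_corpus",
    "build_vocabulary",
    "build_cooccurrence",
    "export_cooccurrence",
]

#: Default English stopword list used when none is supplied.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

_WORD_RE = re.compile(r"\w+", re.UNICODE)
_HAS_DIGIT_RE = re.compile(r"[\d_]")


def preprocess(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Tokenize ``text``, removing punctuation, numbers and stopwords.

    Tokens are produced by splitting on whitespace/punctuation, lowercased,
    and dropped if they contain any digit or appear in ``stopwords``.
    Degenerate input yields an empty list.
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    elif not isinstance(stopwords, (set, frozenset)):
        stopwords = set(stopwords)
    out = []
    for tok in _WORD_RE.findall(text.lower()):
        if _HAS_DIGIT_RE.search(tok):
            continue
        if tok in stopwords:
            continue
        out.append(tok)
    return out


@dataclass
class TokenizedCorpus:
    """An ordered collection of preprocessed token sequences."""

    documents: list[list[str]]

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)

    def __iter__(self) -> Iterator[list[str]]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


def read_corpus(
    path: str | Path,
    stopwords: Iterable[str] | None = None,
) -> TokenizedCorpus:
    """Read a corpus from a text file (one document per line) or a directory
    of ``.txt`` files (one document each), applying :func:`preprocess`."""
    path = Path(path)
    docs: list[list[str]] = []
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            docs.append(preprocess(f.read_text(encoding="utf-8"), stopwords))
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    docs.append(preprocess(line, stopwords))
    return TokenizedCorpus(docs)


@dataclass
class Vocabulary:
    """Ordered token inventory with contiguous 0-based ids and counts.

    Ordering is deterministic: descending corpus frequency, ties broken
    lexicographically.
    """

    tokens: list[str]
    counts: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        return self.index[token]


def build_vocabulary(
    corpus: TokenizedCorpus | Sequence[Sequence[str]],
    min_count: int = 1,
) -> Vocabulary:
    """Build the shared target/context vocabulary from a tokenized corpus.

    Tokens occurring fewer than ``min_count`` times are excluded.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counter: Counter[str] = Counter()
    for doc in corpus:
        counter.update(doc)
    kept = {t: n for t, n in counter.items() if n >= min_count}
    if not kept:
        raise ValueError("empty corpus: no tokens reach min_count, nothing to train on")
    tokens = sorted(kept, key=lambda t: (-kept[t], t))
    return Vocabulary(tokens, kept)


@dataclass
class CooccurrenceMatrix:
    """Symmetric sparse matrix of windowed (target, context) counts.

    ``matrix[i, j]`` is the number of directed pairs in which context ``j``
    fell within ``window`` positions of target ``i``; the total directed-pair
    mass is ``matrix.sum()``.
    """

    vocab: Vocabulary
    window: int
    matrix: sp.csr_matrix  # |V| x |V|, symmetric

    @property
    def n_pairs(self) -> float:
        """Total directed-pair mass |D|."""
        return float(self.matrix.sum())


def build_cooccurrence(
    corpus: TokenizedCorpus | Sequence[Sequence[str]],
    vocab: Vocabulary,
    window: int,
    distance_weighting: bool = False,
) -> CooccurrenceMatrix:
    """Count windowed co-occurrences of in-vocabulary tokens.

    Out-of-vocabulary tokens still occupy positions (they widen the gap
    between surviving tokens) but contribute no counts.  With
    ``distance_weighting=True`` each pair contributes ``1/distance`` instead
    of 1, the reciprocal-distance scheme of the original GloVe counting;
    plain counts are the default.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n = len(vocab)
    index = vocab.index
    acc: Counter[tuple[int, int]] = Counter()
    for doc in corpus:
        ids = [index.get(t, -1) for t in doc]
        L = len(ids)
        for pos, i in enumerate(ids):
            if i < 0:
                continue
            hi = min(L, pos + window + 1)
            for q in range(pos + 1, hi):
                j = ids[q]
                if j < 0 or j == i:
                    continue
                w = 1.0 / (q - pos) if distance_weighting else 1.0
                # one directed pair per side
                acc[(i, j)] += w
                acc[(j, i)] += w
    if acc:
        rows, cols = zip(*acc.keys())
        data = np.fromiter(acc.values(), dtype=np.float64, count=len(acc))
        mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    else:
        mat = sp.csr_matrix((n, n), dtype=np.float64)
    return CooccurrenceMatrix(vocab, window, mat)


def export_cooccurrence(M: CooccurrenceMatrix, path: str | Path) -> None:
    """Write the upper triangle (i <= j by id) as TSV ``token_i token_j count``."""
    coo = sp.triu(M.matrix, k=0).tocoo()
    order = np.lexsort((coo.col, coo.row))
    toks = M.vocab.tokens
    with open(path, "w", encoding="utf-8") as fh:
        for k in order:
            v = coo.data[k]
            v_repr = repr(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{toks[coo.row[k]]}\t{toks[coo.col[k]]}\t{v_repr}\n")
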