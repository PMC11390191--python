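"""Relational semantic repository: triples, their pair matrix and vectors.

A relation triple ``<entity_i, relation, entity_j>`` (e.g. a disease linked
to one of its symptoms) associates words that may never co-occur inside any
context window.  The repository turns a triple collection into the same kind
of symmetric count matrix the corpus produces — every unordered token pair
within a triple co-occurs — and reuses the PPMI + SVD pipeline to obtain
initial vectors over the repository vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from collections import Counter

from .corpus_io import Vocabulary, CooccurrenceMatrix, preprocess
from .ppmi_svd import ppmi, svd_initialize

__all__ = [
    "RelationTriple",
    "RelationalRepository",
    "read_triples",
    "write_triples",
    "triples_to_pairs",
    "build_repository_vectors",
]


@dataclass(frozen=True)
class RelationTriple:
    """One ``<head, relation, tail>`` triple with an optional count weight."""

    head: str
    relation: str
    tail: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.head or not self.tail:
            raise ValueError("triple head and tail must be nonempty")


@dataclass
class RelationalRepository:
    """Triple store with its vocabulary and derived initial vectors."""

    triples: list[RelationTriple]
    vocab: Vocabulary
    W_hat: np.ndarray  # |V_repo| x d
    C_hat: np.ndarray  # |V_repo| x d

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.vocab.tokens)


def read_triples(path: str | Path) -> list[RelationTriple]:
    """Parse a TSV of ``head <TAB> relation <TAB> tail [<TAB> weight]``.

    Blank lines and ``#`` comments are skipped.  Entities may be multi-word.
    """
    triples: list[RelationTriple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                h, r, t = parts
                w = 1.0
            elif len(parts) == 4:
                h, r, t = parts[:3]
                try:
                    w = float(parts[3])
                except ValueError as e:
                    raise ValueError(
                        f"{path}: line {lineno}: bad weight {parts[3]!r}"
                    ) from e
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 or 4 tab-separated "
                    f"columns, got {len(parts)}"
                )
            triples.append(RelationTriple(h, r, t, w))
    return triples


def write_triples(triples: Iterable[RelationTriple], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            if t.weight == 1.0:
                fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")
            else:
                w = repr(int(t.weight)) if t.weight.is_integer() else repr(t.weight)
                fh.write(f"{t.head}\t{t.relation}\t{t.tail}\t{w}\n")


def _triple_tokens(
    t: RelationTriple, stopwords, entity_pairs_only: bool
) -> list[str]:
    head = preprocess(t.head, stopwords)
    tail = preprocess(t.tail, stopwords)
    rel = [] if entity_pairs_only else preprocess(t.relation, stopwords)
    return head + rel + tail


def triples_to_pairs(
    triples: Sequence[RelationTriple],
    stopwords: Iterable[str] | None = None,
    entity_pairs_only: bool = False,
    binary: bool = False,
) -> CooccurrenceMatrix:
    """Build the symmetric pair-count matrix underlying the repository.

    Within each triple every unordered token pair (across head, relation and
    tail tokens; self-pairs excluded) contributes the triple's weight to the
    symmetric count.  ``entity_pairs_only`` drops the relation word from the
    pairing; ``binary`` counts each pair at most once per triple regardless
    of weight.
    """
    if not triples:
        raise ValueError("empty triple collection: no repository to build")
    token_lists: list[tuple[list[str], float]] = []
    counter: Counter[str] = Counter()
    for t in triples:
        toks = _triple_tokens(t, stopwords, entity_pairs_only)
        if len(set(toks)) < 2:
            warnings.warn(
                f"triple {t.head!r}/{t.relation!r}/{t.tail!r} has fewer than "
                "two distinct tokens after preprocessing; skipped",
                stacklevel=2,
            )
            continue
        token_lists.append((toks, 1.0 if binary else t.weight))
        counter.update(toks)
    if not token_lists:
        raise ValueError("all triples vanished under preprocessing")
    tokens = sorted(counter, key=lambda t: (-counter[t], t))
    vocab = Vocabulary(tokens, dict(counter))
    n = len(vocab)
    acc: Counter[tuple[int, int]] = Counter()
    for toks, w in token_lists:
        ids = sorted({vocab[t] for t in toks})
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                acc[(ids[a], ids[b])] += w
                acc[(ids[b], ids[a])] += w
    rows, cols = zip(*acc.keys())
    data = np.fromiter(acc.values(), dtype=np.float64, count=len(acc))
    mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    # window is notional here: triples associate tokens at any distance
    return CooccurrenceMatrix(vocab, window=0, matrix=mat)


def build_repository_vectors(
    triples: Sequence[RelationTriple],
    d: int,
    stopwords: Iterable[str] | None = None,
    entity_pairs_only: bool = False,
    binary: bool = False,
) -> RelationalRepository:
    """PPMI + SVD initial vectors for the repository vocabulary.

    When the repository vocabulary is smaller than ``d`` the factors are
    computed at the attainable rank and zero-padded to ``d`` columns (the
    truncated SVD of a rank-deficient matrix has zero singular values past
    its rank), so repository vectors always align dimensionally with the
    corpus vectors they merge into.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    M = triples_to_pairs(
        triples, stopwords=stopwords, entity_pairs_only=entity_pairs_only, binary=binary
    )
    P = ppmi(M)
    n = len(M.vocab)
    r = min(d, n)
    if P.nnz == 0:
        W_hat = np.zeros((n, d))
        C_hat = np.zeros((n, d))
    else:
        fac = svd_initialize(P, r)
        W_hat = np.zeros((n, d))
        C_hat = np.zeros((n, d))
        W_hat[:, :r] = fac.W
        C_hat[:, :r] = fac.C
    return RelationalRepository(list(triples), M.vocab, W_hat, C_hat)
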