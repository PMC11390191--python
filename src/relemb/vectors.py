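"""Word-vector containers and word2vec-text I/O.

The text format is the word2vec convention: a header line ``|V| d`` followed
by one ``token v1 ... vd`` line per word.  By default values are written with
``repr`` so a written file reads back bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["WordVectors", "EmbeddingSet", "write_word2vec", "read_word2vec"]


@dataclass
class WordVectors:
    """A token -> row mapping over a dense matrix of d-dimensional vectors."""

    tokens: list[str]
    vectors: np.ndarray  # |V| x d

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def get(self, token: str, default=None):
        i = self.index.get(token)
        return self.vectors[i] if i is not None else default


@dataclass
class EmbeddingSet:
    """Trained target (WE), context (CE) and averaged (Merged) vectors.

    ``Merged[t] == (WE[t] + CE[t]) / 2`` for every token, by construction.
    """

    WE: WordVectors
    CE: WordVectors
    Merged: WordVectors

    @classmethod
    def from_matrices(
        cls, tokens: list[str], W: np.ndarray, C: np.ndarray
    ) -> "EmbeddingSet":
        return cls(
            WE=WordVectors(tokens, W),
            CE=WordVectors(tokens, C),
            Merged=WordVectors(tokens, (W + C) / 2.0),
        )

    def view(self, name: str) -> WordVectors:
        try:
            return {"we": self.WE, "ce": self.CE, "merged": self.Merged}[
                name.lower()
            ]
        except KeyError:
            raise ValueError(
                f"unknown embedding view {name!r}; expected WE, CE or Merged"
            ) from None


def write_word2vec(
    vecs: WordVectors, path: str | Path, precision: int | None = None
) -> None:
    """Write vectors in word2vec text format.

    ``precision=None`` (default) uses ``repr`` so values round-trip exactly;
    an integer writes that many decimal places instead.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(vecs)} {vecs.dim}\n")
        for tok, row in zip(vecs.tokens, vecs.vectors):
            if precision is None:
                vals = " ".join(repr(float(x)) for x in row)
            else:
                vals = " ".join(f"{x:.{precision}f}" for x in row)
            fh.write(f"{tok} {vals}\n")


def read_word2vec(path: str | Path) -> WordVectors:
    """Read a word2vec text file written by :func:`write_word2vec` (or any
    tool following the same convention)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n, d = int(header[0]), int(header[1])
        tokens: list[str] = []
        mat = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"{path}: line {i + 2} has {len(parts) - 1} values, expected {d}")
            tokens.append(parts[0])
            mat[i] = [float(x) for x in parts[1:]]
    return WordVectors(tokens, mat)
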