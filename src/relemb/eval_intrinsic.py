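"""Intrinsic embedding evaluation: word similarity and concept categorization.

Word similarity: Spearman rank correlation between embedding cosine
similarities and human scores over a gold pair list; out-of-vocabulary
pairs are skipped and reported through a coverage fraction.

Concept categorization: k-means clustering of concept vectors into as many
clusters as gold categories, scored by purity — the fraction of concepts
assigned to their cluster's majority category.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .vectors import WordVectors

__all__ = [
    "SimilarityGold",
    "CategoryGold",
    "cosine",
    "spearman",
    "purity",
    "eval_similarity",
    "eval_categorization",
    "read_similarity_gold",
    "read_category_gold",
    "write_similarity_gold",
    "write_category_gold",
]


@dataclass
class SimilarityGold:
    """Word pairs with human similarity scores."""

    pairs: list[tuple[str, str, float]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CategoryGold:
    """Concept -> category assignments."""

    assignments: dict[str, str]

    @property
    def n_categories(self) -> int:
        return len(set(self.assignments.values()))

    def __len__(self) -> int:
        return len(self.assignments)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ``u.v / (|u||v|)``; zero vectors are rejected."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(u @ v / (nu * nv))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("constant input: rank correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def eval_similarity(
    vecs: WordVectors, gold: SimilarityGold
) -> tuple[float, float]:
    """Spearman rho between cosine and human scores over covered pairs.

    Returns ``(rho, coverage)`` where coverage is the fraction of gold pairs
    with both words in vocabulary.
    """
    if not gold.pairs:
        raise ValueError("empty gold standard")
    sims, scores = [], []
    for w1, w2, s in gold.pairs:
        if w1 in vecs and w2 in vecs:
            sims.append(cosine(vecs[w1], vecs[w2]))
            scores.append(s)
    if not sims:
        raise ValueError("no gold pair is covered by the vocabulary")
    return spearman(sims, scores), len(sims) / len(gold.pairs)


def purity(clusters: Sequence[int], categories: Sequence[str]) -> float:
    """Fraction of items in their cluster's majority gold category."""
    if len(clusters) != len(categories):
        raise ValueError("clusters and categories must align")
    by_cluster: dict[int, Counter] = {}
    for cl, cat in zip(clusters, categories):
        by_cluster.setdefault(cl, Counter())[cat] += 1
    correct = sum(max(c.values()) for c in by_cluster.values())
    return correct / len(clusters)


def eval_categorization(
    vecs: WordVectors,
    gold: CategoryGold,
    seed: int | None = 0,
    n_init: int = 10,
) -> tuple[float, float]:
    """Cluster covered concepts with k-means (k = number of categories) and
    score purity.  Returns ``(purity, coverage)``."""
    covered = [(c, cat) for c, cat in gold.assignments.items() if c in vecs]
    k = gold.n_categories
    if len({cat for _, cat in covered}) < 2:
        raise ValueError("need at least 2 categories with in-vocabulary concepts")
    if len(covered) < k:
        raise ValueError(
            f"fewer in-vocabulary concepts ({len(covered)}) than categories ({k})"
        )
    X = np.stack([vecs[c] for c, _ in covered])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return purity(labels, [cat for _, cat in covered]), len(covered) / len(gold)


# ---------------------------------------------------------------------------
# gold-file readers: 2 columns + score (similarity) or 2 columns (category),
# delimiter auto-detected among tab / comma / whitespace

def _split_line(line: str) -> list[str]:
    if "\t" in line:
        return line.split("\t")
    if "," in line:
        return next(csv.reader([line]))
    return re.split(r"\s+", line.strip())


def read_similarity_gold(path: str | Path) -> SimilarityGold:
    pairs: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = _split_line(line)
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected word1, word2, score"
                )
            try:
                score = float(parts[2])
            except ValueError as e:
                raise ValueError(
                    f"{path}: line {lineno}: bad score {parts[2]!r}"
                ) from e
            pairs.append((parts[0], parts[1], score))
    return SimilarityGold(pairs)


def read_category_gold(path: str | Path) -> CategoryGold:
    assignments: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = _split_line(line)
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected concept, category"
                )
            assignments[parts[0]] = parts[1]
    return CategoryGold(assignments)


def write_similarity_gold(gold: SimilarityGold, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w1, w2, s in gold.pairs:
            fh.write(f"{w1}\t{w2}\t{s!r}\n")


def write_category_gold(gold: CategoryGold, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for concept, cat in gold.assignments.items():
            fh.write(f"{concept}\t{cat}\n")
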