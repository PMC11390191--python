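"""Synthetic corpora, triples, gold standards and labeled sets.

The generator plants the structure the embedding pipeline is supposed to
recover: topic blocks of words that co-occur densely inside context
windows, shared background filler, and "distant pairs" — word pairs (e.g. a
disease and one of its symptoms) placed at opposite ends of documents so
they never co-occur within any window of size 10, yet are linked by
relation triples.  The distributional signal alone cannot associate a
distant pair; the relational repository can.  Gold similarity scores,
category assignments and labeled sentences are all derived from the same
planted structure, so every downstream module is testable offline.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .corpus_io import TokenizedCorpus
from .eval_intrinsic import (
    CategoryGold,
    SimilarityGold,
    write_category_gold,
    write_similarity_gold,
)
from .relational import RelationTriple, write_triples
from .classify import write_labeled

__all__ = [
    "SyntheticSpec",
    "PRESETS",
    "generate_corpus",
    "generate_triples",
    "generate_gold",
    "min_distant_gap",
    "write_dataset",
]

MAX_WINDOW = 10  # distant pairs must stay farther apart than this


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Token names are all-letters so they survive the preprocessing filters.
    Distant-pair members appear only at positions 0 and ``doc_length - 1``
    of every third document, guaranteeing a within-document gap larger than
    any context window up to 10 tokens.
    """

    n_topics: int = 6
    words_per_topic: int = 10
    n_documents: int = 300
    doc_length: int = 30
    background_vocab_size: int = 150
    topic_word_prob: float = 0.8
    distant_pairs: tuple[tuple[str, str], ...] = (("whipple", "fever"),)
    n_triples_per_distant_pair: int = 5
    n_classes: int = 2
    n_sentences: int = 400
    sentence_length: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_topics",
            "words_per_topic",
            "n_documents",
            "doc_length",
            "background_vocab_size",
            "n_classes",
            "n_sentences",
            "sentence_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.distant_pairs and self.doc_length - 1 <= MAX_WINDOW:
            raise ValueError(
                f"doc_length={self.doc_length} cannot separate distant pairs "
                f"by more than {MAX_WINDOW} tokens"
            )

    # -- vocabularies ------------------------------------------------------
    def topic_words(self, t: int) -> list[str]:
        a = string.ascii_lowercase[t]
        return [
            f"topic{a}{_letters(j)}" for j in range(self.words_per_topic)
        ]

    @property
    def background_words(self) -> list[str]:
        return [f"filler{_letters(j)}" for j in range(self.background_vocab_size)]

    @property
    def topic_map(self) -> dict[str, int]:
        return {
            w: t for t in range(self.n_topics) for w in self.topic_words(t)
        }


def _letters(j: int) -> str:
    """Digit-free suffix: 0 -> 'aa', 1 -> 'ab', ..."""
    hi, lo = divmod(j, 26)
    return string.ascii_lowercase[hi] + string.ascii_lowercase[lo]


PRESETS: dict[str, SyntheticSpec] = {
    "default": SyntheticSpec(),
    "tiny": SyntheticSpec(
        n_topics=2,
        words_per_topic=5,
        n_documents=40,
        doc_length=20,
        background_vocab_size=10,
        n_triples_per_distant_pair=3,
        n_sentences=80,
        sentence_length=10,
    ),
}


def generate_corpus(spec: SyntheticSpec) -> tuple[TokenizedCorpus, dict[str, int]]:
    """Sample the corpus; returns the corpus and the token -> topic map.

    Each document draws one topic; each position is a topic word with
    probability ``topic_word_prob``, otherwise background.  Every third
    document carries one distant pair at its first and last positions
    (pairs rotate round-robin).  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_words
    per_topic = [spec.topic_words(t) for t in range(spec.n_topics)]
    docs: list[list[str]] = []
    pair_cycle = itertools.cycle(range(len(spec.distant_pairs))) if spec.distant_pairs else None
    for d in range(spec.n_documents):
        t = int(rng.integers(spec.n_topics))
        words = per_topic[t]
        doc = [
            words[rng.integers(len(words))]
            if rng.random() < spec.topic_word_prob
            else bg[rng.integers(len(bg))]
            for _ in range(spec.doc_length)
        ]
        if pair_cycle is not None and d % 3 == 0:
            x, y = spec.distant_pairs[next(pair_cycle)]
            doc[0] = x
            doc[-1] = y
        docs.append(doc)
    return TokenizedCorpus(docs), spec.topic_map


def min_distant_gap(corpus: TokenizedCorpus, pair: tuple[str, str]) -> int | None:
    """Smallest within-document index gap between the pair's members, or
    None if they never share a document.  Used to verify (not assume) the
    distant-pair constraint."""
    x, y = pair
    best: int | None = None
    for doc in corpus:
        xs = [i for i, t in enumerate(doc) if t == x]
        ys = [i for i, t in enumerate(doc) if t == y]
        for a in xs:
            for b in ys:
                gap = abs(a - b)
                if best is None or gap < best:
                    best = gap
    return best


def generate_triples(spec: SyntheticSpec) -> list[RelationTriple]:
    """Relation triples linking each distant pair through distinct relation
    words (``n_triples_per_distant_pair`` per pair)."""
    triples: list[RelationTriple] = []
    for x, y in spec.distant_pairs:
        for k in range(spec.n_triples_per_distant_pair):
            triples.append(RelationTriple(x, f"rel{_letters(k)}", y))
    return triples


def generate_gold(
    spec: SyntheticSpec,
) -> tuple[SimilarityGold, CategoryGold, tuple[list[str], list[str]]]:
    """Gold standards consistent with the planted structure.

    Similarity: same-topic pairs and planted distant pairs score high,
    cross-topic pairs low (small seeded jitter breaks ties).  Categories:
    topic membership.  Labeled sentences: ``n_classes`` topics provide
    class-specific vocabularies; the first token of every sentence is a
    topic word, so a bag-of-words majority rule is 100% accurate.
    """
    rng = np.random.default_rng(spec.seed + 1)
    per_topic = [spec.topic_words(t) for t in range(spec.n_topics)]

    pairs: list[tuple[str, str, float]] = []
    cross: list[tuple[str, str]] = []
    for t, words in enumerate(per_topic):
        for a, b in itertools.combinations(words, 2):
            pairs.append((a, b, round(9.0 + rng.uniform(-0.5, 0.5), 4)))
        for u in range(t + 1, spec.n_topics):
            for a in words:
                for b in per_topic[u]:
                    cross.append((a, b))
    n_same = len(pairs)
    take = min(n_same, len(cross))
    sel = rng.choice(len(cross), size=take, replace=False)
    for i in sel:
        a, b = cross[i]
        pairs.append((a, b, round(1.0 + rng.uniform(-0.5, 0.5), 4)))
    for x, y in spec.distant_pairs:
        pairs.append((x, y, 8.5))
    sim_gold = SimilarityGold(pairs)

    cat_gold = CategoryGold(
        {
            w: f"category{string.ascii_lowercase[t]}"
            for t, words in enumerate(per_topic)
            for w in words
        }
    )

    n_cls = min(spec.n_classes, spec.n_topics)
    bg = spec.background_words
    texts: list[str] = []
    labels: list[str] = []
    for s in range(spec.n_sentences):
        cls = s % n_cls
        words = per_topic[cls]
        toks = [words[rng.integers(len(words))]]
        for _ in range(spec.sentence_length - 1):
            if rng.random() < spec.topic_word_prob:
                toks.append(words[rng.integers(len(words))])
            else:
                toks.append(bg[rng.integers(len(bg))])
        texts.append(" ".join(toks))
        labels.append(f"class{string.ascii_lowercase[cls]}")
    return sim_gold, cat_gold, (texts, labels)


def write_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write corpus.txt, triples.tsv, sim_gold.tsv, cat_gold.tsv, labels.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus, _ = generate_corpus(spec)
    triples = generate_triples(spec)
    sim_gold, cat_gold, (texts, labels) = generate_gold(spec)
    paths = {
        "corpus": outdir / "corpus.txt",
        "triples": outdir / "triples.tsv",
        "sim_gold": outdir / "sim_gold.tsv",
        "cat_gold": outdir / "cat_gold.tsv",
        "labels": outdir / "labels.tsv",
    }
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(" ".join(doc) + "\n")
    write_triples(triples, paths["triples"])
    write_similarity_gold(sim_gold, paths["sim_gold"])
    write_category_gold(cat_gold, paths["cat_gold"])
    write_labeled(texts, labels, paths["labels"])
    return paths


def preset(name: str, seed: int | None = None, **overrides) -> SyntheticSpec:
    """Fetch a named preset, optionally reseeded or tweaked."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(spec, **overrides) if overrides else spec
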