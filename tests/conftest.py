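import numpy as np
import pytest

import relemb
from relemb.synthetic_data import PRESETS, generate_corpus, generate_gold, generate_triples


@pytest.fixture(scope="session")
def tiny_spec():
    return PRESETS["tiny"]


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    corpus, topic_map = generate_corpus(tiny_spec)
    return corpus, topic_map


@pytest.fixture(scope="session")
def tiny_ppmi(tiny_corpus):
    corpus, _ = tiny_corpus
    vocab = relemb.build_vocabulary(corpus)
    M = relemb.build_cooccurrence(corpus, vocab, window=5)
    return relemb.ppmi(M)


@pytest.fixture(scope="session")
def tiny_embeddings(tiny_ppmi):
    """Embeddings trained once on the tiny preset (d=16, 50 iterations)."""
    emb, state = relemb.train(tiny_ppmi, d=16, seed=0)
    return emb, state


@pytest.fixture(scope="session")
def tiny_gold(tiny_spec):
    return generate_gold(tiny_spec)


@pytest.fixture(scope="session")
def tiny_triples(tiny_spec):
    return generate_triples(tiny_spec)


def random_count_matrix(rng: np.random.Generator, n: int, density: float = 0.5):
    """Symmetric integer count matrix with zero diagonal, as a
    CooccurrenceMatrix over a synthetic vocabulary."""
    import scipy.sparse as sp

    from relemb.corpus_io import CooccurrenceMatrix, Vocabulary

    counts = rng.integers(0, 10, size=(n, n)).astype(float)
    counts *= rng.random((n, n)) < density
    counts = np.triu(counts, k=1)
    counts = counts + counts.T
    tokens = [f"w{chr(97 + i // 26)}{chr(97 + i % 26)}" for i in range(n)]
    vocab = Vocabulary(tokens, {t: 1 for t in tokens})
    return CooccurrenceMatrix(vocab, window=5, matrix=sp.csr_matrix(counts))
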