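"""Vector merging and AdaGrad training of the augmented objective.

The trainer minimizes a GloVe-style weighted least-squares loss over the
stored (positive-PPMI) pairs of the corpus association matrix:

    J_a = 1/2 sum_{(w,c): p_wc > 0} f(p_wc) (w'^T c' + b_w + b_c - ln p_wc)^2

with weight f(p) = min((p / p_max)^alpha, 1).  The optimized variables w'
and c' start from the PPMI+SVD corpus factors, augmented at initialization
by the relational repository: any token found in the repository vocabulary
has its target and context rows replaced by the average of its corpus and
repository vectors (w' = 0.5 (w + w_hat)); tokens outside the repository
keep their corpus vectors unchanged.  At the pair level this realizes the
three membership cases — both words in the repository, neither, or exactly
one.  Updates use AdaGrad: each coordinate's step is the learning rate
divided by the root of its accumulated squared gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp

from .corpus_io import Vocabulary
from .ppmi_svd import AssociationMatrix, InitialFactors, svd_initialize
from .relational import RelationalRepository
from .vectors import EmbeddingSet

__all__ = [
    "PairCategory",
    "TrainingState",
    "categorize_pair",
    "merge_vectors",
    "weight",
    "glove_weight",
    "objective",
    "gradients",
    "adagrad_step",
    "train",
]

ADAGRAD_EPS = 1e-8  # inside the root; stabilizes the first step


class PairCategory(Enum):
    """Membership case of a (target, context) pair w.r.t. the repository
    vocabulary: both members, neither, or exactly one."""

    BOTH = "both"
    NEITHER = "neither"
    ONE = "one"


def categorize_pair(w: str, c: str, repo_vocab) -> PairCategory:
    w_in = w in repo_vocab
    c_in = c in repo_vocab
    if w_in and c_in:
        return PairCategory.BOTH
    if not w_in and not c_in:
        return PairCategory.NEITHER
    return PairCategory.ONE


def merge_vectors(
    W: np.ndarray,
    C: np.ndarray,
    W_hat: np.ndarray,
    C_hat: np.ndarray,
    corpus_vocab: Vocabulary,
    repo_vocab: Vocabulary,
) -> tuple[np.ndarray, np.ndarray]:
    """Token-level merge of corpus and repository initial vectors.

    For every corpus token ``t`` in the repository vocabulary,
    ``W'[t] = 0.5 (W[t] + W_hat[t])`` and likewise for the context row;
    all other rows are returned unchanged (bitwise).
    """
    if W.shape[1] != W_hat.shape[1]:
        raise ValueError(
            f"dimension mismatch: corpus d={W.shape[1]}, repository d={W_hat.shape[1]}"
        )
    W_out = W.copy()
    C_out = C.copy()
    for tok, i in corpus_vocab.index.items():
        j = repo_vocab.index.get(tok)
        if j is not None:
            W_out[i] = 0.5 * (W[i] + W_hat[j])
            C_out[i] = 0.5 * (C[i] + C_hat[j])
    return W_out, C_out


def weight(p, p_max: float, alpha: float = 0.75):
    """Co-occurrence weight ``f(p) = min((p / p_max)^alpha, 1)``.

    ``p`` is the pair's PPMI value and ``p_max`` the maximum over all stored
    pairs; accepts scalars or arrays.  Pairs with nonpositive PPMI carry no
    weight — they are excluded from the objective — so ``p <= 0`` raises.
    """
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr <= 0):
        raise ValueError("weight is defined only for positive PPMI values")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    out = np.minimum((p_arr / p_max) ** alpha, 1.0)
    return float(out) if np.isscalar(p) else out


def glove_weight(x, x_max: float = 100.0, alpha: float = 0.75):
    """Original GloVe weight ``f(x) = min((x / x_max)^alpha, 1)`` on raw
    co-occurrence counts, used by the GloVe-comparison mode."""
    x_arr = np.asarray(x, dtype=np.float64)
    out = np.minimum((x_arr / x_max) ** alpha, 1.0)
    return float(out) if np.isscalar(x) else out


@dataclass
class TrainingState:
    """Merged parameters, AdaGrad accumulators and the loss trace."""

    W: np.ndarray  # |V| x d, the w' rows
    C: np.ndarray  # |V| x d, the c' rows
    b_w: np.ndarray  # |V|
    b_c: np.ndarray  # |V|
    eta: float = 0.05
    G_w: np.ndarray = None  # squared-gradient accumulators
    G_c: np.ndarray = None
    G_bw: np.ndarray = None
    G_bc: np.ndarray = None
    loss_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.G_w is None:
            self.G_w = np.zeros_like(self.W)
        if self.G_c is None:
            self.G_c = np.zeros_like(self.C)
        if self.G_bw is None:
            self.G_bw = np.zeros_like(self.b_w)
        if self.G_bc is None:
            self.G_bc = np.zeros_like(self.b_c)

    @classmethod
    def initialize(
        cls, W: np.ndarray, C: np.ndarray, eta: float = 0.05
    ) -> "TrainingState":
        n = W.shape[0]
        return cls(
            W=W.copy(), C=C.copy(), b_w=np.zeros(n), b_c=np.zeros(n), eta=eta
        )


def _pair_arrays(P: AssociationMatrix, alpha: float):
    """Flatten stored pairs into (rows, cols, f-weights, log-targets)."""
    coo = P.matrix.tocoo()
    if coo.nnz == 0:
        raise ValueError("association matrix has no stored pairs")
    f = weight(coo.data, P.p_max, alpha)
    return coo.row, coo.col, np.asarray(f), np.log(coo.data)


def _residuals(state: TrainingState, rows, cols, logp):
    return (
        np.einsum("ij,ij->i", state.W[rows], state.C[cols])
        + state.b_w[rows]
        + state.b_c[cols]
        - logp
    )


def objective(state: TrainingState, P: AssociationMatrix, alpha: float = 0.75) -> float:
    """Evaluate J_a over all stored (positive-PPMI) pairs."""
    rows, cols, f, logp = _pair_arrays(P, alpha)
    r = _residuals(state, rows, cols, logp)
    return 0.5 * float(np.sum(f * r * r))


def gradients(
    state: TrainingState, P: AssociationMatrix, alpha: float = 0.75
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Full-batch analytic gradients of J_a w.r.t. (W', C', b_w, b_c).

    dJ/dw' sums ``f (w'^T c' + b_w + b_c - ln p) c'`` over the target's
    stored context pairs; context and bias gradients are analogous (biases
    drop the vector factor).  Tokens in no stored pair get zero gradient.
    """
    rows, cols, f, logp = _pair_arrays(P, alpha)
    r = _residuals(state, rows, cols, logp)
    fr = f * r
    n = state.W.shape[0]
    S = sp.csr_matrix((fr, (rows, cols)), shape=(n, n))
    gW = S @ state.C
    gC = S.T @ state.W
    g_bw = np.asarray(S.sum(axis=1)).ravel()
    g_bc = np.asarray(S.sum(axis=0)).ravel()
    return gW, gC, g_bw, g_bc


def adagrad_step(
    state: TrainingState,
    grads: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> TrainingState:
    """One AdaGrad update of every parameter group, in place.

    Each accumulator grows by the squared gradient; each coordinate moves by
    ``eta * g / sqrt(accumulator + eps)``.  Zero-gradient coordinates are
    untouched (their accumulators do not grow).
    """
    gW, gC, g_bw, g_bc = grads
    eta = state.eta
    for theta, G, g in (
        (state.W, state.G_w, gW),
        (state.C, state.G_c, gC),
        (state.b_w, state.G_bw, g_bw),
        (state.b_c, state.G_bc, g_bc),
    ):
        G += g * g
        nz = G > 0
        theta[nz] -= eta * g[nz] / np.sqrt(G[nz] + ADAGRAD_EPS)
    return state


try:  # jitted inner loop; the numpy path below is the reference semantics
    from numba import njit

    @njit(cache=False)
    def _sgd_epoch_kernel(
        W, C, b_w, b_c, G_w, G_c, G_bw, G_bc, rows, cols, f, logp, order, eta, eps
    ):  # pragma: no cover - exercised through _sgd_epoch
        d = W.shape[1]
        for n in range(order.shape[0]):
            k = order[n]
            i = rows[k]
            j = cols[k]
            dot = 0.0
            for a in range(d):
                dot += W[i, a] * C[j, a]
            r = f[k] * (dot + b_w[i] + b_c[j] - logp[k])
            for a in range(d):
                gw = r * C[j, a]
                gc = r * W[i, a]
                G_w[i, a] += gw * gw
                G_c[j, a] += gc * gc
                W[i, a] -= eta * gw / np.sqrt(G_w[i, a] + eps)
                C[j, a] -= eta * gc / np.sqrt(G_c[j, a] + eps)
            G_bw[i] += r * r
            G_bc[j] += r * r
            b_w[i] -= eta * r / np.sqrt(G_bw[i] + eps)
            b_c[j] -= eta * r / np.sqrt(G_bc[j] + eps)

except ImportError:  # pragma: no cover
    _sgd_epoch_kernel = None


def _sgd_epoch(state: TrainingState, rows, cols, f, logp, order) -> None:
    """One pass of per-pair stochastic AdaGrad updates in ``order``."""
    if _sgd_epoch_kernel is not None:
        _sgd_epoch_kernel(
            state.W,
            state.C,
            state.b_w,
            state.b_c,
            state.G_w,
            state.G_c,
            state.G_bw,
            state.G_bc,
            rows.astype(np.int64),
            cols.astype(np.int64),
            f,
            logp,
            order.astype(np.int64),
            state.eta,
            ADAGRAD_EPS,
        )
        return
    W, C, b_w, b_c = state.W, state.C, state.b_w, state.b_c
    G_w, G_c, G_bw, G_bc = state.G_w, state.G_c, state.G_bw, state.G_bc
    eta = state.eta
    eps = ADAGRAD_EPS
    for k in order:
        i = rows[k]
        j = cols[k]
        wi = W[i]
        cj = C[j]
        r = f[k] * (wi @ cj + b_w[i] + b_c[j] - logp[k])
        gw = r * cj
        gc = r * wi
        G_w[i] += gw * gw
        G_c[j] += gc * gc
        G_bw[i] += r * r
        G_bc[j] += r * r
        W[i] = wi - eta * gw / np.sqrt(G_w[i] + eps)
        C[j] = cj - eta * gc / np.sqrt(G_c[j] + eps)
        b_w[i] -= eta * r / np.sqrt(G_bw[i] + eps)
        b_c[j] -= eta * r / np.sqrt(G_bc[j] + eps)


def train(
    P: AssociationMatrix,
    repository: RelationalRepository | None = None,
    d: int = 100,
    eta: float = 0.05,
    iterations: int = 50,
    alpha: float = 0.75,
    seed: int | None = None,
    batch_mode: str = "pair",
    initial: InitialFactors | None = None,
) -> tuple[EmbeddingSet, TrainingState]:
    """Full training pipeline: initialize, merge, optimize.

    Initial factors come from the rank-``d`` SVD of the corpus PPMI matrix
    (or ``initial`` if precomputed); repository vectors, when given, are
    merged in token-wise before optimization.  ``batch_mode="pair"`` applies
    one AdaGrad update per stored pair in a per-iteration shuffled order
    (seeded); ``"full"`` takes one full-batch step per iteration.  Returns
    the trained WE/CE/Merged views and the final state with its loss trace
    (entry 0 is the pre-training loss).
    """
    if batch_mode not in ("pair", "full"):
        raise ValueError(f"batch_mode must be 'pair' or 'full', got {batch_mode!r}")
    vocab = P.vocab
    if initial is None:
        initial = svd_initialize(P, d)
    W0, C0 = initial.W, initial.C
    if repository is not None:
        if repository.W_hat.shape[1] != W0.shape[1]:
            raise ValueError(
                f"repository dimension {repository.W_hat.shape[1]} != corpus "
                f"dimension {W0.shape[1]}"
            )
        W0, C0 = merge_vectors(
            W0, C0, repository.W_hat, repository.C_hat, vocab, repository.vocab
        )
    state = TrainingState.initialize(W0, C0, eta=eta)
    rows, cols, f, logp = _pair_arrays(P, alpha)
    rng = np.random.default_rng(seed)
    state.loss_trace.append(objective(state, P, alpha))
    n_pairs = len(rows)
    for it in range(iterations):
        if batch_mode == "pair":
            order = rng.permutation(n_pairs)
            _sgd_epoch(state, rows, cols, f, logp, order)
        else:
            adagrad_step(state, gradients(state, P, alpha))
        loss = objective(state, P, alpha)
        if not np.isfinite(loss):
            raise ArithmeticError(
                f"training diverged at iteration {it + 1}: J_a = {loss}"
            )
        state.loss_trace.append(loss)
    emb = EmbeddingSet.from_matrices(list(vocab.tokens), state.W, state.C)
    return emb, state
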