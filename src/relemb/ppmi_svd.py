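"""PMI/PPMI association weighting and truncated-SVD initialization.

Counts are converted to pointwise mutual information,

    PMI(w, c) = ln( P(w, c) / (P(w) P(c)) ),

with probabilities estimated from directed-pair totals: ``P(w, c) =
n_(w,c) / |D|`` and marginals ``n_w = sum_c n_(w,c)``.  Positive PMI (PPMI)
clips negatives to zero and drops them from sparse storage.  A rank-``d``
truncated SVD of the PPMI matrix, ``P ~ U S V^T``, gives the initial target
and context factors ``W = U S`` and ``C = V S`` (rows are word vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .corpus_io import CooccurrenceMatrix, Vocabulary

__all__ = [
    "AssociationMatrix",
    "InitialFactors",
    "pmi",
    "ppmi",
    "svd_initialize",
    "export_ppmi",
]

# below this size a dense LAPACK SVD is cheaper and fully deterministic
_DENSE_SVD_MAX = 600


@dataclass
class AssociationMatrix:
    """Sparse symmetric PPMI matrix with its maximum entry.

    Stored entries are strictly positive (zeros and negative PMI values are
    dropped); ``p_max`` is the maximum stored value, used by the training
    weight function.
    """

    vocab: Vocabulary
    matrix: sp.csr_matrix
    p_max: float

    @property
    def nnz(self) -> int:
        return self.matrix.nnz


@dataclass
class InitialFactors:
    """Rank-``d`` factors of the PPMI matrix: ``W = U S``, ``C = V S``."""

    W: np.ndarray  # |V| x d
    C: np.ndarray  # |V| x d
    singular_values: np.ndarray  # length d, nonincreasing


def pmi(M: CooccurrenceMatrix) -> sp.csr_matrix:
    """PMI of every stored co-occurrence pair (natural log).

    Unobserved pairs (count 0) are simply absent from the returned sparse
    matrix: their PMI would be ``-inf``.
    """
    mat = M.matrix
    total = mat.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix: no pairs to weight")
    marg = np.asarray(mat.sum(axis=1)).ravel()  # n_w (== n_c by symmetry)
    coo = mat.tocoo()
    # PMI = ln(n_wc * |D| / (n_w * n_c)); |D| factors cancel consistently
    vals = np.log(coo.data * total / (marg[coo.row] * marg[coo.col]))
    return sp.csr_matrix((vals, (coo.row, coo.col)), shape=mat.shape)


def ppmi(M: CooccurrenceMatrix) -> AssociationMatrix:
    """Positive PMI: clip negatives to zero and drop them from storage."""
    P = pmi(M).tocoo()
    keep = P.data > 0
    mat = sp.csr_matrix(
        (P.data[keep], (P.row[keep], P.col[keep])), shape=P.shape
    )
    p_max = float(mat.data.max()) if mat.nnz else 0.0
    return AssociationMatrix(M.vocab, mat, p_max)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-magnitude component of each left singular vector
    positive so factorizations are reproducible across runs/solvers."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def svd_initialize(P: AssociationMatrix, d: int) -> InitialFactors:
    """Rank-``d`` truncated SVD of the PPMI matrix.

    Returns target factors ``W = U S_d`` and context factors ``C = V S_d``
    with singular values sorted descending and a deterministic sign
    convention.  ``W @ diag(1/S) @ C.T`` is the best rank-``d`` approximation
    of ``P`` (Eckart-Young).
    """
    n = len(P.vocab)
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, |V|={n}], got {d}")
    mat = P.matrix
    if n <= _DENSE_SVD_MAX or d >= n - 1:
        U, s, Vt = np.linalg.svd(mat.toarray(), full_matrices=False)
        U, s, Vt = U[:, :d], s[:d], Vt[:d]
    else:
        # largest-k sparse solver with a fixed starting vector for determinism
        v0 = np.ones(n)
        U, s, Vt = svds(mat, k=d, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    if not np.all(np.isfinite(s)):
        raise ArithmeticError("SVD did not converge: non-finite singular values")
    U, Vt = _fix_signs(U, Vt)
    W = U * s
    C = Vt.T * s
    return InitialFactors(W=W, C=C, singular_values=s)


def export_ppmi(P: AssociationMatrix, path) -> None:
    """Write stored PPMI entries (i <= j) as TSV with 6 decimal places."""
    coo = sp.triu(P.matrix, k=0).tocoo()
    order = np.lexsort((coo.col, coo.row))
    toks = P.vocab.tokens
    with open(path, "w", encoding="utf-8") as fh:
        for k in order:
            fh.write(
                f"{toks[coo.row[k]]}\t{toks[coo.col[k]]}\t{coo.data[k]:.6f}\n"
            )
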