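"""Vector merging, the augmented objective, its gradients, and AdaGrad."""

import numpy as np
import pytest
import scipy.sparse as sp

import relemb
from relemb.augment_train import (
    ADAGRAD_EPS,
    PairCategory,
    TrainingState,
    adagrad_step,
    categorize_pair,
    glove_weight,
    gradients,
    merge_vectors,
    objective,
    train,
    weight,
)
from relemb.corpus_io import Vocabulary
from relemb.ppmi_svd import AssociationMatrix
from relemb.relational import RelationTriple, build_repository_vectors

from conftest import random_count_matrix


def make_vocab(tokens):
    return Vocabulary(list(tokens), {t: 1 for t in tokens})


def random_association(rng, n, density=0.4):
    """Symmetric positive sparse association matrix."""
    vals = rng.random((n, n)) * 2.0
    mask = np.triu(rng.random((n, n)) < density, k=1)
    vals = np.where(mask, vals, 0.0)
    vals = vals + vals.T
    vocab = make_vocab([f"w{chr(97 + i // 26)}{chr(97 + i % 26)}" for i in range(n)])
    return AssociationMatrix(vocab, sp.csr_matrix(vals), float(vals.max()))


class TestCategorizePair:
    V = {"whipple", "fever"}

    @pytest.mark.parametrize(
        "w, c, expected",
        [
            ("whipple", "fever", PairCategory.BOTH),
            ("rare", "illness", PairCategory.NEITHER),
            ("whipple", "illness", PairCategory.ONE),
            ("illness", "fever", PairCategory.ONE),
        ],
    )
    def test_cases(self, w, c, expected):
        assert categorize_pair(w, c, self.V) is expected


class TestMergeVectors:
    def test_member_is_averaged(self):
        cv = make_vocab(["t"])
        rv = make_vocab(["t"])
        W = np.array([[1.0, 0.0]])
        What = np.array([[0.0, 1.0]])
        Wm, Cm = merge_vectors(W, W.copy(), What, What.copy(), cv, rv)
        assert np.allclose(Wm[0], [0.5, 0.5])

    def test_nonmember_kept_bitwise(self):
        cv = make_vocab(["t", "u"])
        rv = make_vocab(["t"])
        rng = np.random.default_rng(0)
        W = rng.normal(size=(2, 3))
        C = rng.normal(size=(2, 3))
        What = rng.normal(size=(1, 3))
        Chat = rng.normal(size=(1, 3))
        Wm, Cm = merge_vectors(W, C, What, Chat, cv, rv)
        assert np.array_equal(Wm[cv["u"]], W[cv["u"]])
        assert np.array_equal(Cm[cv["u"]], C[cv["u"]])

    def test_matches_per_token_rule_on_random_overlap(self):
        rng = np.random.default_rng(1)
        corpus_tokens = [f"c{chr(97 + i // 26)}{chr(97 + i % 26)}" for i in range(40)]
        repo_tokens = corpus_tokens[:15] + [f"r{chr(97 + i)}" for i in range(5)]
        cv = make_vocab(corpus_tokens)
        rv = make_vocab(repo_tokens)
        W = rng.normal(size=(40, 6))
        C = rng.normal(size=(40, 6))
        What = rng.normal(size=(20, 6))
        Chat = rng.normal(size=(20, 6))
        Wm, Cm = merge_vectors(W, C, What, Chat, cv, rv)
        for tok in corpus_tokens:
            i = cv[tok]
            if tok in rv:
                assert np.allclose(Wm[i], 0.5 * (W[i] + What[rv[tok]]))
                assert np.allclose(Cm[i], 0.5 * (C[i] + Chat[rv[tok]]))
            else:
                assert np.array_equal(Wm[i], W[i])

    def test_dimension_mismatch_rejected(self):
        cv = make_vocab(["t"])
        rv = make_vocab(["t"])
        with pytest.raises(ValueError, match="dimension mismatch"):
            merge_vectors(
                np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 4)), np.zeros((1, 4)), cv, rv
            )


class TestWeight:
    def test_at_max_is_one(self):
        assert weight(2.5, 2.5) == 1.0

    def test_closed_form_sixteenth(self):
        assert weight(1.0, 16.0, alpha=0.75) == pytest.approx(0.125, abs=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            weight(0.0, 1.0)
        with pytest.raises(ValueError):
            weight(-0.5, 1.0)

    def test_matches_formula_on_random_draws(self):
        rng = np.random.default_rng(2)
        p_max = 3.0
        p = rng.uniform(1e-6, p_max, size=1000)
        w = weight(p, p_max, alpha=0.75)
        assert np.allclose(w, np.minimum((p / p_max) ** 0.75, 1.0), atol=1e-14)
        assert np.all((w > 0) & (w <= 1))

    def test_glove_weight_caps_at_one(self):
        assert glove_weight(100.0, x_max=100.0) == 1.0
        assert glove_weight(400.0, x_max=100.0) == 1.0
        assert glove_weight(12.5, x_max=100.0, alpha=0.75) == pytest.approx(
            0.125**0.75
        )


def naive_objective(state, P, alpha):
    """Double-loop oracle for J_a over stored pairs."""
    dense = P.matrix.toarray()
    total = 0.0
    n = dense.shape[0]
    for i in range(n):
        for j in range(n):
            p = dense[i, j]
            if p > 0:
                f = min((p / P.p_max) ** alpha, 1.0)
                r = state.W[i] @ state.C[j] + state.b_w[i] + state.b_c[j] - np.log(p)
                total += 0.5 * f * r * r
    return total


class TestObjective:
    def test_zero_residual_gives_zero(self):
        vocab = make_vocab(["a", "b"])
        p = 2.0
        P = AssociationMatrix(vocab, sp.csr_matrix(np.array([[0.0, p], [p, 0.0]])), p)
        # choose b so that w'c' + b_w + b_c = log p exactly
        state = TrainingState(
            W=np.zeros((2, 2)),
            C=np.zeros((2, 2)),
            b_w=np.full(2, np.log(p) / 2),
            b_c=np.full(2, np.log(p) / 2),
        )
        assert objective(state, P) == pytest.approx(0.0, abs=1e-15)

    def test_single_pair_half_r_squared(self):
        vocab = make_vocab(["a", "b"])
        p = np.e  # log p = 1, f = 1 at the max
        mat = sp.csr_matrix(np.array([[0.0, p], [0.0, 0.0]]))
        P = AssociationMatrix(vocab, mat, float(p))
        state = TrainingState(
            W=np.zeros((2, 1)), C=np.zeros((2, 1)), b_w=np.zeros(2), b_c=np.zeros(2)
        )
        # residual = -log p = -1
        assert objective(state, P) == pytest.approx(0.5, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        P = random_association(rng, 20)
        state = TrainingState(
            W=rng.normal(size=(20, 5)),
            C=rng.normal(size=(20, 5)),
            b_w=rng.normal(size=20),
            b_c=rng.normal(size=20),
        )
        assert objective(state, P, 0.75) == pytest.approx(
            naive_objective(state, P, 0.75), abs=1e-10
        )


class TestGradients:
    def test_zero_at_zero_residual(self):
        vocab = make_vocab(["a", "b"])
        p = 2.0
        P = AssociationMatrix(vocab, sp.csr_matrix(np.array([[0.0, p], [p, 0.0]])), p)
        state = TrainingState(
            W=np.zeros((2, 2)),
            C=np.zeros((2, 2)),
            b_w=np.full(2, np.log(p) / 2),
            b_c=np.full(2, np.log(p) / 2),
        )
        for g in gradients(state, P):
            assert np.allclose(g, 0.0, atol=1e-15)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(4)
        P = random_association(rng, 10)
        d = 4
        state = TrainingState(
            W=rng.normal(size=(10, d)),
            C=rng.normal(size=(10, d)),
            b_w=rng.normal(size=10),
            b_c=rng.normal(size=10),
        )
        gW, gC, gbw, gbc = gradients(state, P, 0.75)
        h = 1e-5
        for arr, grad in ((state.W, gW), (state.C, gC), (state.b_w, gbw), (state.b_c, gbc)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                jp = objective(state, P, 0.75)
                arr[idx] = orig - h
                jm = objective(state, P, 0.75)
                arr[idx] = orig
                num = (jp - jm) / (2 * h)
                denom = max(1.0, abs(num), abs(grad[idx]))
                assert abs(num - grad[idx]) / denom < 1e-5

    def test_tokens_without_pairs_have_zero_gradient(self):
        vocab = make_vocab(["a", "b", "c"])
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 1.5
        P = AssociationMatrix(vocab, sp.csr_matrix(mat), 1.5)
        rng = np.random.default_rng(5)
        state = TrainingState(
            W=rng.normal(size=(3, 2)),
            C=rng.normal(size=(3, 2)),
            b_w=rng.normal(size=3),
            b_c=rng.normal(size=3),
        )
        gW, gC, gbw, gbc = gradients(state, P)
        assert np.all(gW[2] == 0) and np.all(gC[2] == 0)
        assert gbw[2] == 0 and gbc[2] == 0


class TestAdaGrad:
    def test_first_step_magnitude_is_eta(self):
        state = TrainingState(
            W=np.zeros((2, 3)), C=np.zeros((2, 3)), b_w=np.zeros(2), b_c=np.zeros(2),
            eta=0.05,
        )
        rng = np.random.default_rng(6)
        # |g| >= 0.1 keeps the eps correction below the 1e-6 tolerance
        g = tuple(
            rng.uniform(0.1, 2.0, size=s.shape) * rng.choice([-1.0, 1.0], size=s.shape)
            for s in (state.W, state.C, state.b_w, state.b_c)
        )
        adagrad_step(state, g)
        for theta, grad in zip((state.W, state.C, state.b_w, state.b_c), g):
            nz = grad != 0
            assert np.allclose(np.abs(theta[nz]), 0.05, atol=1e-6)
            assert np.all(np.sign(theta[nz]) == -np.sign(grad[nz]))

    def test_zero_gradient_leaves_parameter_and_accumulator(self):
        state = TrainingState(
            W=np.ones((1, 2)), C=np.ones((1, 2)), b_w=np.ones(1), b_c=np.ones(1)
        )
        zeros = tuple(np.zeros_like(a) for a in (state.W, state.C, state.b_w, state.b_c))
        adagrad_step(state, zeros)
        assert np.all(state.W == 1.0)
        assert np.all(state.G_w == 0.0)

    def test_five_scripted_steps_match_hand_recurrence(self):
        state = TrainingState(
            W=np.array([[1.0]]), C=np.zeros((1, 1)), b_w=np.zeros(1), b_c=np.zeros(1),
            eta=0.05,
        )
        gs = [0.3, -0.7, 0.1, 0.9, -0.2]
        # hand-rolled scalar recurrence
        theta, acc = 1.0, 0.0
        for g in gs:
            acc += g * g
            theta -= 0.05 * g / np.sqrt(acc + ADAGRAD_EPS)
        for g in gs:
            adagrad_step(
                state,
                (np.array([[g]]), np.zeros((1, 1)), np.zeros(1), np.zeros(1)),
            )
        assert state.W[0, 0] == pytest.approx(theta, abs=1e-12)

    def test_accumulators_nondecreasing(self):
        rng = np.random.default_rng(7)
        state = TrainingState(
            W=rng.normal(size=(3, 2)), C=rng.normal(size=(3, 2)),
            b_w=np.zeros(3), b_c=np.zeros(3),
        )
        prev = state.G_w.copy()
        for _ in range(4):
            g = tuple(rng.normal(size=s.shape) for s in (state.W, state.C, state.b_w, state.b_c))
            adagrad_step(state, g)
            assert np.all(state.G_w >= prev)
            prev = state.G_w.copy()


class TestTrain:
    def test_loss_decreases_on_toy_problem(self):
        rng = np.random.default_rng(8)
        P = random_association(rng, 12)
        _, state = train(P, d=4, iterations=50, seed=0)
        assert state.loss_trace[-1] < state.loss_trace[0]

    def test_merged_view_is_average(self, tiny_embeddings):
        emb, _ = tiny_embeddings
        assert np.array_equal(
            emb.Merged.vectors, (emb.WE.vectors + emb.CE.vectors) / 2.0
        )

    def test_disjoint_repository_bit_identical_to_baseline(self, tiny_ppmi):
        repo = build_repository_vectors(
            [RelationTriple("zzzqa", "zzzqb", "zzzqc")], d=16
        )
        assert not any(t in tiny_ppmi.vocab for t in repo.vocab.tokens)
        e0, s0 = train(tiny_ppmi, d=16, seed=3)
        e1, s1 = train(tiny_ppmi, repository=repo, d=16, seed=3)
        assert np.array_equal(e0.WE.vectors, e1.WE.vectors)
        assert np.array_equal(e0.CE.vectors, e1.CE.vectors)
        assert s0.loss_trace == s1.loss_trace

    def test_same_seed_reproducible(self, tiny_ppmi):
        e0, _ = train(tiny_ppmi, d=8, iterations=5, seed=9)
        e1, _ = train(tiny_ppmi, d=8, iterations=5, seed=9)
        assert np.array_equal(e0.Merged.vectors, e1.Merged.vectors)

    def test_full_batch_mode_also_descends(self):
        rng = np.random.default_rng(10)
        P = random_association(rng, 15)
        _, state = train(P, d=5, iterations=50, seed=0, batch_mode="full")
        assert state.loss_trace[-1] < state.loss_trace[0]

    def test_dimension_mismatch_with_repository(self, tiny_ppmi):
        repo = build_repository_vectors(
            [RelationTriple("alpha", "rel", "beta")], d=4
        )
        with pytest.raises(ValueError, match="dimension"):
            train(tiny_ppmi, repository=repo, d=8, seed=0)

    def test_estimator_wrapper_fits_and_transforms(self, tiny_spec):
        from relemb.synthetic_data import generate_corpus, generate_triples

        corpus, _ = generate_corpus(tiny_spec)
        est = relemb.RelationalWordEmbedding(
            dim=8, window=5, n_iter=5, random_state=0
        ).fit(corpus, triples=generate_triples(tiny_spec))
        assert est.loss_trace_[-1] < est.loss_trace_[0]
        assert "whipple" in est.repository_
        X = est.transform([["whipple", "fever"], ["nosuchtoken"]])
        assert X.shape == (2, 8)
        assert np.all(X[1] == 0)

    def test_estimator_sklearn_clone(self):
        from sklearn.base import clone

        est = relemb.RelationalWordEmbedding(dim=7, window=3)
        cloned = clone(est)
        assert cloned.get_params()["dim"] == 7
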