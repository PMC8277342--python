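"""Embedding fine-tuning: loss, gradients, optimizer, vector IO."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from ocdtext import (CooccurrenceMatrix, EmbedConfig, EmbeddingTable,
                     Vocabulary, fit_mittens, glove_weight, mittens_loss,
                     read_vectors, train_mittens, write_vectors)
from ocdtext.embedding import TrainingState, _init_state


def _two_word_cooc(x12):
    vocab = Vocabulary(index={"a": 0, "b": 1}, frequency={"a": 1, "b": 1})
    X = np.array([[0.0, x12], [x12, 0.0]])
    return CooccurrenceMatrix(sp.csr_matrix(X), vocab)


class TestGloveWeight:
    @pytest.mark.parametrize("x,expected", [
        (100.0, 1.0),                      # cap boundary
        (150.0, 1.0),                      # above cap
        (0.0, 0.0),                        # zero count
        (1.0, 100.0 ** -0.75),             # = 0.03162...
    ])
    def test_values(self, x, expected):
        assert glove_weight(x, 100.0, 0.75) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        xs = rng.uniform(0, 500, size=200)
        w = glove_weight(xs, 100.0, 0.75)
        assert np.all((0 <= w) & (w <= 1))
        assert np.all(np.diff(w[np.argsort(xs)]) >= 0)  # monotone


class TestMittensLoss:
    def test_perfect_fit_zero_loss(self):
        cooc = _two_word_cooc(math.e)
        # w.wc + b + bc = 1 = log(e) for both ordered pairs
        state = TrainingState(words=["a", "b"],
                              W=np.zeros((2, 3)), Wc=np.zeros((2, 3)),
                              b=np.full(2, 0.5), bc=np.full(2, 0.5),
                              ref=np.zeros((2, 3)),
                              has_ref=np.zeros(2, dtype=bool))
        assert mittens_loss(state, cooc, EmbedConfig(dim=3, mu=0.0)) == 0.0

    def test_two_word_toy_hand_computation(self):
        # zero parameters, X_12 = e: each ordered pair contributes
        # f(e) * (0 - 1)^2; penalty adds mu * sum ||r_i||^2
        cooc = _two_word_cooc(math.e)
        r = np.array([[1.0, 2.0], [3.0, 4.0]])
        state = TrainingState(words=["a", "b"],
                              W=np.zeros((2, 2)), Wc=np.zeros((2, 2)),
                              b=np.zeros(2), bc=np.zeros(2),
                              ref=r, has_ref=np.ones(2, dtype=bool))
        got = mittens_loss(state, cooc, EmbedConfig(dim=2, mu=0.1))
        expected = 2.0 * glove_weight(math.e) + 0.1 * float((r ** 2).sum())
        assert got == pytest.approx(expected, rel=1e-12)

    def test_mu_zero_equals_plain_glove_summation(self, random_cooccurrence):
        cfg = EmbedConfig(dim=4, mu=0.0, seed=5)
        state = _init_state(random_cooccurrence, None, cfg)
        dense = np.asarray(random_cooccurrence.matrix.todense(), dtype=float)
        naive = 0.0
        for i in range(5):
            for j in range(5):
                if dense[i, j] > 0:
                    delta = (state.W[i] @ state.Wc[j] + state.b[i]
                             + state.bc[j] - math.log(dense[i, j]))
                    naive += glove_weight(dense[i, j]) * delta ** 2
        got = mittens_loss(state, random_cooccurrence, cfg)
        assert got == pytest.approx(naive, rel=1e-12)

    def test_nonfinite_parameters_rejected(self, random_cooccurrence):
        cfg = EmbedConfig(dim=4)
        state = _init_state(random_cooccurrence, None, cfg)
        state.W[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            mittens_loss(state, random_cooccurrence, cfg)

    def test_invariant_to_vocabulary_reordering(self, rng):
        words = ["a", "b", "c", "d"]
        upper = np.triu(rng.integers(1, 9, size=(4, 4)), k=1)
        dense = (upper + upper.T).astype(float)
        perm = [2, 0, 3, 1]
        losses = []
        for order in (list(range(4)), perm):
            vocab = Vocabulary(
                index={words[o]: i for i, o in enumerate(order)},
                frequency={w: 1 for w in words})
            X = dense[np.ix_(order, order)]
            cooc = CooccurrenceMatrix(sp.csr_matrix(X), vocab)
            W = rng.standard_normal((4, 3))
            # reuse the same per-word parameters in both orderings
            if not losses:
                params = {words[o]: (W[i].copy(), i) for i, o in
                          enumerate(order)}
            Wp = np.vstack([params[words[o]][0] for o in order])
            state = TrainingState(words=[words[o] for o in order],
                                  W=Wp, Wc=Wp * 0.5,
                                  b=np.zeros(4), bc=np.zeros(4),
                                  ref=np.zeros((4, 3)),
                                  has_ref=np.zeros(4, dtype=bool))
            losses.append(mittens_loss(state, cooc, EmbedConfig(dim=3,
                                                                mu=0.0)))
        assert losses[0] == pytest.approx(losses[1], rel=1e-12)


def _numerical_gradient(state, cooc, cfg, arr, idx, h=1e-6):
    orig = arr[idx]
    arr[idx] = orig + h
    up = mittens_loss(state, cooc, cfg)
    arr[idx] = orig - h
    down = mittens_loss(state, cooc, cfg)
    arr[idx] = orig
    return (up - down) / (2 * h)


def test_analytic_gradients_match_finite_differences(random_cooccurrence,
                                                     rng):
    cfg = EmbedConfig(dim=3, mu=0.5, seed=2)
    pre = EmbeddingTable(words=["a", "c"],
                         vectors={"a": rng.standard_normal(3),
                                  "c": rng.standard_normal(3)}, dim=3)
    state = _init_state(random_cooccurrence, pre, cfg)
    state.W += rng.standard_normal(state.W.shape) * 0.1
    dense = np.asarray(random_cooccurrence.matrix.todense(), dtype=float)
    mask = dense > 0
    weights = np.where(mask, glove_weight(dense, cfg.x_max, cfg.alpha), 0.0)
    logx = np.where(mask, np.log(np.where(mask, dense, 1.0)), 0.0)
    scores = state.W @ state.Wc.T + state.b[:, None] + state.bc[None, :]
    g = 2.0 * weights * (scores - logx)
    grad_W = g @ state.Wc
    grad_Wc = g.T @ state.W
    grad_b = g.sum(axis=1)
    grad_bc = g.sum(axis=0)
    pen = 2.0 * cfg.mu * (state.W + state.Wc - state.ref)
    pen[~state.has_ref] = 0.0
    grad_W = grad_W + pen
    grad_Wc = grad_Wc + pen
    for arr, grad in ((state.W, grad_W), (state.Wc, grad_Wc),
                      (state.b, grad_b), (state.bc, grad_bc)):
        flat_idx = [np.unravel_index(i, arr.shape)
                    for i in rng.choice(arr.size, size=4, replace=False)]
        for idx in flat_idx:
            num = _numerical_gradient(state, random_cooccurrence, cfg,
                                      arr, idx)
            denom = max(abs(num), abs(grad[idx]), 1e-8)
            assert abs(num - grad[idx]) / denom <= 1e-4


class TestFitMittens:
    def test_huge_mu_pins_vectors_to_pretrained(self, random_cooccurrence):
        pre = fit_mittens(random_cooccurrence, None,
                          EmbedConfig(dim=4, mu=0.0, n_epochs=5, seed=9))
        cfg = EmbedConfig(dim=4, mu=1e6, n_epochs=10, seed=3)
        out = fit_mittens(random_cooccurrence, pre, cfg)
        assert max(np.linalg.norm(out[w] - pre[w]) for w in pre.words) <= 1e-2

    def test_mu_zero_matches_independent_glove_loop(self,
                                                    random_cooccurrence):
        """Reference plain-GloVe AdaGrad reimplemented with explicit loops.

        The two computations differ only in float-addition order (BLAS vs
        sequential loops), so they agree to the last ulp.
        """
        cfg = EmbedConfig(dim=4, mu=0.0, n_epochs=30, seed=3)
        dense = np.asarray(random_cooccurrence.matrix.todense(), dtype=float)
        n, d, lr = 5, cfg.dim, cfg.learning_rate
        ref_rng = np.random.default_rng(cfg.seed)
        lim = 0.5 / d
        W = ref_rng.uniform(-lim, lim, size=(n, d))
        Wc = ref_rng.uniform(-lim, lim, size=(n, d))
        b = ref_rng.uniform(-lim, lim, size=n)
        bc = ref_rng.uniform(-lim, lim, size=n)
        accs = [np.zeros_like(W), np.zeros_like(Wc),
                np.zeros_like(b), np.zeros_like(bc)]
        for _ in range(cfg.n_epochs):
            gW, gWc = np.zeros_like(W), np.zeros_like(Wc)
            gb, gbc = np.zeros_like(b), np.zeros_like(bc)
            for i in range(n):
                for j in range(n):
                    if dense[i, j] <= 0:
                        continue
                    f = glove_weight(dense[i, j], cfg.x_max, cfg.alpha)
                    delta = (float(W[i] @ Wc[j]) + b[i] + bc[j]
                             - math.log(dense[i, j]))
                    g = 2.0 * f * delta
                    gW[i] += g * Wc[j]
                    gWc[j] += g * W[i]
                    gb[i] += g
                    gbc[j] += g
            for p, g, acc in zip((W, Wc, b, bc), (gW, gWc, gb, gbc), accs):
                acc += g ** 2
                p -= lr * g / (np.sqrt(acc) + 1e-8)
        table = fit_mittens(random_cooccurrence, None, cfg)
        mine = table.matrix(["a", "b", "c", "d", "e"])
        np.testing.assert_allclose(mine, W + Wc, rtol=0, atol=1e-15)

    def test_loss_decreases_over_training(self, random_cooccurrence):
        cfg = EmbedConfig(dim=4, mu=0.1, n_epochs=60, learning_rate=0.05,
                          seed=1)
        pre = fit_mittens(random_cooccurrence, None,
                          EmbedConfig(dim=4, mu=0.0, n_epochs=3, seed=7))
        _, history = train_mittens(random_cooccurrence, pre, cfg)
        assert history[50] <= history[1]
        assert all(np.isfinite(history))

    def test_mu_monotonicity_of_displacement(self, random_cooccurrence):
        pre = fit_mittens(random_cooccurrence, None,
                          EmbedConfig(dim=4, mu=0.0, n_epochs=5, seed=9))
        disps = []
        for mu in (0.0, 0.1, 1.0, 10.0, 100.0):
            out = fit_mittens(random_cooccurrence, pre,
                              EmbedConfig(dim=4, mu=mu, n_epochs=200,
                                          seed=3))
            disps.append(sum(float(np.sum((out[w] - pre[w]) ** 2))
                             for w in pre.words))
        assert all(a >= b - 1e-12 for a, b in zip(disps, disps[1:]))

    def test_words_without_pretrained_vectors_still_train(
            self, random_cooccurrence):
        pre = EmbeddingTable(words=["a", "b"],
                             vectors={"a": np.ones(4), "b": -np.ones(4)},
                             dim=4)
        out = fit_mittens(random_cooccurrence, pre,
                          EmbedConfig(dim=4, mu=0.1, n_epochs=50, seed=4))
        for w in ("c", "d", "e"):
            assert np.all(np.isfinite(out[w]))
            assert np.any(out[w] != 0)

    def test_deterministic_given_seed(self, random_cooccurrence):
        cfg = EmbedConfig(dim=4, n_epochs=20, seed=6)
        t1 = fit_mittens(random_cooccurrence, None, cfg)
        t2 = fit_mittens(random_cooccurrence, None, cfg)
        assert all(np.array_equal(t1[w], t2[w]) for w in t1.words)

    def test_dimension_mismatch_rejected(self, random_cooccurrence):
        pre = EmbeddingTable(words=["a"], vectors={"a": np.zeros(7)}, dim=7)
        with pytest.raises(ValueError):
            fit_mittens(random_cooccurrence, pre, EmbedConfig(dim=4))


class TestVectorIO:
    def test_round_trip(self, tmp_path, rng):
        table = EmbeddingTable(words=["cat", "dog", "eel"],
                               vectors={w: rng.standard_normal(5)
                                        for w in ("cat", "dog", "eel")},
                               dim=5)
        path = tmp_path / "vecs.txt"
        write_vectors(table, path)
        back = read_vectors(path)
        assert back.words == table.words
        for w in table.words:
            np.testing.assert_allclose(back[w], table[w], atol=1e-8)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("dog 0.1 0.2 0.3\ncat 0.1 0.2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_vectors(path)

    def test_restricting_to_vocabulary(self, tmp_path, rng):
        path = tmp_path / "big.txt"
        with open(path, "w") as fh:
            for i in range(2000):
                vals = " ".join(f"{v:.4f}" for v in rng.standard_normal(3))
                fh.write(f"word{i} {vals}\n")
        keep = [f"word{i}" for i in range(0, 2000, 20)]
        table = read_vectors(path, restrict_to=keep)
        assert len(table.words) == 100
        assert set(table.words) == set(keep)
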