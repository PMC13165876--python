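"""Subspace decomposition, encoder, gradients, attention, voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gazecog as gc
from gazecog.model import mil, nn
from gazecog.model.encoder import EMBED_DIM, MSPCNNEncoder


def brute_force_window_count(L, W, S):
    count = 0
    start = 0
    while start + W <= L:
        count += 1
        start += S
    return count


class TestMakeSubspaces:
    def test_example_counts(self):
        spec = gc.WindowSpec(W=150, S=50)
        assert len(mil.make_subspaces(np.zeros((3, 250)), spec)) == 3
        assert len(mil.make_subspaces(np.zeros((3, 150)), spec)) == 1

    def test_tail_discard_boundary(self):
        spec = gc.WindowSpec(W=150, S=50)
        with pytest.warns(UserWarning):
            bag = mil.make_subspaces(np.zeros((3, 149)), spec)
        assert len(bag) == 0

    def test_single_window_is_whole_sequence(self):
        X = np.arange(2 * 150, dtype=float).reshape(2, 150)
        bag = mil.make_subspaces(X, gc.WindowSpec(W=150, S=50))
        np.testing.assert_array_equal(bag.instances[0], X)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(L=st.integers(1, 700), W=st.integers(1, 200), S=st.integers(1, 200))
    def test_count_matches_brute_enumeration(self, L, W, S):
        if S > W:
            return
        spec = gc.WindowSpec(W=W, S=S)
        assert spec.count(L) == brute_force_window_count(L, W, S)

    def test_window_contents_match_definition(self):
        X = np.arange(400, dtype=float).reshape(1, 400)
        spec = gc.WindowSpec(W=150, S=50)
        bag = mil.make_subspaces(X, spec)
        for n_idx in range(len(bag)):
            np.testing.assert_array_equal(
                bag.instances[n_idx][0],
                X[0, n_idx * 50:n_idx * 50 + 150])


class TestEncoder:
    def test_embedding_length_144(self):
        enc = MSPCNNEncoder(17, np.random.default_rng(0))
        z, _ = enc.forward(np.random.default_rng(1).normal(size=(2, 17, 150)))
        assert z.shape == (2, EMBED_DIM) == (2, 144)

    def test_zero_input_zero_biases_zero_embedding(self):
        enc = MSPCNNEncoder(5, np.random.default_rng(0))
        z, _ = enc.forward(np.zeros((1, 5, 150)))
        np.testing.assert_allclose(z, 0.0)

    def test_not_time_reversal_invariant(self):
        enc = MSPCNNEncoder(3, np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(1, 3, 150))
        z_fwd, _ = enc.forward(x)
        z_rev, _ = enc.forward(x[:, :, ::-1].copy())
        assert np.abs(z_fwd - z_rev).max() > 1e-4


class TestGradients:
    """Backward passes validated against central finite differences."""

    @staticmethod
    def numgrad(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            fp = f()
            x[i] -= 2 * eps
            fm = f()
            x[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        return g

    def test_conv1d_gradients(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 12))
        W = rng.normal(size=(4, 3, 5))
        b = rng.normal(size=4)

        def loss():
            y, _ = nn.conv1d_forward(x, W, b, pad=2)
            return float((y ** 2).sum() / 2)

        y, cache = nn.conv1d_forward(x, W, b, pad=2)
        dx, dW, db = nn.conv1d_backward(y, cache)
        np.testing.assert_allclose(dx, self.numgrad(loss, x), atol=1e-5)
        np.testing.assert_allclose(dW, self.numgrad(loss, W), atol=1e-5)
        np.testing.assert_allclose(db, self.numgrad(loss, b), atol=1e-5)

    def test_maxpool_gradient(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 11))

        def loss():
            y, _ = nn.maxpool1d_forward(x, 2)
            return float((y ** 2).sum() / 2)

        y, cache = nn.maxpool1d_forward(x, 2)
        dx = nn.maxpool1d_backward(y, cache)
        np.testing.assert_allclose(dx, self.numgrad(loss, x), atol=1e-5)

    def test_attention_parameter_gradients(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(5, 8))
        params = {"Wv": rng.normal(size=(4, 8)), "Wu": rng.normal(size=(4, 8)),
                  "w": rng.normal(size=4), "Wc": rng.normal(size=(2, 8)),
                  "bc": rng.normal(size=2)}
        label = 1

        def loss():
            logits, _ = mil._attn_forward_full(z, params)
            l, _, _ = nn.softmax_xent(logits[None, :], np.array([label]))
            return l

        logits, cache = mil._attn_forward_full(z, params)
        _, dlogits, _ = nn.softmax_xent(logits[None, :], np.array([label]))
        grads = mil._attn_backward(dlogits[0], cache, params)
        for key in ("Wv", "Wu", "w", "Wc", "bc"):
            np.testing.assert_allclose(
                grads[key], self.numgrad(loss, params[key]), atol=1e-5,
                err_msg=key)


class TestGatedAttention:
    def test_singleton_bag(self):
        rng = np.random.default_rng(0)
        params = mil.init_attention(rng, D=144)
        z = rng.normal(size=(1, 144))
        a, z_bag = gc.gated_attention(z, params)
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(z_bag, z[0], atol=1e-6)

    def test_identical_instances_uniform_attention(self):
        rng = np.random.default_rng(1)
        params = mil.init_attention(rng, D=144)
        z = np.tile(rng.normal(size=144), (4, 1))
        a, _ = gc.gated_attention(z, params)
        np.testing.assert_allclose(a, 0.25, atol=1e-7)

    def test_matches_hand_rolled_loop(self):
        rng = np.random.default_rng(2)
        params = mil.init_attention(rng, D=16, K=6)
        z = rng.normal(size=(7, 16))
        a, z_bag = gc.gated_attention(z, params)
        # independent per-instance loop evaluation
        e = np.empty(7)
        for n_i in range(7):
            t = np.tanh(params["Wv"] @ z[n_i])
            s = 1 / (1 + np.exp(-params["Wu"] @ z[n_i]))
            e[n_i] = params["w"] @ (t * s)
        a_ref = np.exp(e - e.max())
        a_ref /= a_ref.sum()
        z_ref = sum(a_ref[n_i] * z[n_i] for n_i in range(7))
        np.testing.assert_allclose(a, a_ref, atol=1e-10)
        np.testing.assert_allclose(z_bag, z_ref, atol=1e-10)

    def test_attention_simplex_and_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        params = mil.init_attention(rng, D=12, K=5)
        z = rng.normal(size=(6, 12))
        a, z_bag = gc.gated_attention(z, params)
        assert (a >= 0).all()
        assert a.sum() == pytest.approx(1.0)
        perm = rng.permutation(6)
        a_p, z_bag_p = gc.gated_attention(z[perm], params)
        np.testing.assert_allclose(a_p, a[perm], atol=1e-12)
        np.testing.assert_allclose(z_bag_p, z_bag, atol=1e-12)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            gc.gated_attention(np.zeros((0, 144)),
                               mil.init_attention(np.random.default_rng(0)))


class TestSoftWeighting:
    def test_zero_loss_gives_unit_weight(self):
        assert np.exp(-1.0 * 0.0) == 1.0

    def test_weight_monotone_decreasing_in_loss(self):
        losses = np.array([0.0, 0.5, 1.0, 3.0])
        w = np.exp(-1.0 * losses)
        assert (np.diff(w) < 0).all()

    def test_phase1_learns_separable_instances(self):
        rng = np.random.default_rng(5)
        n = 80
        X = rng.normal(size=(2 * n, 4, 60)).astype(np.float32)
        X[n:, 0] += 2.0  # class-1 windows carry a mean shift
        y = np.array([0] * n + [1] * n)
        enc, head = mil.phase1_train(
            X, y, mil.SoftWeightConfig(epochs=15), rng, in_channels=4)
        logits, _ = head.forward(enc.encode(X))
        assert (logits.argmax(1) == y).mean() >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mil.phase1_train(np.zeros((4, 2, 60), dtype=np.float32),
                             np.zeros(4, dtype=int),
                             mil.SoftWeightConfig(epochs=1),
                             np.random.default_rng(0), in_channels=2)


class TestPhase2:
    def test_encoder_frozen_during_phase2(self):
        rng = np.random.default_rng(6)
        enc = MSPCNNEncoder(3, rng)
        before = {k: v.copy() for k, v in enc.params.items()}
        bags = [(rng.normal(size=(4, 3, 60)).astype(np.float32), i % 2)
                for i in range(6)]
        mil.phase2_train(bags, enc, mil.Phase2Config(epochs=2), rng)
        for k in before:
            np.testing.assert_array_equal(enc.params[k], before[k])

    def test_planted_signal_window_gets_max_attention(self):
        rng = np.random.default_rng(7)
        n_bags, n_inst = 20, 8
        bags, signal_at = [], []
        for i in range(n_bags):
            x = rng.normal(size=(n_inst, 3, 60)).astype(np.float32)
            lab = i % 2
            j = int(rng.integers(n_inst))
            if lab == 1:
                x[j, 1] += 3.0  # one window carries the class signal
            bags.append((x, lab))
            signal_at.append(j)
        inst = np.concatenate([b[0] for b in bags])
        labels = np.concatenate([np.full(n_inst, b[1]) for b in bags])
        enc, _ = mil.phase1_train(inst, labels,
                                  mil.SoftWeightConfig(epochs=12), rng,
                                  in_channels=3)
        params = mil.phase2_train(bags, enc, mil.Phase2Config(epochs=20), rng)
        hits = 0
        positives = 0
        for (x, lab), j in zip(bags, signal_at):
            if lab != 1:
                continue
            positives += 1
            pred = mil.predict_bag(enc.encode(x), params)
            hits += int(pred.attention.argmax() == j)
        assert hits / positives >= 0.8


class TestVotingAndMetrics:
    def test_majority_examples(self):
        T = list(mil.TASKS)
        votes = dict(zip(T, [1, 1, 1, 0, 0]))
        assert mil.majority_vote(votes).final == 1
        votes = dict(zip(T, [0, 0, 0, 0, 0]))
        assert mil.majority_vote(votes).final == 0

    def test_tie_after_abstention_flags_cd(self):
        T = list(mil.TASKS)
        votes = dict(zip(T, [1, 1, 0, 0, None]))
        result = mil.majority_vote(votes)
        assert result.final == 1
        assert result.tie_flag

    def test_metrics_closed_form(self):
        # TP=5, FP=1, FN=0, TN=4
        y_true = np.array([1] * 5 + [0] * 5)
        y_pred = np.array([1] * 5 + [1] + [0] * 4)
        m = gc.classification_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["precision"] == pytest.approx(5 / 6)
        assert m["recall"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 * (5 / 6) / (1 + 5 / 6))

    def test_perfect_predictor(self):
        y = np.array([0, 1, 1, 0])
        m = gc.classification_metrics(y, y)
        assert all(v == 1.0 for v in m.values())

    def test_no_positive_predictions_zero_precision(self):
        m = gc.classification_metrics(np.array([1, 1]), np.array([0, 0]))
        assert m["precision"] == 0.0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_cohort):
        rng = np.random.default_rng(0)
        subs = [mil.prepare_subject(r, int(r.group is gc.Group.CD),
                                    window=gc.WindowSpec(W=150, S=150))
                for r in tiny_cohort.sessions]
        models = mil.train_task_models(
            subs, [], rng,
            mil.SoftWeightConfig(epochs=1), mil.Phase2Config(epochs=1))
        path = tmp_path / "models.npz"
        mil.save_models(models, path)
        loaded = mil.load_models(path)
        assert set(loaded) == set(models)
        for task in models:
            before = mil.predict_subject(subs[0], models).votes[task]
            after = mil.predict_subject(subs[0], loaded).votes[task]
            assert before == after
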