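"""Sequence classifiers: attention math, gradients, training mechanics."""

import numpy as np
import pytest

import wristgait as wg
from wristgait import autodiff as ad
from wristgait.models import (
    ModelSpec,
    SequenceClassifier,
    TrainConfig,
    _Adam,
    attention_path,
)


def _spec(arch="lstm_att", T=20, D=4, M=3, h=8, **kw):
    return ModelSpec(arch=arch, T=T, D=D, n_classes=M, hidden_size=h,
                     embed_size=kw.pop("embed_size", 16), seed=kw.pop("seed", 0),
                     **kw)


def _random_set(spec, n=24, seed=0):
    rng = np.random.default_rng(seed)
    segs = [
        wg.Segment(rng.normal(size=(spec.T, spec.D)), class_id=i % spec.n_classes,
                   subject_id=i % 4, source_recording_id="r")
        for i in range(n)
    ]
    return wg.SegmentSet(segs, [f"c{i}" for i in range(spec.n_classes)])


class TestAttentionOp:
    def test_identical_states_give_uniform_alpha_and_context(self):
        T, h = 12, 5
        state = np.random.default_rng(0).normal(size=h)
        states = np.tile(state, (T, 1))
        Wa = np.random.default_rng(1).normal(size=(h, h))
        alpha, context, _ = wg.multiplicative_attention(states, Wa)
        np.testing.assert_allclose(alpha, np.full(T, 1.0 / T), atol=1e-12)
        np.testing.assert_allclose(context, state, atol=1e-12)

    def test_orthonormal_states_identity_score_closed_form(self):
        T = 5
        states = np.eye(T)  # orthonormal, a_T = e_T in the set
        alpha, _, _ = wg.multiplicative_attention(states, np.eye(T))
        e = np.e
        expected = np.full(T, 1.0 / (e + T - 1))
        expected[-1] = e / (e + T - 1)
        np.testing.assert_allclose(alpha, expected, atol=1e-12)

    def test_context_matches_explicit_loop(self):
        rng = np.random.default_rng(7)
        for T in (6, 150):
            states = rng.normal(size=(T, 8))
            Wa = rng.normal(size=(8, 8))
            alpha, context, _ = wg.multiplicative_attention(states, Wa)
            assert abs(alpha.sum() - 1.0) < 1e-6 and (alpha >= 0).all()
            ctx = np.zeros(8)
            for t in range(T):
                ctx += alpha[t] * states[t]
            np.testing.assert_allclose(context, ctx, atol=1e-6)

    def test_h_tilde_bounded_by_tanh(self):
        rng = np.random.default_rng(3)
        states = rng.normal(size=(10, 6))
        _, _, h_tilde = wg.multiplicative_attention(
            states, rng.normal(size=(6, 6)), Wc=rng.normal(size=(12, 4)),
            bc=np.zeros(4),
        )
        assert (np.abs(h_tilde) < 1.0).all()


class TestGradients:
    def test_attention_cross_entropy_path_matches_finite_differences(self):
        """Analytic gradients on a T=6, h=4, M=3 attention head vs central
        differences (h=1e-5) within 1e-4 relative error."""
        rng = np.random.default_rng(0)
        T, h, M, E = 6, 4, 3, 5
        states = rng.normal(size=(2, T, h))
        params = {
            "Wa": rng.normal(size=(h, h)),
            "Wc": rng.normal(size=(2 * h, E)),
            "bc": rng.normal(size=E),
            "Ws": rng.normal(size=(E, M)),
            "bs": rng.normal(size=M),
        }
        y = np.eye(M)[[0, 2]]
        loss, leaves = attention_path(states, params, y)
        loss.backward()

        def value(name, flat):
            p2 = {k: v.copy() for k, v in params.items()}
            s2 = states.copy()
            if name == "states":
                s2 = flat.reshape(states.shape)
            else:
                p2[name] = flat.reshape(params[name].shape)
            l2, _ = attention_path(s2, p2, y)
            return float(l2.data)

        eps = 1e-5
        for name, leaf in leaves.items():
            base = (states if name == "states" else params[name]).ravel()
            grad = leaf.grad.ravel()
            for i in range(base.size):
                e = np.zeros_like(base)
                e[i] = eps
                num = (value(name, base + e) - value(name, base - e)) / (2 * eps)
                denom = max(abs(num), abs(grad[i]), 1e-8)
                assert abs(num - grad[i]) / denom < 1e-4, (name, i)

    @pytest.mark.parametrize("arch", ["conv1d", "lstm", "gru", "gru_att"])
    def test_full_model_loss_gradient_spot_check(self, arch):
        """Finite-difference spot check through encoder + head + loss."""
        T = 16 if arch == "conv1d" else 6
        spec = _spec(arch=arch, T=T, D=2, M=3, h=4, embed_size=5)
        model = SequenceClassifier(spec)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, T, 2))
        y = np.eye(3)[[1, 2]]

        def loss_value(params):
            tensors = {k: ad.Tensor(v) for k, v in params.items()}
            out = model._forward(x, tensors)
            loss, _ = ad.softmax_cross_entropy(out["logits"], y)
            return float(loss.data)

        tensors = {k: ad.parameter(v) for k, v in model.params.items()}
        out = model._forward(x, tensors)
        loss, _ = ad.softmax_cross_entropy(out["logits"], y)
        loss.backward()
        eps = 1e-6
        rng2 = np.random.default_rng(2)
        for name, t in tensors.items():
            flat = model.params[name].ravel()
            grad = (t.grad if t.grad is not None else np.zeros_like(flat)).ravel()
            picks = rng2.choice(flat.size, size=min(4, flat.size), replace=False)
            for i in picks:
                pert = {k: v.copy() for k, v in model.params.items()}
                pert[name].ravel()[i] += eps
                up = loss_value(pert)
                pert[name].ravel()[i] -= 2 * eps
                down = loss_value(pert)
                num = (up - down) / (2 * eps)
                assert abs(num - grad[i]) <= 1e-4 * max(1.0, abs(num)), name


class TestEncodeAndClassify:
    def test_zero_input_zero_recurrent_params_give_zero_states(self):
        spec = _spec(arch="lstm", T=8, D=3, h=4)
        model = SequenceClassifier(spec)
        for k in list(model.params):
            if k.startswith(("W", "b")) and k not in ("Ws", "bs"):
                model.params[k] = np.zeros_like(model.params[k])
        res = wg.ClassifierResults(spec, model.params, [], ["a", "b", "c"])
        states = res.encode(np.zeros((8, 3)))
        np.testing.assert_allclose(states, 0.0, atol=1e-12)

    @pytest.mark.parametrize("arch", ["lstm", "gru", "lstm_att"])
    def test_state_sequence_length_equals_T(self, arch):
        spec = _spec(arch=arch)
        res = wg.ClassifierResults(
            spec, SequenceClassifier(spec).params, [], ["a", "b", "c"]
        )
        x = np.random.default_rng(0).normal(size=(spec.T, spec.D))
        assert res.encode(x).shape == (spec.T, spec.hidden_size)

    def test_identical_inputs_identical_outputs(self):
        spec = _spec(arch="gru_att")
        res = wg.ClassifierResults(
            spec, SequenceClassifier(spec).params, [], ["a", "b", "c"]
        )
        x = np.random.default_rng(5).normal(size=(spec.T, spec.D))
        p1, c1, a1 = res.classify(x)
        p2, c2, a2 = res.classify(x)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(a1, a2)
        assert c1 == c2

    def test_probabilities_normalized_and_nonnegative(self):
        spec = _spec(arch="conv1d")
        res = wg.ClassifierResults(
            spec, SequenceClassifier(spec).params, [], ["a", "b", "c"]
        )
        x = np.random.default_rng(2).normal(size=(4, spec.T, spec.D))
        probs, pred, alpha = res.classify(x)
        assert alpha is None
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()
        np.testing.assert_array_equal(pred, probs.argmax(axis=1))

    def test_zero_output_weights_give_uniform_and_tiebreak_zero(self):
        spec = _spec(arch="lstm")
        model = SequenceClassifier(spec)
        model.params["Ws"] = np.zeros_like(model.params["Ws"])
        model.params["bs"] = np.zeros_like(model.params["bs"])
        res = wg.ClassifierResults(spec, model.params, [], ["a", "b", "c"])
        probs, pred, _ = res.classify(
            np.random.default_rng(1).normal(size=(spec.T, spec.D))
        )
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-6)
        assert pred == 0

    def test_alpha_only_for_attention_archs(self):
        for arch, has in (("lstm", False), ("lstm_att", True)):
            spec = _spec(arch=arch)
            res = wg.ClassifierResults(
                spec, SequenceClassifier(spec).params, [], ["a", "b", "c"]
            )
            x = np.random.default_rng(0).normal(size=(spec.T, spec.D))
            _, _, alpha = res.classify(x)
            assert (alpha is not None) == has
            if has:
                assert abs(alpha.sum() - 1.0) < 1e-6

    def test_embedding_width_and_determinism(self):
        spec = _spec(arch="conv1d", embed_size=64)
        res = wg.ClassifierResults(
            spec, SequenceClassifier(spec).params, [], ["a", "b", "c"]
        )
        x = np.random.default_rng(0).normal(size=(spec.T, spec.D))
        e1, e2 = res.embed(x), res.embed(x)
        assert e1.shape == (64,)
        np.testing.assert_array_equal(e1, e2)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        y = np.eye(4)[[0, 1, 2]]
        assert wg.cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_M(self):
        M = 18
        y = np.eye(M)[[3]]
        p = np.full((1, M), 1.0 / M)
        assert wg.cross_entropy_loss(y, p) == pytest.approx(np.log(18), rel=1e-9)

    def test_matches_scalar_loop_on_random_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m, M = rng.integers(1, 10), rng.integers(2, 8)
            y = np.eye(M)[rng.integers(0, M, size=m)]
            p = rng.dirichlet(np.ones(M), size=m)
            loop = 0.0
            for i in range(m):
                for c in range(M):
                    if y[i, c]:
                        loop -= np.log(max(p[i, c], 1e-12))
            loop /= m
            assert wg.cross_entropy_loss(y, p) == pytest.approx(loop, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wg.cross_entropy_loss(np.eye(3), np.ones((2, 3)) / 3)


class TestAdam:
    def test_first_step_matches_hand_computed_update(self):
        cfg = TrainConfig(learning_rate=0.05)
        t = ad.parameter(np.array([3.0]))
        opt = _Adam({"w": t}, cfg)
        # quadratic f(w) = 0.5 w^2 -> grad = w
        t.grad = t.data.copy()
        g = 3.0
        opt.step()
        mhat, vhat = g, g * g  # bias-corrected first moments
        expected = 3.0 - 0.05 * mhat / (np.sqrt(vhat) + 1e-8)
        assert t.data[0] == pytest.approx(expected, abs=1e-10)


class TestTraining:
    def test_single_batch_overfit(self):
        spec = _spec(arch="lstm_att", T=12, D=3, M=3, h=12, embed_size=16)
        data = _random_set(spec, n=8, seed=4)
        res = SequenceClassifier(spec).fit(
            data, None,
            TrainConfig(max_epochs=220, batch_size=8, learning_rate=5e-3,
                        seed=0),
        )
        assert res.history[-1]["train_loss"] < 0.01

    def test_training_is_deterministic_under_seed(self):
        spec = _spec(arch="gru", T=10, D=3, M=3, h=6)
        data = _random_set(spec, n=18, seed=1)
        cfg = TrainConfig(max_epochs=3, batch_size=6, seed=7)
        a = SequenceClassifier(_spec(arch="gru", T=10, D=3, M=3, h=6)).fit(
            data, data, cfg)
        b = SequenceClassifier(_spec(arch="gru", T=10, D=3, M=3, h=6)).fit(
            data, data, cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        assert a.history == b.history

    def test_shape_mismatch_rejected(self):
        spec = _spec(arch="conv1d", T=10, D=3)
        data = _random_set(_spec(arch="conv1d", T=12, D=3), n=6)
        with pytest.raises(ValueError):
            SequenceClassifier(spec).fit(data, None, TrainConfig(max_epochs=1))


class TestCheckpoint:
    def test_save_load_identical_predictions(self, tmp_path):
        spec = _spec(arch="lstm_att", T=10, D=3, M=3, h=6)
        data = _random_set(spec, n=12, seed=2)
        res = SequenceClassifier(spec).fit(
            data, None, TrainConfig(max_epochs=2, batch_size=6, seed=0)
        )
        path = tmp_path / "ckpt.npz"
        res.save(path)
        back = wg.ClassifierResults.load(path)
        x = data.tensor()
        np.testing.assert_array_equal(res.predict(data), back.predict(data))
        np.testing.assert_array_equal(
            res.attention_weights(x[0]), back.attention_weights(x[0])
        )
        assert back.class_vocabulary == res.class_vocabulary

    def test_summary_mentions_architecture(self):
        spec = _spec(arch="gru_att")
        res = wg.ClassifierResults(
            spec, SequenceClassifier(spec).params, [], ["a", "b", "c"]
        )
        assert "gru_att" in res.summary()
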