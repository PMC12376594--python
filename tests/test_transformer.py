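"""Cross-scale transformer tests: the vectorised attention against a
brute-force double-loop oracle, architectural contracts, permutation
invariance, gradient flow, and learning on planted-signal data."""

import numpy as np
import pytest

from pathofuse import nn
from pathofuse.nn import Tensor
from pathofuse import simulate as sim
from pathofuse.patches import SamplerConfig, cluster_sample
from pathofuse.transformer import (CrossScaleTransformer,
                                   CrossScaleTransformerClassifier,
                                   ModelConfig, TrainConfig, aggregate_patient,
                                   attention, sigmoid)

RNG = np.random.default_rng(0)


def brute_force_attention(q_src, kv_src, w_q, w_k, w_v, w_out):
    """Independent oracle: explicit per-head, per-query double loop."""
    h, d, d_k = w_q.shape
    n_q, n_k = q_src.shape[0], kv_src.shape[0]
    heads = np.zeros((n_q, h, d_k))
    for head in range(h):
        Q = q_src @ w_q[head]
        K = kv_src @ w_k[head]
        V = kv_src @ w_v[head]
        for i in range(n_q):
            logits = np.array([Q[i] @ K[j] / np.sqrt(d_k)
                               for j in range(n_k)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            heads[i, head] = sum(w[j] * V[j] for j in range(n_k))
    return heads.reshape(n_q, h * d_k) @ w_out


def random_attention_params(d=8, d_k=4, h=3, rng=RNG):
    return (rng.standard_normal((h, d, d_k)),
            rng.standard_normal((h, d, d_k)),
            rng.standard_normal((h, d, d_k)),
            rng.standard_normal((h * d_k, d)))


class TestAttention:
    @pytest.mark.parametrize("n_q,n_k", [(1, 1), (3, 5), (8, 8), (5, 2)])
    def test_matches_brute_force_oracle(self, n_q, n_k):
        rng = np.random.default_rng(100 + n_q * 10 + n_k)
        wq, wk, wv, wo = random_attention_params(rng=rng)
        q_src = rng.standard_normal((n_q, 8))
        kv_src = rng.standard_normal((n_k, 8))
        out = attention(Tensor(q_src), Tensor(kv_src), Tensor(wq), Tensor(wk),
                        Tensor(wv), Tensor(wo)).data
        oracle = brute_force_attention(q_src, kv_src, wq, wk, wv, wo)
        assert np.abs(out - oracle).max() < 1e-6

    def test_many_random_cases_against_oracle(self):
        worst = 0.0
        for case in range(100):
            rng = np.random.default_rng(case)
            wq, wk, wv, wo = random_attention_params(rng=rng)
            n_q, n_k = rng.integers(1, 9, size=2)
            q_src = rng.standard_normal((n_q, 8))
            kv_src = rng.standard_normal((n_k, 8))
            out = attention(Tensor(q_src), Tensor(kv_src), Tensor(wq),
                            Tensor(wk), Tensor(wv), Tensor(wo)).data
            oracle = brute_force_attention(q_src, kv_src, wq, wk, wv, wo)
            worst = max(worst, np.abs(out - oracle).max())
        assert worst <= 1e-6

    def test_softmax_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        q = Tensor(rng.standard_normal((4, 8)))
        wq, wk, _, _ = random_attention_params(rng=rng)
        Q = q.reshape(1, 4, 8) @ Tensor(wq)
        K = q.reshape(1, 4, 8) @ Tensor(wk)
        weights = ((Q @ K.swapaxes(-1, -2)) * 0.5).softmax(-1).data
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_key_returns_its_value_vector(self):
        """With one key/value token the softmax weight is 1, so each
        pre-projection head output equals that token's value vector."""
        rng = np.random.default_rng(5)
        wq, wk, wv, _ = random_attention_params(rng=rng)
        identity_out = np.eye(3 * 4 * 1)[:12, :8]   # project heads untouched
        q_src = rng.standard_normal((6, 8))
        kv_src = rng.standard_normal((1, 8))
        out = attention(Tensor(q_src), Tensor(kv_src), Tensor(wq), Tensor(wk),
                        Tensor(wv), Tensor(np.eye(12)[:, :8])).data
        head_vals = (kv_src @ wv).reshape(1, -1)    # (1, h*d_k)
        expected = np.tile(head_vals, (6, 1)) @ np.eye(12)[:, :8]
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_empty_kv_rejected(self):
        wq, wk, wv, wo = random_attention_params()
        with pytest.raises(ValueError):
            attention(Tensor(np.zeros((2, 8))), Tensor(np.zeros((0, 8))),
                      Tensor(wq), Tensor(wk), Tensor(wv), Tensor(wo))


class TestModel:
    def test_embed_tokens_nonnegative_and_right_width(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        z = RNG.standard_normal((12, 16))
        out = model.embed_tokens(z, "low")
        assert out.shape == (12, 32)
        assert (out.data >= 0).all()

    def test_single_token_inference_finite(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        model.eval()
        out = model.embed_tokens(RNG.standard_normal((1, 16)), "high")
        assert np.isfinite(out.data).all()

    def test_block_preserves_shapes(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        x_l = Tensor(RNG.standard_normal((13, 32)))
        x_h = Tensor(RNG.standard_normal((13, 32)))
        for block in model.blocks:
            y_l, y_h = block(x_l, x_h)
            assert y_l.shape == x_l.shape and y_h.shape == x_h.shape

    def test_uniform_weight_hook_averages_other_branch(self, tiny_model_config):
        """Forcing uniform attention makes every cross-attended token equal
        the mean of the other branch's (projected) value vectors."""
        model = CrossScaleTransformer(tiny_model_config)
        cross = model.blocks[1]
        assert cross.cross
        x_l = Tensor(RNG.standard_normal((5, 32)))
        x_h = Tensor(RNG.standard_normal((7, 32)))
        q_l = cross.norm1_l(x_l)
        q_h = cross.norm1_h(x_h)
        out = cross.attn_l(q_l, q_h, force_uniform=True).data
        # hand-computed: mean value vector per head, concatenated, projected
        a = cross.attn_l
        v = (q_h.data[None] @ a.w_v.data)            # (h, n_h, d_k)
        mean_v = v.mean(axis=1)                      # (h, d_k)
        expected_row = mean_v.reshape(-1) @ a.w_out.data
        for i in range(5):
            np.testing.assert_allclose(out[i], expected_row, atol=1e-10)

    def test_forward_feature_is_2d_and_deterministic(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        model.eval()
        z_l = RNG.standard_normal((12, 16))
        z_h = RNG.standard_normal((12, 16))
        with nn.no_grad():
            logit1, feat1 = model(z_l, z_h)
            logit2, feat2 = model(z_l, z_h)
        assert feat1.shape == (64,)                  # 2 * d
        assert float(logit1.data) == float(logit2.data)

    def test_token_count_mismatch_rejected(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        with pytest.raises(ValueError):
            model(RNG.standard_normal((11, 16)), RNG.standard_normal((12, 16)))

    def test_permutation_invariance_of_logit(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        model.eval()
        z_l = RNG.standard_normal((12, 16))
        z_h = RNG.standard_normal((12, 16))
        with nn.no_grad():
            base = float(model(z_l, z_h)[0].data)
            perm = float(model(z_l[RNG.permutation(12)],
                               z_h[RNG.permutation(12)])[0].data)
        assert abs(base - perm) <= 1e-5

    def test_every_parameter_receives_gradient(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        logit, _ = model(RNG.standard_normal((12, 16)),
                         RNG.standard_normal((12, 16)))
        loss = nn.bce_with_logits(logit.reshape(1), np.array([1.0]))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.abs(p.grad).max() > 0, f"{name} gradient all-zero"

    def test_zeroed_head_probability_half(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        model.eval()
        with nn.no_grad():
            logit, _ = model(RNG.standard_normal((12, 16)),
                             RNG.standard_normal((12, 16)))
        assert sigmoid(float(logit.data)) == 0.5


class TestAggregation:
    def test_examples(self):
        assert aggregate_patient([0.2, 0.8]) == pytest.approx(0.5)
        assert aggregate_patient([0.7]) == pytest.approx(0.7)
        vals = np.random.default_rng(1).random(5)
        assert aggregate_patient(vals) == pytest.approx(vals.sum() / 5,
                                                        abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])


from conftest import sampled_token_cohort


class TestTraining:
    def test_learns_planted_signal_and_beats_permuted_control(
            self, planted_signal_experiment):
        exp = planted_signal_experiment
        clf = exp["clf"]
        assert len(clf.fold_aucs_) == 4
        assert exp["test_auc"] >= exp["perm_auc"] + 0.25
        # first epoch's training loss is finite and positive
        assert clf.history_[0][0]["loss"] > 0
        assert np.isfinite(clf.history_[0][0]["loss"])

    def test_single_class_and_leaky_folds_rejected(self, tiny_model_config,
                                                   tiny_train_config):
        X, y, groups = sampled_token_cohort(signal=0.0, n_patients=8, seed=2)
        clf = CrossScaleTransformerClassifier(tiny_model_config,
                                              tiny_train_config)
        with pytest.raises(ValueError):
            clf.fit(X, np.zeros(len(X)), groups=groups)
        bad_folds = [(np.arange(len(X)), np.arange(len(X)))]
        with pytest.raises(ValueError, match="both train and validation"):
            clf.fit(X, y, groups=groups, folds=bad_folds)

    def test_predict_slide_draw_averaging(self, tiny_model_config):
        """n_draws=1 equals one direct forward on the sampled tokens; the
        Monte-Carlo spread of the estimate shrinks with more draws."""
        spec = sim.SyntheticCohortSpec(
            n_patients=2, slides_per_patient=(1.0,), embed_dim=16,
            patch_counts={224: 40, 512: 40}, signal_strength=1.0, seed=5)
        cohort = sim.gen_embedding_cohort(spec)
        slide = cohort.slides[0]
        clf = CrossScaleTransformerClassifier(tiny_model_config)
        clf.model_ = CrossScaleTransformer(tiny_model_config)
        clf.classes_ = np.array([0, 1])
        p1 = clf.predict_slide(slide.bags[224], slide.bags[512], n_draws=1,
                               seed=3)
        tok_l, _ = cluster_sample(slide.bags[224], SamplerConfig(3, 4, seed=3))
        tok_h, _ = cluster_sample(slide.bags[512], SamplerConfig(3, 4, seed=3))
        with nn.no_grad():
            direct = sigmoid(float(clf.model_(tok_l, tok_h)[0].data))
        assert p1 == pytest.approx(direct, abs=1e-12)
        est_10 = [clf.predict_slide(slide.bags[224], slide.bags[512],
                                    n_draws=10, seed=1000 * (k + 1))
                  for k in range(8)]
        est_100 = [clf.predict_slide(slide.bags[224], slide.bags[512],
                                     n_draws=100, seed=100000 + 1000 * k)
                   for k in range(8)]
        assert np.var(est_100) <= np.var(est_10)
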