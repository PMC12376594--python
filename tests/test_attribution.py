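"""Integrated-gradients tests: exactness on linear maps, the completeness
axiom, per-patch aggregation arithmetic, repeated-sampling maps, and
planted-signal recovery of informative patches."""

import numpy as np
import pandas as pd
import pytest

from pathofuse import nn
from pathofuse.attribution import (integrated_gradients,
                                   integrated_gradients_model,
                                   patch_importance, select_representative,
                                   slide_attribution_map)
from pathofuse.patches import PatchBag, PatchRef, SamplerConfig
from pathofuse.transformer import CrossScaleTransformer

RNG = np.random.default_rng(7)


class TestIntegratedGradients:
    def test_linear_map_is_exact_for_any_step_count(self):
        w = RNG.standard_normal((6, 4))
        x = RNG.standard_normal((6, 4))
        f = lambda t: (t * nn.Tensor(w)).sum()
        for steps in (2, 5, 64):
            attr, = integrated_gradients(f, [x], n_steps=steps)
            np.testing.assert_allclose(attr, w * x, atol=1e-12)

    def test_zero_difference_gives_zero_attribution(self):
        x = RNG.standard_normal((3, 5))
        f = lambda t: (t * t).sum()
        attr, = integrated_gradients(f, [x], baselines=[x.copy()])
        np.testing.assert_array_equal(attr, np.zeros_like(x))

    def test_completeness_on_trained_model(self, planted_signal_experiment):
        """On the trained tiny transformer, attributions of the most
        confidently attributed held-out slide sum to F(X) - F(0) within 1%
        at 128 steps, and refining the partition does not hurt."""
        exp = planted_signal_experiment
        model = exp["clf"].model_
        model.eval()
        X = exp["X"][exp["n_train"]:]
        diffs = []
        for z_l, z_h in X:
            with nn.no_grad():
                f_x = float(model(z_l, z_h)[0].data)
                f_0 = float(model(np.zeros_like(z_l),
                                  np.zeros_like(z_h))[0].data)
            diffs.append(f_x - f_0)
        best = int(np.argmax(np.abs(diffs)))
        z_l, z_h = X[best]
        gaps = []
        for steps in (32, 64, 128):
            a_l, a_h = integrated_gradients_model(model, z_l, z_h,
                                                  n_steps=steps)
            total = a_l.sum() + a_h.sum()
            gaps.append(abs(total - diffs[best]) / abs(diffs[best]))
        assert gaps[-1] <= 0.01
        assert gaps[1] <= gaps[0] + 2e-3    # refinement does not hurt
        assert gaps[2] <= gaps[0] + 2e-3

    def test_shape_mismatch_and_bad_steps_rejected(self):
        f = lambda t: t.sum()
        with pytest.raises(ValueError):
            integrated_gradients(f, [np.zeros((2, 2))],
                                 baselines=[np.zeros((3, 2))])
        with pytest.raises(ValueError):
            integrated_gradients(f, [np.zeros((2, 2))], n_steps=1)


class TestPatchImportance:
    def test_constant_token_gives_its_value(self):
        idx, vals = patch_importance(np.full((1, 4), 2.0), np.array([5]))
        assert idx.tolist() == [5] and vals[0] == pytest.approx(2.0)

    def test_duplicate_tokens_average(self):
        raw = np.vstack([np.full(4, 1.0), np.full(4, 3.0)])
        idx, vals = patch_importance(raw, np.array([2, 2]))
        assert idx.tolist() == [2] and vals[0] == pytest.approx(2.0)

    def test_three_token_hand_computation(self):
        raw = np.array([[1.0, 3.0], [2.0, 2.0], [10.0, 0.0]])
        idx, vals = patch_importance(raw, np.array([0, 1, 0]))
        # patch 0: mean(mean(1,3), mean(10,0)) = mean(2, 5) = 3.5
        np.testing.assert_allclose(vals, [3.5, 2.0])

    def test_misaligned_provenance_rejected(self):
        with pytest.raises(ValueError):
            patch_importance(np.zeros((3, 2)), np.array([0, 1]))


def toy_bags(n=30, d=16, seed=0, signal_idx=()):
    rng = np.random.default_rng(seed)
    bags = {}
    for scale in (224, 512):
        E = rng.standard_normal((n, d))
        for i in signal_idx:
            E[i] += 3.0
        refs = [PatchRef("s0", scale, i * scale, 0) for i in range(n)]
        bags[scale] = PatchBag("s0", scale, E, refs)
    return bags


class TestSlideMap:
    def test_single_draw_equals_direct_pass(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        model.eval()
        bags = toy_bags()
        cfg = SamplerConfig(3, 4, seed=0)
        res = slide_attribution_map(model, bags, cfg, cfg, n_draws=1,
                                    n_steps=16, seed=9)
        from pathofuse.patches import cluster_sample
        tok_l, prov_l = cluster_sample(bags[224], SamplerConfig(3, 4, seed=9))
        tok_h, prov_h = cluster_sample(bags[512],
                                       SamplerConfig(3, 4, seed=10))
        a_l, a_h = integrated_gradients_model(model, tok_l, tok_h, n_steps=16)
        idx, vals = patch_importance(a_l, prov_l)
        np.testing.assert_allclose(res.values[224][idx], vals, atol=1e-12)
        assert (res.coverage[224][idx] == 1).all()

    def test_same_seed_identical_maps(self, tiny_model_config):
        model = CrossScaleTransformer(tiny_model_config)
        bags = toy_bags(seed=3)
        cfg = SamplerConfig(3, 4, seed=0)
        r1 = slide_attribution_map(model, bags, cfg, cfg, n_draws=5,
                                   n_steps=8, seed=4)
        r2 = slide_attribution_map(model, bags, cfg, cfg, n_draws=5,
                                   n_steps=8, seed=4)
        for s in (224, 512):
            np.testing.assert_array_equal(r1.values[s], r2.values[s])

    def test_many_draw_mean_converges(self, tiny_model_config):
        """Per-patch mean over many draws approaches the mean over even
        more draws (Monte-Carlo convergence on a toy slide)."""
        model = CrossScaleTransformer(tiny_model_config)
        bags = toy_bags(n=12, seed=5)    # 12 patches -> every draw covers all
        cfg = SamplerConfig(3, 4, seed=0)
        r_small = slide_attribution_map(model, bags, cfg, cfg, n_draws=60,
                                        n_steps=8, seed=1)
        r_big = slide_attribution_map(model, bags, cfg, cfg, n_draws=240,
                                      n_steps=8, seed=2)
        v1, v2 = r_small.values[224], r_big.values[224]
        # standard error from the bigger run's spread across patches
        spread = np.nanstd(v1 - v2)
        assert np.nanmax(np.abs(v1 - v2)) < max(4 * spread, 0.05)


class TestSelectRepresentative:
    @staticmethod
    def tables():
        slide_table = pd.DataFrame({
            "slide_id": ["a", "b", "c"],
            "label": [1, 1, 0],
            "score": [0.9, 0.6, 0.2],
        })
        patch_table = pd.DataFrame({
            "slide_id": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "scale": [224] * 9,
            "row0": [0, 224, 448] * 3,
            "col0": [0, 0, 0] * 3,
            "value": [0.5, 0.5, 0.1, 0.3, 0.2, 0.9, -0.5, -0.1, -0.5],
        })
        return slide_table, patch_table

    def test_clamp_when_fewer_slides_than_requested(self):
        slide_table, patch_table = self.tables()
        out = select_representative(slide_table, patch_table, n_slides=200,
                                    n_patches=2)
        assert set(out["slide_id"]) == {"a", "b", "c"}

    def test_tie_breaks_on_coordinates(self):
        slide_table, patch_table = self.tables()
        out = select_representative(slide_table, patch_table, n_slides=1,
                                    n_patches=1)
        top_a = out[(out["slide_id"] == "a")]
        assert top_a["row0"].iloc[0] == 0        # tied 0.5s: lower row0 wins
        low_c = out[(out["slide_id"] == "c")]
        assert low_c["row0"].iloc[0] == 0        # tied -0.5s

    def test_selected_carrier_patches_enriched_for_planted_signal(self):
        """On a cohort where 30% of carrier patches carry the planted
        signal, the top-gradient shortlist of high-scoring carrier slides
        is clearly enriched for signal-bearing patches over that base
        rate (per-patch attribution at this desk scale is noisy, so the
        check is enrichment, not near-perfect recovery)."""
        from pathofuse import simulate as sim
        from pathofuse.patches import cluster_sample
        from pathofuse.transformer import (CrossScaleTransformerClassifier,
                                           ModelConfig, TrainConfig)

        frac = 0.3
        spec = sim.SyntheticCohortSpec(
            n_patients=80, slides_per_patient=(1.0,), embed_dim=16,
            patch_counts={224: 24, 512: 24}, signal_strength=2.0,
            signal_fraction=frac, seed=1)
        cohort = sim.gen_embedding_cohort(spec)
        pairs = []
        for s in cohort.slides:
            tl, _ = cluster_sample(s.bags[224], SamplerConfig(3, 4, seed=1))
            th, _ = cluster_sample(s.bags[512], SamplerConfig(3, 4, seed=2))
            pairs.append((tl, th))
        y = cohort.slide_labels
        mcfg = ModelConfig(d=32, d_k=8, n_heads=2, n_blocks=2, c_l=3, s_l=4,
                           c_h=3, s_h=4, d_in_low=16, d_in_high=16, seed=0)
        tcfg = TrainConfig(lr=1e-3, weight_decay=1e-3, batch_size=32,
                           max_epochs=30, patience=10, warmup_epochs=3,
                           cosine_t_max=27, n_folds=2, seed=0)
        clf = CrossScaleTransformerClassifier(mcfg, tcfg)
        clf.fit(pairs, y, groups=[s.patient_id for s in cohort.slides])
        cfg = SamplerConfig(3, 4, seed=0)
        slide_rows, patch_rows, flags = [], [], {}
        for s in cohort.slides:
            if s.label != 1:
                continue
            res = slide_attribution_map(clf.model_, s.bags, cfg, cfg,
                                        n_draws=25, n_steps=32, seed=11)
            prob = clf.predict_slide(s.bags[224], s.bags[512], n_draws=5,
                                     seed=3)
            slide_rows.append({"slide_id": s.slide_id, "label": s.label,
                               "score": prob})
            patch_rows.append(res.to_frame(s.bags))
            for scale in (224, 512):
                for ref, fl in zip(s.bags[scale].patch_refs,
                                   s.signal_flags[scale]):
                    flags[(s.slide_id, scale, ref.row0, ref.col0)] = fl
        shortlist = select_representative(
            pd.DataFrame(slide_rows),
            pd.concat(patch_rows, ignore_index=True),
            n_slides=10, n_patches=5)
        carriers = shortlist[shortlist["slide_label"] == 1]
        assert len(carriers) > 0
        hit = np.mean([flags[(r.slide_id, r.scale, r.row0, r.col0)]
                       for r in carriers.itertuples()])
        assert hit >= 1.3 * frac
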