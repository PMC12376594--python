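"""Fusion tests: phenotype standardisation, the KL closed form against a
Monte-Carlo oracle, the ELBO decomposition, latent recovery on
linear-Gaussian two-view data, the fused classifier, and permutation
Shapley values against the linear closed form."""

import numpy as np
import pandas as pd
import pytest

from pathofuse import fusion as F
from pathofuse import simulate as sim
from pathofuse.errors import SchemaError


def canonical_correlations(A, B):
    """Top canonical correlation between column spaces of A and B."""
    def whiten(X):
        X = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        keep = S > 1e-10 * S[0]
        return U[:, keep]
    Ua, Ub = whiten(A), whiten(B)
    s = np.linalg.svd(Ua.T @ Ub, compute_uv=False)
    return s[0]


class TestStandardizer:
    @staticmethod
    def table():
        spec = sim.SyntheticCohortSpec(n_patients=200, missing_rate=0.0,
                                       seed=0)
        df, _ = sim.gen_phenotypes(spec)
        return df

    def test_fit_set_continuous_has_mean0_sd1(self):
        df = self.table()
        std = F.PhenotypeStandardizer().fit(df)
        out = std.transform(df)
        col = std.feature_names_.index("age_at_diagnosis")
        assert abs(out[:, col].mean()) < 1e-9
        assert abs(out[:, col].std() - 1.0) < 1e-9

    def test_unseen_category_goes_to_unknown_bucket(self):
        df = self.table()
        std = F.PhenotypeStandardizer().fit(df)
        new = df.head(2).copy()
        new.loc[new.index[0], "grade"] = "IV"
        out = std.transform(new)
        col = std.feature_names_.index("grade=__unknown__")
        assert out[0, col] == 1.0 and out[1, col] == 0.0

    def test_missing_goes_to_indicator(self):
        df = self.table()
        std = F.PhenotypeStandardizer().fit(df)
        new = df.head(1).copy()
        new.loc[new.index[0], "er_positive"] = np.nan
        out = std.transform(new)
        col = std.feature_names_.index("er_positive=__missing__")
        assert out[0, col] == 1.0

    def test_width_equals_sum_of_field_widths_and_is_constant(self):
        df = self.table()
        std = F.PhenotypeStandardizer().fit(df)
        expected = 0
        for c in df.columns:
            if std.kinds_[c] == "continuous":
                expected += 1
            else:
                expected += len(std.levels_[c]) + 2
        assert std.width_ == expected
        assert std.transform(df.head(3)).shape == (3, expected)
        assert std.transform(df.tail(50)).shape == (50, expected)

    def test_transform_before_fit_is_state_error(self):
        with pytest.raises(Exception):
            F.PhenotypeStandardizer().transform(self.table())


class TestKL:
    def test_standard_normal_is_zero(self):
        assert F.kl_standard_normal(np.zeros(7), np.ones(7)) == 0.0

    def test_unit_mean_is_half(self):
        assert F.kl_standard_normal(np.array([1.0]), np.array([1.0])) == 0.5

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dim = rng.integers(1, 6)
            mu = rng.normal(0, 1.5, dim)
            sigma = rng.uniform(0.3, 2.5, dim)
            closed = F.kl_standard_normal(mu, sigma)
            z = mu + sigma * rng.standard_normal((100_000, dim))
            log_q = (-0.5 * ((z - mu) / sigma) ** 2
                     - np.log(sigma) - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            diffs = log_q - log_p
            mc, se = diffs.mean(), diffs.std() / np.sqrt(len(diffs))
            assert abs(closed - mc) <= 2 * se + 1e-3

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            F.kl_standard_normal(np.zeros(2), np.array([1.0, 0.0]))


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        mu = np.arange(5.0)
        np.testing.assert_array_equal(
            F.reparameterize(mu, np.ones(5), np.zeros(5)), mu)

    def test_sample_variance_matches_sigma(self):
        rng = np.random.default_rng(1)
        sigma = np.array([0.5, 2.0])
        z = F.reparameterize(np.zeros(2), sigma,
                             rng.standard_normal((10_000, 2)))
        np.testing.assert_allclose(z.var(axis=0), sigma**2, rtol=0.05)

    def test_gradient_wrt_mu_is_identity(self):
        from pathofuse.nn import Tensor
        mu = Tensor(np.array([1.0, 2.0]), requires_grad=True)
        z = F.reparameterize(mu, Tensor(np.array([3.0, 4.0])),
                             Tensor(np.array([0.7, -0.2])))
        z.sum().backward()
        np.testing.assert_array_equal(mu.grad, np.ones(2))


class TestMcVae:
    def test_elbo_has_four_reconstruction_terms_and_decomposes(
            self, two_view_vae):
        vae, X1, X2, _ = two_view_vae
        comp = vae.elbo_components(X1[:32], X2[:32])
        rec_keys = [k for k in comp if k.startswith("rec_")]
        assert len(rec_keys) == 4
        reassembled = (vae.beta * (comp["kl_patho"] + comp["kl_pheno"])
                       - sum(comp[k] for k in rec_keys))
        assert abs(reassembled - comp["loss"]) < 1e-9

    def test_beta_zero_loss_is_negative_reconstruction(self, two_view_vae):
        vae, X1, X2, _ = two_view_vae
        beta = vae.beta
        try:
            vae.beta = 0.0
            comp = vae.elbo_components(X1[:16], X2[:16])
            assert comp["loss"] == pytest.approx(-comp["l_rec"], abs=1e-12)
        finally:
            vae.beta = beta

    def test_training_reduces_loss(self, two_view_vae):
        vae, *_ = two_view_vae
        losses = [h["loss"] for h in vae.history_]
        assert losses[min(49, len(losses) - 1)] <= losses[0]

    def test_latent_recovery_top_canonical_correlation(self, two_view_vae):
        vae, X1, X2, Z = two_view_vae
        fused = vae.transform((X1, X2))
        assert fused.shape == (500, 16)
        assert canonical_correlations(fused, Z) >= 0.8

    def test_cross_reconstruction_recovers_other_view(self, two_view_vae):
        """Decoding the phenotype-channel latent through the patho decoder
        correlates with the held-out view (cross-modal reasoning)."""
        from pathofuse import nn as nnmod
        vae, X1, X2, _ = two_view_vae
        mu_f, _ = vae.posterior("pheno", X2)
        with nnmod.no_grad():
            recon = vae.channel_patho_.decode(nnmod.Tensor(mu_f)).data
        rs = [np.corrcoef(recon[:, j], X1[:, j])[0, 1]
              for j in range(X1.shape[1])]
        assert np.mean(rs) >= 0.7

    def test_seeded_run_reproducible(self):
        X1, X2, _ = sim.gen_two_view_linear(60, latent_dim=2, dims=(6, 5),
                                            noise_sd=0.1, seed=3)
        kw = dict(latent_dim=4, hidden_patho=16, hidden_pheno=16,
                  max_epochs=30, patience=40, warmup_epochs=5,
                  cosine_t_max=25, seed=11)
        v1 = F.MultiChannelVAE(**kw).fit((X1, X2))
        v2 = F.MultiChannelVAE(**kw).fit((X1, X2))
        assert abs(v1.final_loss_ - v2.final_loss_) < 1e-6

    def test_transform_deterministic_and_cross_inference(self, two_view_vae):
        vae, X1, X2, _ = two_view_vae
        f1 = vae.transform((X1[:5], X2[:5]))
        f2 = vae.transform((X1[:5], X2[:5]))
        np.testing.assert_array_equal(f1, f2)
        imputed = vae.transform((None, X2[:5]))
        assert vae.last_transform_imputed_ == "patho"
        mu_f, _ = vae.posterior("pheno", X2[:5])
        np.testing.assert_array_equal(imputed[:, :8], mu_f)
        np.testing.assert_array_equal(imputed[:, 8:], mu_f)

    def test_unpaired_batch_rejected(self):
        with pytest.raises(ValueError):
            F.MultiChannelVAE().fit((np.zeros((4, 3)), np.zeros((5, 3))))


class TestFusionHead:
    def test_zeroed_head_gives_half_probability(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 6))
        y = rng.integers(0, 2, 50)
        clf = F.FusionHeadClassifier(hidden=4, max_epochs=2, seed=0).fit(X, y)
        for p in clf.model_.parameters():
            p.data[:] = 0.0
        np.testing.assert_allclose(clf.predict_proba(X)[:, 1], 0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            F.FusionHeadClassifier().fit(np.zeros((10, 3)), np.zeros(10))

    def test_permuted_labels_stay_near_chance(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 8))
        y = rng.integers(0, 2, 300)
        clf = F.FusionHeadClassifier(max_epochs=40, seed=0).fit(X, y)
        auc = roc_auc_score(y, clf.decision_function(X))
        assert 0.35 <= auc <= 0.75        # in-sample, small capacity

    def test_learns_separable_signal(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400)
        X = rng.standard_normal((400, 8)) + 1.5 * y[:, None]
        clf = F.FusionHeadClassifier(max_epochs=60, seed=0).fit(X[:300],
                                                                y[:300])
        assert roc_auc_score(y[300:],
                             clf.decision_function(X[300:])) >= 0.9


class TestShapley:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(6)
        f = lambda X: X @ w
        x = rng.standard_normal(6)
        bg = rng.standard_normal((40, 6))
        phi = F.shapley_contributions(f, x, bg, n_permutations=2000, seed=1)
        exact = w * (x - bg.mean(axis=0))
        assert np.abs(phi - exact).max() <= 0.05 * max(np.abs(exact).max(),
                                                       1.0)

    def test_efficiency_exact_for_single_background_row(self):
        """With one background row, every permutation telescopes, so
        Sum(phi) equals f(x) - f(background) exactly."""
        rng = np.random.default_rng(1)
        w = rng.standard_normal(5)
        f = lambda X: np.tanh(X @ w)
        x = rng.standard_normal(5)
        bg = rng.standard_normal((1, 5))
        phi = F.shapley_contributions(f, x, bg, n_permutations=50, seed=3)
        target = f(x[None])[0] - f(bg)[0]
        assert abs(phi.sum() - target) < 1e-12

    def test_efficiency_within_sampling_error_for_background_set(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal(5)
        f = lambda X: np.tanh(X @ w)
        x = rng.standard_normal(5)
        bg = rng.standard_normal((30, 5))
        fb = f(bg)
        reps = [F.shapley_contributions(f, x, bg, n_permutations=500,
                                        seed=s).sum() for s in range(8)]
        target = f(x[None])[0] - fb.mean()
        se = fb.std() / np.sqrt(500 * len(reps))
        assert abs(np.mean(reps) - target) <= 3 * se

    def test_constant_feature_gets_zero(self):
        w = np.array([1.0, 2.0, 3.0])
        f = lambda X: X @ w
        x = np.array([0.5, 1.0, 2.0])
        bg = np.tile(np.array([0.5, 0.0, 0.0]), (10, 1))
        phi = F.shapley_contributions(f, x, bg, n_permutations=200, seed=0)
        assert phi[0] == 0.0

    def test_bad_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            F.shapley_contributions(lambda X: X.sum(1), np.zeros(3),
                                    np.zeros((2, 3)), n_permutations=0)


class TestMultimodalGain:
    def test_fused_beats_weaker_modality(self):
        """On one complementary-signal cohort the fused classifier tracks
        the best single modality and clearly beats the weaker one (the
        multi-seed average is exercised in the acceptance suite)."""
        from pathofuse.evaluation import auc_with_ci
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        res = F.fused_vs_single_modality_benchmark(seed=0)
        assert res["fused"] >= min(res["patho"], res["pheno"]) + 0.05
        assert res["fused"] >= max(res["patho"], res["pheno"]) - 0.02
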