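import numpy as np
import pytest

from pathofuse import nn
from pathofuse.transformer import ModelConfig, TrainConfig


def numeric_gradient(f, arrays, wrt: int, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f(*arrays) w.r.t. arrays[wrt]."""
    arrays = [np.array(a, dtype=np.float64) for a in arrays]
    target = arrays[wrt]
    grad = np.zeros_like(target)
    it = np.nditer(target, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = target[idx]
        target[idx] = orig + eps
        fp = f(*arrays)
        target[idx] = orig - eps
        fm = f(*arrays)
        target[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    """A desk-scale transformer: 12 tokens per branch, 32-d, 2 blocks."""
    return ModelConfig(d=32, d_k=8, n_heads=2, n_blocks=2, c_l=3, s_l=4,
                       c_h=3, s_h=4, d_in_low=16, d_in_high=16, seed=0)


@pytest.fixture(scope="session")
def tiny_train_config() -> TrainConfig:
    return TrainConfig(lr=1e-3, weight_decay=1e-3, batch_size=32,
                       max_epochs=30, patience=10, warmup_epochs=3,
                       cosine_t_max=27, n_folds=4, seed=0)


def sampled_token_cohort(signal: float, n_patients: int = 120, seed: int = 1):
    """Cluster-sampled token pairs from a planted-signal cohort."""
    from pathofuse import simulate as sim
    from pathofuse.patches import SamplerConfig, cluster_sample

    spec = sim.SyntheticCohortSpec(
        n_patients=n_patients, slides_per_patient=(1.0,), embed_dim=16,
        patch_counts={224: 24, 512: 24}, signal_strength=signal, seed=seed)
    cohort = sim.gen_embedding_cohort(spec)
    pairs = []
    for s in cohort.slides:
        tok_l, _ = cluster_sample(s.bags[224], SamplerConfig(3, 4, seed=seed))
        tok_h, _ = cluster_sample(s.bags[512], SamplerConfig(3, 4,
                                                             seed=seed + 1))
        pairs.append((tok_l, tok_h))
    return pairs, cohort.slide_labels, [s.patient_id for s in cohort.slides]


@pytest.fixture(scope="session")
def planted_signal_experiment(tiny_model_config, tiny_train_config):
    """Train the tiny transformer on a 120-patient planted-signal cohort
    (signal 2.0) and on a label-permuted copy; report held-out AUCs.

    Computed once per session; shared by the learning-sanity unit test and
    the acceptance check.
    """
    from sklearn.metrics import roc_auc_score
    from pathofuse.transformer import CrossScaleTransformerClassifier

    X, y, groups = sampled_token_cohort(signal=2.0, n_patients=120, seed=1)
    n_tr = 90
    clf = CrossScaleTransformerClassifier(tiny_model_config,
                                          tiny_train_config)
    clf.fit([X[i] for i in range(n_tr)], y[:n_tr], groups=groups[:n_tr])
    test_auc = roc_auc_score(y[n_tr:], clf.decision_function(X[n_tr:]))
    # null control: mean over 3 independent whole-cohort permutations
    # (a single permutation's held-out AUC has sd ~0.13 at this size)
    perm_aucs = []
    for rep in range(3):
        y_perm = np.random.default_rng(rep).permutation(y)
        clf_perm = CrossScaleTransformerClassifier(tiny_model_config,
                                                   tiny_train_config)
        clf_perm.fit([X[i] for i in range(n_tr)], y_perm[:n_tr],
                     groups=groups[:n_tr])
        perm_aucs.append(roc_auc_score(
            y_perm[n_tr:], clf_perm.decision_function(X[n_tr:])))
    return {"clf": clf, "test_auc": test_auc,
            "perm_auc": float(np.mean(perm_aucs)),
            "X": X, "y": y, "n_train": n_tr}


def top_canonical_correlation(A, B):
    """Top canonical correlation between the column spaces of A and B."""
    def whiten(X):
        X = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        return U[:, S > 1e-10 * S[0]]
    s = np.linalg.svd(whiten(A).T @ whiten(B), compute_uv=False)
    return s[0]


@pytest.fixture(scope="session")
def two_view_vae():
    """mcVAE fitted on linear-Gaussian two-view data with a 4-d shared
    latent (session-scoped: shared by recovery, decomposition and
    acceptance tests)."""
    from pathofuse import fusion as F
    from pathofuse import simulate as sim

    X1, X2, Z = sim.gen_two_view_linear(500, latent_dim=4, dims=(20, 12),
                                        noise_sd=0.1, seed=0)
    vae = F.MultiChannelVAE(latent_dim=8, hidden_patho=32, hidden_pheno=32,
                            lr=5e-4, max_epochs=800, patience=100,
                            warmup_epochs=20, cosine_t_max=700,
                            batch_size=32, seed=0)
    vae.fit((X1, X2))
    return vae, X1, X2, Z
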