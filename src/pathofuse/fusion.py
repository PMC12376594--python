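"""Multimodal fusion: a multi-channel variational auto-encoder unifying the
1536-d slide representation with standardised clinical phenotypes, a fused
classification head, and a permutation-sampling Shapley explainer.

The mcVAE holds one encoder/decoder pair per modality ("channel").  Both
channels share a standard-normal latent prior; the training objective adds
intra-modal self-reconstruction and inter-modal cross-reconstruction terms
(all four decoder/latent combinations) to a KL regulariser:

    L = beta * (KL_patho + KL_pheno) - sum_{i,j} log p(X_i | Z_j)

with Gaussian unit-variance likelihoods, i.e. reconstruction log-likelihood
equals -0.5 * ||x - x_hat||^2 up to constants.  Latents are sampled with
the reparameterisation trick Z = mu + eps * sigma during training and
collapse to the posterior means (eps = 0) for deterministic inference; the
fused patient representation is the concatenation of the two channels'
posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from . import nn
from .nn import Tensor
from .errors import SchemaError

__all__ = ["PhenotypeStandardizer", "kl_standard_normal", "reparameterize",
           "MultiChannelVAE", "FusionHeadClassifier",
           "shapley_contributions", "top_canonical_correlation",
           "fused_vs_single_modality_benchmark"]


# ---------------------------------------------------------------------------
# phenotype standardisation
# ---------------------------------------------------------------------------

class PhenotypeStandardizer(BaseEstimator, TransformerMixin):
    """Standardise a mixed phenotype table into a numeric design matrix.

    Continuous columns are z-scored with training-set mean/SD; missing
    values fall back to the training mean (i.e. 0 after scaling).
    Categorical columns are one-hot encoded with an extra unknown-level
    bucket and a missing indicator.  The schema (column kinds and category
    levels) is inferred on fit and frozen afterwards.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.columns_ = list(X.columns)
        self.kinds_, self.stats_, self.levels_ = {}, {}, {}
        for col in self.columns_:
            s = X[col]
            if pd.api.types.is_numeric_dtype(s):
                self.kinds_[col] = "continuous"
                mu = float(s.mean())
                sd = float(s.std(ddof=0))
                self.stats_[col] = (mu, sd if sd > 1e-12 else 1.0)
            else:
                self.kinds_[col] = "categorical"
                self.levels_[col] = sorted(s.dropna().astype(str).unique())
        self.feature_names_ = []
        for col in self.columns_:
            if self.kinds_[col] == "continuous":
                self.feature_names_.append(col)
            else:
                self.feature_names_.extend(
                    [f"{col}={lv}" for lv in self.levels_[col]]
                    + [f"{col}=__unknown__", f"{col}=__missing__"])
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "columns_")
        missing_cols = set(self.columns_) - set(X.columns)
        if missing_cols:
            raise SchemaError(f"phenotype table lacks columns {missing_cols}")
        blocks = []
        for col in self.columns_:
            s = X[col]
            if self.kinds_[col] == "continuous":
                mu, sd = self.stats_[col]
                vals = pd.to_numeric(s, errors="coerce").to_numpy(np.float64)
                z = (vals - mu) / sd
                z[~np.isfinite(z)] = 0.0            # missing -> fit-set mean
                blocks.append(z[:, None])
            else:
                levels = self.levels_[col]
                block = np.zeros((len(s), len(levels) + 2))
                vals = s.astype(object)
                for i, v in enumerate(vals):
                    if pd.isna(v):
                        block[i, -1] = 1.0          # missing indicator
                    elif str(v) in levels:
                        block[i, levels.index(str(v))] = 1.0
                    else:
                        block[i, -2] = 1.0          # unknown-level bucket
                blocks.append(block)
        return np.hstack(blocks)

    @property
    def width_(self) -> int:
        check_is_fitted(self, "columns_")
        return len(self.feature_names_)

    def to_json(self, path) -> None:
        import json

        check_is_fitted(self, "columns_")
        with open(path, "w") as fh:
            json.dump({"columns": self.columns_, "kinds": self.kinds_,
                       "stats": self.stats_, "levels": self.levels_}, fh)

    @classmethod
    def from_json(cls, path) -> "PhenotypeStandardizer":
        import json

        with open(path) as fh:
            meta = json.load(fh)
        std = cls()
        std.columns_ = meta["columns"]
        std.kinds_ = meta["kinds"]
        std.stats_ = {k: tuple(v) for k, v in meta["stats"].items()}
        std.levels_ = meta["levels"]
        std.feature_names_ = []
        for col in std.columns_:
            if std.kinds_[col] == "continuous":
                std.feature_names_.append(col)
            else:
                std.feature_names_.extend(
                    [f"{col}={lv}" for lv in std.levels_[col]]
                    + [f"{col}=__unknown__", f"{col}=__missing__"])
        return std


# ---------------------------------------------------------------------------
# VAE primitives
# ---------------------------------------------------------------------------

def kl_standard_normal(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL divergence of a diagonal Gaussian from the standard normal:
    0.5 * sum_k (sigma_k^2 + mu_k^2 - 1 - log sigma_k^2)."""
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(0.5 * np.sum(sigma**2 + mu**2 - 1.0 - np.log(sigma**2)))


def reparameterize(mu, sigma, eps):
    """Elementwise mu + eps * sigma (works on arrays and graph tensors)."""
    return mu + eps * sigma


class _Channel(nn.Module):
    """One modality: encoder to (mu, log sigma), decoder back to the input.

    The Gaussian likelihood carries a learnable homoscedastic observation
    log-variance: with a fixed unit variance, a converged VAE prunes every
    direction whose data variance falls below 1, which silently discards
    class-relevant but variance-poor directions; learning the noise floor
    keeps any structure above the residual noise.
    """

    def __init__(self, input_dim: int, hidden: int, latent: int,
                 rng: np.random.Generator):
        super().__init__()
        self.input_dim = input_dim
        self.enc_hidden = nn.Linear(input_dim, hidden, rng)
        self.enc_mu = nn.Linear(hidden, latent, rng)
        self.enc_logsigma = nn.Linear(hidden, latent, rng)
        self.dec_hidden = nn.Linear(latent, hidden, rng)
        self.dec_out = nn.Linear(hidden, input_dim, rng)
        # one observation log-variance per reconstruction route: the
        # cross-modal route has irreducibly larger residuals and must not
        # inflate the noise floor of the self route
        self.log_var_self = Tensor(np.zeros(()), requires_grad=True)
        self.log_var_cross = Tensor(np.zeros(()), requires_grad=True)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc_hidden(x).relu()
        log_sigma = self.enc_logsigma(h)
        # clamp via tanh to keep sigma in a sane range and > 0
        return self.enc_mu(h), (log_sigma.tanh() * 5.0).exp()

    def decode(self, z: Tensor) -> Tensor:
        return self.dec_out(self.dec_hidden(z).relu())


class MultiChannelVAE(BaseEstimator, TransformerMixin):
    """Two-channel VAE over paired (histopathology, phenotype) vectors.

    ``fit`` expects ``X = (X_patho, X_pheno)`` with one row per patient in
    each array.  ``transform`` returns the fused representation: the
    concatenated posterior means of the two channels (width ``2 *
    latent_dim``); with one modality set to ``None`` the missing channel's
    block is imputed by the observed channel's posterior mean
    (cross-inference, flagged through ``last_transform_imputed_``).

    Training minimises ``beta * (KL_1 + KL_2) - L_rec`` where L_rec sums
    the four (decoder channel, latent channel) Gaussian reconstruction
    terms, using AdamW (lr 5e-4, weight decay 5e-4, batch 32) with linear
    warm-up and cosine annealing and early stopping on validation loss.
    """

    def __init__(self, latent_dim=32, hidden_patho=256, hidden_pheno=64,
                 beta=0.25, lr=5e-4, weight_decay=5e-4, batch_size=32,
                 max_epochs=2000, patience=100, warmup_epochs=50,
                 cosine_t_max=50, val_fraction=0.1, seed=0):
        self.latent_dim = latent_dim
        self.hidden_patho = hidden_patho
        self.hidden_pheno = hidden_pheno
        self.beta = beta
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.warmup_epochs = warmup_epochs
        self.cosine_t_max = cosine_t_max
        self.val_fraction = val_fraction
        self.seed = seed

    # -- objective -------------------------------------------------------
    def _elbo_terms(self, xp: np.ndarray, xf: np.ndarray,
                    eps_rng: np.random.Generator | None) -> dict[str, Tensor]:
        """Loss components for one batch; eps_rng None => deterministic
        (posterior means)."""
        tp, tf = Tensor(xp), Tensor(xf)
        mu_p, sig_p = self.channel_patho_.encode(tp)
        mu_f, sig_f = self.channel_pheno_.encode(tf)
        if eps_rng is None:
            z_p, z_f = mu_p, mu_f
        else:
            z_p = reparameterize(mu_p, sig_p, Tensor(
                eps_rng.standard_normal(mu_p.shape)))
            z_f = reparameterize(mu_f, sig_f, Tensor(
                eps_rng.standard_normal(mu_f.shape)))
        n = xp.shape[0]
        terms: dict[str, Tensor] = {}
        for name, x, dec in (("patho", tp, self.channel_patho_),
                             ("pheno", tf, self.channel_pheno_)):
            for zname, z in (("patho", z_p), ("pheno", z_f)):
                lv = dec.log_var_self if zname == name else dec.log_var_cross
                diff = dec.decode(z) - x
                terms[f"rec_{name}|{zname}"] = (
                    (diff * diff).sum() * (-lv).exp() * (-0.5 / n)
                    + lv * (-0.5 * dec.input_dim))
        kl_p = ((sig_p**2.0 + mu_p**2.0 - 1.0
                 - (sig_p**2.0).log()).sum() * (0.5 / n))
        kl_f = ((sig_f**2.0 + mu_f**2.0 - 1.0
                 - (sig_f**2.0).log()).sum() * (0.5 / n))
        terms["kl_patho"], terms["kl_pheno"] = kl_p, kl_f
        rec = None
        for k, v in terms.items():
            if k.startswith("rec_"):
                rec = v if rec is None else rec + v
        terms["l_rec"] = rec
        terms["l_reg"] = (kl_p + kl_f) * self.beta
        terms["loss"] = terms["l_reg"] - rec
        return terms

    def elbo_components(self, X_patho: np.ndarray, X_pheno: np.ndarray,
                        seed: int | None = None) -> dict[str, float]:
        """Numeric loss decomposition on a batch (deterministic latents by
        default)."""
        check_is_fitted(self, "channel_patho_")
        xp, xf = self._check_pair(X_patho, X_pheno)
        rng = np.random.default_rng(seed) if seed is not None else None
        with nn.no_grad():
            terms = self._elbo_terms(xp, xf, rng)
        return {k: float(v.data) for k, v in terms.items()}

    @staticmethod
    def _check_pair(X_patho, X_pheno) -> tuple[np.ndarray, np.ndarray]:
        xp = np.asarray(X_patho, dtype=np.float64)
        xf = np.asarray(X_pheno, dtype=np.float64)
        if xp.shape[0] != xf.shape[0]:
            raise ValueError("channels must be paired: row counts differ")
        return xp, xf

    # -- training --------------------------------------------------------
    def fit(self, X, y=None):
        xp, xf = self._check_pair(*X)
        if xp.shape[0] < 2:
            raise ValueError("training requires at least two patients")
        rng = np.random.default_rng(self.seed)
        self.channel_patho_ = _Channel(xp.shape[1], self.hidden_patho,
                                       self.latent_dim, rng)
        self.channel_pheno_ = _Channel(xf.shape[1], self.hidden_pheno,
                                       self.latent_dim, rng)
        # start the observation noise at the marginal variance: the
        # log-variance moves only ~lr per optimiser step, so a poor start
        # freezes an over-wide noise floor and collapses the posterior
        for ch, x in ((self.channel_patho_, xp), (self.channel_pheno_, xf)):
            lv0 = float(np.log(max(x.var(), 1e-8)))
            ch.log_var_self.data = np.array(lv0)
            # the untrained cross route predicts nothing, so its residual
            # starts at the data variance and rises while the latents are
            # still unaligned; starting it wider keeps the cross penalty
            # from crushing self-reconstruction early in training
            ch.log_var_cross.data = np.array(lv0 + np.log(4.0))
        params = (self.channel_patho_.parameters()
                  + self.channel_pheno_.parameters())
        opt = nn.AdamW(params, lr=self.lr, weight_decay=self.weight_decay)
        sched = nn.WarmupCosineSchedule(self.lr, self.warmup_epochs,
                                        self.cosine_t_max)
        n = xp.shape[0]
        n_val = max(1, int(round(self.val_fraction * n))) if n > 4 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        eps_rng = np.random.default_rng(self.seed + 1)
        order_rng = np.random.default_rng(self.seed + 2)
        best_val, best_state, best_epoch = np.inf, None, -1
        self.history_ = []
        for epoch in range(self.max_epochs):
            sched.apply(opt, epoch)
            order = order_rng.permutation(tr_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                terms = self._elbo_terms(xp[idx], xf[idx], eps_rng)
                loss = terms["loss"]
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"divergent mcVAE loss at epoch {epoch}: "
                        f"{float(loss.data)!r}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            epoch_loss /= len(tr_idx)
            if n_val:
                with nn.no_grad():
                    val_loss = float(
                        self._elbo_terms(xp[val_idx], xf[val_idx],
                                         None)["loss"].data)
            else:
                val_loss = epoch_loss
            self.history_.append({"epoch": epoch, "loss": epoch_loss,
                                  "val_loss": val_loss})
            if val_loss < best_val - 1e-9:
                best_val, best_epoch = val_loss, epoch
                best_state = (self.channel_patho_.state_dict(),
                              self.channel_pheno_.state_dict())
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            self.channel_patho_.load_state_dict(best_state[0])
            self.channel_pheno_.load_state_dict(best_state[1])
        self.channel_patho_.eval()
        self.channel_pheno_.eval()
        self.final_loss_ = best_val
        return self

    # -- inference -------------------------------------------------------
    def posterior(self, channel: str, X: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "channel_patho_")
        ch = {"patho": self.channel_patho_,
              "pheno": self.channel_pheno_}[channel]
        with nn.no_grad():
            mu, sigma = ch.encode(Tensor(np.asarray(X, dtype=np.float64)))
        return mu.data, sigma.data

    def save_checkpoint(self, prefix) -> None:
        """Weights as .npz plus hyperparameters as .json."""
        import json
        from pathlib import Path

        check_is_fitted(self, "channel_patho_")
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        state = {}
        for name, ch in (("patho", self.channel_patho_),
                         ("pheno", self.channel_pheno_)):
            for k, v in ch.state_dict().items():
                state[f"{name}:{k}"] = v
        np.savez(str(prefix) + ".npz", **state)
        dims = {"patho_dim": self.channel_patho_.input_dim,
                "pheno_dim": self.channel_pheno_.input_dim}
        with open(str(prefix) + ".json", "w") as fh:
            json.dump({**self.get_params(), **dims}, fh)

    @classmethod
    def load_checkpoint(cls, prefix) -> "MultiChannelVAE":
        import json

        with open(str(prefix) + ".json") as fh:
            meta = json.load(fh)
        dims = {k: meta.pop(k) for k in ("patho_dim", "pheno_dim")}
        vae = cls(**meta)
        rng = np.random.default_rng(vae.seed)
        vae.channel_patho_ = _Channel(dims["patho_dim"], vae.hidden_patho,
                                      vae.latent_dim, rng)
        vae.channel_pheno_ = _Channel(dims["pheno_dim"], vae.hidden_pheno,
                                      vae.latent_dim, rng)
        with np.load(str(prefix) + ".npz") as data:
            for name, ch in (("patho", vae.channel_patho_),
                             ("pheno", vae.channel_pheno_)):
                ch.load_state_dict({k.split(":", 1)[1]: data[k]
                                    for k in data.files
                                    if k.startswith(name + ":")})
        vae.channel_patho_.eval()
        vae.channel_pheno_.eval()
        return vae

    def transform(self, X) -> np.ndarray:
        X_patho, X_pheno = X
        self.last_transform_imputed_ = None
        if X_patho is None and X_pheno is None:
            raise ValueError("at least one modality must be observed")
        if X_patho is None:
            mu_f, _ = self.posterior("pheno", X_pheno)
            self.last_transform_imputed_ = "patho"
            return np.hstack([mu_f, mu_f])
        if X_pheno is None:
            mu_p, _ = self.posterior("patho", X_patho)
            self.last_transform_imputed_ = "pheno"
            return np.hstack([mu_p, mu_p])
        mu_p, _ = self.posterior("patho", X_patho)
        mu_f, _ = self.posterior("pheno", X_pheno)
        return np.hstack([mu_p, mu_f])


# ---------------------------------------------------------------------------
# fusion classification head
# ---------------------------------------------------------------------------

class FusionHeadClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer classification head on the fused latent.

    Affine -> ReLU -> dropout 0.4 -> affine -> logit; trained with binary
    cross-entropy, AdamW (lr 5e-4, weight decay 5e-4, batch 60, up to 100
    epochs) and early stopping (patience 10) on validation AUC.
    """

    def __init__(self, hidden=32, dropout=0.4, lr=5e-4, weight_decay=5e-4,
                 batch_size=60, max_epochs=100, patience=10,
                 val_fraction=0.2, seed=0):
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present")
        rng = np.random.default_rng(self.seed)
        drop_rng = np.random.default_rng(self.seed + 1)
        self.model_ = nn.Sequential(
            nn.Linear(X.shape[1], self.hidden, rng),
            nn.ReLU(),
            nn.Dropout(self.dropout, drop_rng),
            nn.Linear(self.hidden, 1, rng),
        )
        opt = nn.AdamW(self.model_.parameters(), lr=self.lr,
                       weight_decay=self.weight_decay)
        n = len(y)
        perm = rng.permutation(n)
        n_val = max(2, int(round(self.val_fraction * n)))
        # keep both classes in validation if possible
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
            pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
            val_idx = np.concatenate([pos[:max(1, n_val // 2)],
                                      neg[:max(1, n_val // 2)]])
            tr_idx = np.setdiff1d(perm, val_idx)
        order_rng = np.random.default_rng(self.seed + 2)
        # model selection on validation loss: smoother than AUC on the
        # small validation splits typical at this cohort size
        best_loss, best_state, best_epoch = np.inf, None, -1
        for epoch in range(self.max_epochs):
            order = order_rng.permutation(tr_idx)
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.model_(Tensor(X[idx])).reshape(-1)
                loss = nn.bce_with_logits(logits, y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
            self.model_.eval()
            with nn.no_grad():
                val_logits = self.model_(Tensor(X[val_idx])).reshape(-1)
                val_loss = float(nn.bce_with_logits(val_logits,
                                                    y[val_idx]).data)
            self.model_.train()
            if val_loss < best_loss - 1e-9:
                best_loss, best_epoch = val_loss, epoch
                best_state = self.model_.state_dict()
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.model_.eval()
        with nn.no_grad():
            val_logits = self.model_(Tensor(X[val_idx])).reshape(-1).data
        self.val_auc_ = (roc_auc_score(y[val_idx], val_logits)
                         if len(np.unique(y[val_idx])) > 1 else np.nan)
        return self

    def save_checkpoint(self, prefix) -> None:
        import json
        from pathlib import Path

        check_is_fitted(self, "model_")
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        state = self.model_.state_dict()
        np.savez(str(prefix) + ".npz", **state)
        in_dim = self.model_.layers[0].in_features
        with open(str(prefix) + ".json", "w") as fh:
            json.dump({**self.get_params(), "input_dim": in_dim}, fh)

    @classmethod
    def load_checkpoint(cls, prefix) -> "FusionHeadClassifier":
        import json

        with open(str(prefix) + ".json") as fh:
            meta = json.load(fh)
        in_dim = meta.pop("input_dim")
        clf = cls(**meta)
        rng = np.random.default_rng(clf.seed)
        drop_rng = np.random.default_rng(clf.seed + 1)
        clf.model_ = nn.Sequential(
            nn.Linear(in_dim, clf.hidden, rng),
            nn.ReLU(),
            nn.Dropout(clf.dropout, drop_rng),
            nn.Linear(clf.hidden, 1, rng),
        )
        with np.load(str(prefix) + ".npz") as data:
            clf.model_.load_state_dict({k: data[k] for k in data.files})
        clf.model_.eval()
        clf.classes_ = np.array([0.0, 1.0])
        return clf

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        with nn.no_grad():
            return self.model_(
                Tensor(np.asarray(X, dtype=np.float64))).reshape(-1).data

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def top_canonical_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """Top canonical correlation between the column spaces of A and B
    (latent-recovery diagnostic)."""
    def whiten(X):
        X = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        return U[:, S > 1e-10 * S[0]]
    s = np.linalg.svd(whiten(A).T @ whiten(B), compute_uv=False)
    return float(s[0])


def fused_vs_single_modality_benchmark(seed: int, n_patients: int = 600,
                                       ) -> dict[str, float]:
    """One run of the complementary-signal fusion benchmark.

    Generates a paired cohort in which the image summary and the phenotype
    table carry independent label signal, fits per-modality logistic
    baselines plus the mcVAE + fusion head, and evaluates all three on a
    held-out half.  Returns AUCs under keys ``patho``, ``pheno``,
    ``fused``.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    from .simulate import gen_multimodal_cohort

    Xp, pheno, y = gen_multimodal_cohort(n_patients=n_patients, seed=seed)
    Xf = PhenotypeStandardizer().fit(pheno).transform(pheno)
    n_tr = n_patients // 2
    aucs: dict[str, float] = {}
    for name, X in (("patho", Xp), ("pheno", Xf)):
        lr = LogisticRegression(max_iter=3000).fit(X[:n_tr], y[:n_tr])
        aucs[name] = roc_auc_score(y[n_tr:], lr.decision_function(X[n_tr:]))
    vae = MultiChannelVAE(latent_dim=16, hidden_patho=64, hidden_pheno=64,
                          max_epochs=300, patience=60, warmup_epochs=20,
                          cosine_t_max=250, seed=seed)
    vae.fit((Xp[:n_tr], Xf[:n_tr]))
    fused_tr = vae.transform((Xp[:n_tr], Xf[:n_tr]))
    fused_te = vae.transform((Xp[n_tr:], Xf[n_tr:]))
    head = FusionHeadClassifier(hidden=128, max_epochs=100, patience=10,
                                seed=seed).fit(fused_tr, y[:n_tr])
    aucs["fused"] = roc_auc_score(y[n_tr:], head.decision_function(fused_te))
    return aucs


# ---------------------------------------------------------------------------
# Shapley contributions
# ---------------------------------------------------------------------------

def shapley_contributions(predict_fn, sample: np.ndarray,
                          background: np.ndarray, n_permutations: int = 200,
                          seed: int = 0) -> np.ndarray:
    """Monte-Carlo permutation Shapley values for one sample.

    `predict_fn` maps an (n, d) matrix to n scalars (for a classifier, a
    probability or decision value).  Each iteration draws a background row
    and a feature permutation and accumulates marginal contributions as
    features switch from background to sample values; the efficiency
    property Sum(phi) ~= f(sample) - mean f(background) holds in
    expectation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(sample, dtype=np.float64).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if bg.shape[0] == 0:
        raise ValueError("background set must be nonempty")
    d = x.shape[0]
    rng = np.random.default_rng(seed)
    phi = np.zeros(d)
    for _ in range(n_permutations):
        b = bg[rng.integers(0, bg.shape[0])]
        order = rng.permutation(d)
        # all intermediate points in one batch: row k has the first k
        # features of `order` switched to the sample's values
        grid = np.tile(b, (d + 1, 1))
        for k, feat in enumerate(order):
            grid[k + 1:, feat] = x[feat]
        preds = np.asarray(predict_fn(grid), dtype=np.float64).ravel()
        phi[order] += np.diff(preds) / n_permutations
    return phi
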