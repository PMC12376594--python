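"""Two-branch multi-scale transformer for slide-level mutation prediction.

The model consumes two sampled token sets per slide — embeddings of 224-px
("low-scale") and 512-px ("high-scale") patches — and emits a single
carrier logit plus a slide representation formed by concatenating the two
branches' class tokens (1536-d at the default token width of 768).

Each branch embeds its tokens (linear -> batch standardisation -> ReLU),
prepends a learnable class token, and runs through a stack of pre-norm
residual blocks in which scaled-dot-product attention alternates between
within-branch self-attention (even blocks) and cross-attention (odd
blocks), where each branch's full token set queries the other branch's
tokens as keys/values.  Tokens are cluster samples with no meaningful
order, so no positional encoding is used and the slide logit is invariant
to within-branch token permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.utils.validation import check_is_fitted

from . import nn
from .nn import Tensor
from .patches import PatchBag, SamplerConfig, cluster_sample

__all__ = ["ModelConfig", "TrainConfig", "CrossScaleTransformer",
           "CrossScaleTransformerClassifier", "attention",
           "aggregate_patient", "sigmoid"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the published recipe:
    token width 768, 64-d heads x 12, 12 blocks, 30x60 tokens per scale)."""

    d: int = 768
    d_k: int = 64
    n_heads: int = 12
    n_blocks: int = 12
    c_l: int = 30
    s_l: int = 60
    c_h: int = 30
    s_h: int = 60
    d_in_low: int | None = None     # defaults to d
    d_in_high: int | None = None
    mlp_ratio: int = 4
    dropout: float = 0.0
    start_with_self: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if min(self.d, self.d_k, self.n_heads) < 1:
            raise ValueError("d, d_k and n_heads must be >= 1")

    @property
    def n_low(self) -> int:
        return self.c_l * self.s_l

    @property
    def n_high(self) -> int:
        return self.c_h * self.s_h

    @property
    def feature_dim(self) -> int:
        return 2 * self.d


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe: binary cross-entropy on logits, adaptive-moment
    optimiser with decoupled weight decay, linear warm-up then cosine
    annealing, patient-level 4-fold cross-validation with early stopping on
    validation AUC."""

    lr: float = 1e-5
    weight_decay: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 20
    warmup_epochs: int = 5
    cosine_t_max: int = 95
    n_folds: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @classmethod
    def finetune_preset(cls) -> "TrainConfig":
        """Preset for adapting a trained model to fresh-frozen material."""
        return cls(lr=1e-3, weight_decay=5e-4, batch_size=2, max_epochs=50,
                   patience=10, warmup_epochs=10, cosine_t_max=20)


# ---------------------------------------------------------------------------
# attention primitive
# ---------------------------------------------------------------------------

def attention(q_src: Tensor, kv_src: Tensor, w_q: Tensor, w_k: Tensor,
              w_v: Tensor, w_out: Tensor, force_uniform: bool = False,
              ) -> Tensor:
    """Multi-head scaled dot-product attention.

    `q_src` (n_q, d) provides queries; `kv_src` (n_k, d) provides keys and
    values — identical sources give self-attention, sources from different
    branches give cross-attention.  Projections `w_q`, `w_k`, `w_v` are
    stacked per head, shape (h, d, d_k); head outputs are concatenated and
    projected by `w_out` of shape (h*d_k, d).  `force_uniform` is a test
    hook replacing the softmax with uniform weights over keys.
    """
    if kv_src.shape[0] == 0:
        raise ValueError("attention requires at least one key/value token")
    n_q, d = q_src.shape
    h, _, d_k = w_q.shape
    q = q_src.reshape(1, n_q, d) @ w_q                      # (h, n_q, d_k)
    k = kv_src.reshape(1, kv_src.shape[0], d) @ w_k         # (h, n_k, d_k)
    v = kv_src.reshape(1, kv_src.shape[0], d) @ w_v
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if force_uniform:
        weights = Tensor(np.full(scores.shape, 1.0 / scores.shape[-1]))
    else:
        weights = scores.softmax(axis=-1)
    heads = weights @ v                                     # (h, n_q, d_k)
    merged = heads.transpose(1, 0, 2).reshape(n_q, h * d_k)
    return merged @ w_out


class BranchAttention(nn.Module):
    """Per-branch attention parameters: per-head W_Q/W_K/W_V and the
    concatenated-head output projection."""

    def __init__(self, d: int, d_k: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(d)
        self.w_q = Tensor(rng.normal(0, scale, (n_heads, d, d_k)), requires_grad=True)
        self.w_k = Tensor(rng.normal(0, scale, (n_heads, d, d_k)), requires_grad=True)
        self.w_v = Tensor(rng.normal(0, scale, (n_heads, d, d_k)), requires_grad=True)
        self.w_out = Tensor(rng.normal(0, 1.0 / np.sqrt(n_heads * d_k),
                                       (n_heads * d_k, d)), requires_grad=True)

    def forward(self, q_src: Tensor, kv_src: Tensor,
                force_uniform: bool = False) -> Tensor:
        return attention(q_src, kv_src, self.w_q, self.w_k, self.w_v,
                         self.w_out, force_uniform=force_uniform)


class FeedForward(nn.Module):
    def __init__(self, d: int, mlp_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(d, d * mlp_ratio, rng)
        self.fc2 = nn.Linear(d * mlp_ratio, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiScaleBlock(nn.Module):
    """One pre-norm residual block over both branches.

    `cross=False`: each branch self-attends.  `cross=True`: each branch's
    tokens (class token included) query the other branch's tokens.
    """

    def __init__(self, cfg: ModelConfig, cross: bool, rng: np.random.Generator):
        super().__init__()
        self.cross = cross
        self.norm1_l = nn.LayerNorm(cfg.d)
        self.norm1_h = nn.LayerNorm(cfg.d)
        self.attn_l = BranchAttention(cfg.d, cfg.d_k, cfg.n_heads, rng)
        self.attn_h = BranchAttention(cfg.d, cfg.d_k, cfg.n_heads, rng)
        self.norm2_l = nn.LayerNorm(cfg.d)
        self.norm2_h = nn.LayerNorm(cfg.d)
        self.ffn_l = FeedForward(cfg.d, cfg.mlp_ratio, rng)
        self.ffn_h = FeedForward(cfg.d, cfg.mlp_ratio, rng)

    def forward(self, x_l: Tensor, x_h: Tensor,
                force_uniform: bool = False) -> tuple[Tensor, Tensor]:
        q_l, q_h = self.norm1_l(x_l), self.norm1_h(x_h)
        if self.cross:
            a_l = self.attn_l(q_l, q_h, force_uniform)
            a_h = self.attn_h(q_h, q_l, force_uniform)
        else:
            a_l = self.attn_l(q_l, q_l, force_uniform)
            a_h = self.attn_h(q_h, q_h, force_uniform)
        x_l, x_h = x_l + a_l, x_h + a_h
        x_l = x_l + self.ffn_l(self.norm2_l(x_l))
        x_h = x_h + self.ffn_h(self.norm2_h(x_h))
        return x_l, x_h


class CrossScaleTransformer(nn.Module):
    """The full two-branch model: embedding layers, class tokens, stacked
    multi-scale blocks, and a linear fusion head on the concatenated class
    tokens."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d_in_l = cfg.d_in_low if cfg.d_in_low is not None else cfg.d
        d_in_h = cfg.d_in_high if cfg.d_in_high is not None else cfg.d
        self.embed_lin_l = nn.Linear(d_in_l, cfg.d, rng)
        self.embed_bn_l = nn.BatchNorm1d(cfg.d)
        self.embed_lin_h = nn.Linear(d_in_h, cfg.d, rng)
        self.embed_bn_h = nn.BatchNorm1d(cfg.d)
        self.cls_l = Tensor(rng.normal(0, 0.02, (1, cfg.d)), requires_grad=True)
        self.cls_h = Tensor(rng.normal(0, 0.02, (1, cfg.d)), requires_grad=True)
        self.blocks = []
        for b in range(cfg.n_blocks):
            cross = (b % 2 == 1) if cfg.start_with_self else (b % 2 == 0)
            block = MultiScaleBlock(cfg, cross, rng)
            setattr(self, f"block{b}", block)
            self.blocks.append(block)
        self.head = nn.Linear(cfg.feature_dim, 1, rng)

    # -- pieces ----------------------------------------------------------
    def embed_tokens(self, z: Tensor | np.ndarray, branch: str) -> Tensor:
        """Embedding layer: linear map, per-feature batch standardisation,
        rectification (outputs elementwise >= 0)."""
        z = z if isinstance(z, Tensor) else Tensor(z)
        if branch == "low":
            return self.embed_bn_l(self.embed_lin_l(z)).relu()
        if branch == "high":
            return self.embed_bn_h(self.embed_lin_h(z)).relu()
        raise ValueError(f"unknown branch {branch!r}")

    def forward_batch(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                      ) -> Tensor:
        """Logits for a minibatch of slides.

        All slides' tokens pass through the embedding layer jointly, so the
        batch standardisation uses statistics of the whole minibatch rather
        than of a single slide (a per-slide standardisation would remove
        exactly the between-slide mean differences the model must learn).
        The transformer blocks then run per slide.
        """
        for z_l, z_h in pairs:
            if z_l.shape[0] != self.cfg.n_low or z_h.shape[0] != self.cfg.n_high:
                raise ValueError("token count mismatch with configuration")
        joint_l = self.embed_tokens(
            nn.concatenate([Tensor._coerce(z) for z, _ in pairs], axis=0), "low")
        joint_h = self.embed_tokens(
            nn.concatenate([Tensor._coerce(z) for _, z in pairs], axis=0), "high")
        logits = []
        for i in range(len(pairs)):
            x_l = nn.concatenate(
                [self.cls_l,
                 joint_l[i * self.cfg.n_low:(i + 1) * self.cfg.n_low]], axis=0)
            x_h = nn.concatenate(
                [self.cls_h,
                 joint_h[i * self.cfg.n_high:(i + 1) * self.cfg.n_high]], axis=0)
            for block in self.blocks:
                x_l, x_h = block(x_l, x_h)
            feature = nn.concatenate([x_l[0], x_h[0]], axis=0)
            logits.append(self.head(feature.reshape(1, -1)).reshape(1))
        return nn.concatenate(logits, axis=0)

    def forward(self, z_l: Tensor | np.ndarray, z_h: Tensor | np.ndarray,
                force_uniform: bool = False) -> tuple[Tensor, Tensor]:
        """Map two token matrices to (logit, slide feature).

        Token counts must match the configured ``c*s`` per branch.
        """
        z_l = z_l if isinstance(z_l, Tensor) else Tensor(z_l)
        z_h = z_h if isinstance(z_h, Tensor) else Tensor(z_h)
        if z_l.shape[0] != self.cfg.n_low or z_h.shape[0] != self.cfg.n_high:
            raise ValueError(
                f"expected {self.cfg.n_low}/{self.cfg.n_high} tokens per "
                f"branch, got {z_l.shape[0]}/{z_h.shape[0]}")
        x_l = nn.concatenate([self.cls_l, self.embed_tokens(z_l, "low")], axis=0)
        x_h = nn.concatenate([self.cls_h, self.embed_tokens(z_h, "high")], axis=0)
        for block in self.blocks:
            x_l, x_h = block(x_l, x_h, force_uniform)
        feature = nn.concatenate([x_l[0], x_h[0]], axis=0)
        logit = self.head(feature.reshape(1, -1)).reshape(())
        return logit, feature


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def aggregate_patient(slide_probabilities) -> float:
    """Patient-level score: arithmetic mean of the patient's slide scores."""
    probs = np.asarray(list(slide_probabilities), dtype=np.float64)
    if probs.size == 0:
        raise ValueError("aggregate_patient requires at least one slide score")
    return float(probs.mean())


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CrossScaleTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Slide-level carrier classifier around :class:`CrossScaleTransformer`.

    `X` is a sequence of ``(tokens_low, tokens_high)`` pairs, one per slide;
    `y` the binary slide labels; `groups` the patient ids used for
    patient-level fold splitting.  Cross-validation keeps, per fold, the
    epoch with the best validation AUC and finally the fold with the best
    validation AUC overall.

    Fitted attributes: ``model_``, ``fold_aucs_``, ``best_fold_``,
    ``history_`` (per fold, per epoch: loss and validation AUC),
    ``classes_``.
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.model_config = model_config
        self.train_config = train_config

    # -- internals -------------------------------------------------------
    def _loss_on(self, model: CrossScaleTransformer, X, y, idx) -> Tensor:
        logits = model.forward_batch([X[i] for i in idx])
        return nn.bce_with_logits(logits, np.asarray(y)[idx])

    def _val_auc(self, model: CrossScaleTransformer, X, y, idx) -> float:
        model.eval()
        with nn.no_grad():
            logits = [float(model(X[i][0], X[i][1])[0].data) for i in idx]
        model.train()
        return roc_auc_score(np.asarray(y)[idx], logits)

    def fit(self, X, y, groups=None, folds=None):
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        mcfg = self.model_config or ModelConfig()
        tcfg = self.train_config or TrainConfig()
        if groups is None:
            groups = np.arange(len(y))
        groups = np.asarray(groups)
        if folds is None:
            gkf = GroupKFold(n_splits=tcfg.n_folds)
            folds = list(gkf.split(np.zeros(len(y)), y, groups))
        for tr, va in folds:
            if set(groups[tr]) & set(groups[va]):
                raise ValueError("a patient appears in both train and "
                                 "validation folds")
        self.classes_ = np.unique(y)
        self.fold_aucs_, self.history_ = [], []
        fold_states = []
        for fold_idx, (tr, va) in enumerate(folds):
            model = CrossScaleTransformer(replace(mcfg, seed=mcfg.seed + fold_idx))
            opt = nn.AdamW(model.parameters(), lr=tcfg.lr,
                           weight_decay=tcfg.weight_decay)
            sched = nn.WarmupCosineSchedule(tcfg.lr, tcfg.warmup_epochs,
                                            tcfg.cosine_t_max)
            rng = np.random.default_rng(tcfg.seed * 1000 + fold_idx)
            best_auc, best_state, best_epoch = -np.inf, None, -1
            log = []
            for epoch in range(tcfg.max_epochs):
                sched.apply(opt, epoch)
                order = rng.permutation(tr)
                epoch_loss = 0.0
                for start in range(0, len(order), tcfg.batch_size):
                    batch = order[start:start + tcfg.batch_size]
                    loss = self._loss_on(model, X, y, batch)
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    epoch_loss += float(loss.data) * len(batch)
                val_auc = self._val_auc(model, X, y, va)
                log.append({"epoch": epoch, "loss": epoch_loss / len(order),
                            "val_auc": val_auc})
                if val_auc > best_auc:
                    best_auc, best_epoch = val_auc, epoch
                    best_state = model.state_dict()
                elif epoch - best_epoch >= tcfg.patience:
                    break
            self.fold_aucs_.append(best_auc)
            self.history_.append(log)
            fold_states.append((best_state, replace(mcfg, seed=mcfg.seed + fold_idx)))
        self.fold_aucs_ = np.asarray(self.fold_aucs_)
        self.best_fold_ = int(np.argmax(self.fold_aucs_))
        state, cfg = fold_states[self.best_fold_]
        self.model_ = CrossScaleTransformer(cfg)
        self.model_.load_state_dict(state)
        self.model_.eval()
        return self

    # -- inference -------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        with nn.no_grad():
            return np.array([float(self.model_(zl, zh)[0].data)
                             for zl, zh in X])

    def predict_proba(self, X) -> np.ndarray:
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def slide_features(self, X) -> np.ndarray:
        """Slide representations (concatenated class tokens, 2*d each)."""
        check_is_fitted(self, "model_")
        self.model_.eval()
        with nn.no_grad():
            return np.stack([self.model_(zl, zh)[1].data for zl, zh in X])

    def save_checkpoint(self, prefix) -> None:
        """Write weights (.npz) plus the architecture config (.json)."""
        import dataclasses
        import json
        from pathlib import Path

        check_is_fitted(self, "model_")
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(str(prefix) + ".npz", **self.model_.state_dict())
        cfg = self.model_config or ModelConfig()
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(dataclasses.asdict(cfg), fh)

    @classmethod
    def load_checkpoint(cls, prefix) -> "CrossScaleTransformerClassifier":
        import json

        with open(str(prefix) + ".json") as fh:
            cfg = ModelConfig(**json.load(fh))
        clf = cls(model_config=cfg)
        clf.model_ = CrossScaleTransformer(cfg)
        with np.load(str(prefix) + ".npz") as data:
            clf.model_.load_state_dict({k: data[k] for k in data.files})
        clf.model_.eval()
        clf.classes_ = np.array([0.0, 1.0])
        return clf

    def predict_slide(self, bag_low: PatchBag, bag_high: PatchBag,
                      n_draws: int = 1, seed: int = 0) -> float:
        """Slide probability averaged over repeated cluster samplings."""
        check_is_fitted(self, "model_")
        mcfg = self.model_config or ModelConfig()
        probs = []
        self.model_.eval()
        for draw in range(n_draws):
            tok_l, _ = cluster_sample(bag_low, SamplerConfig(
                n_clusters=mcfg.c_l, n_samples=mcfg.s_l, seed=seed + draw))
            tok_h, _ = cluster_sample(bag_high, SamplerConfig(
                n_clusters=mcfg.c_h, n_samples=mcfg.s_h, seed=seed + draw))
            with nn.no_grad():
                logit = float(self.model_(tok_l, tok_h)[0].data)
            probs.append(sigmoid(logit))
        return float(np.mean(probs))
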