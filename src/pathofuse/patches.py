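"""Whole-slide-image pre-processing: tessellation, tissue and tumor
filtering, patch encoding, and clustering-based bag sampling.

A slide enters the model not as pixels but as a *bag* of patch embeddings:
the slide is tessellated into non-overlapping patches at two scales
(224 px and 512 px at 20x magnification), patches with less than half
tissue are dropped, remaining (optionally tumor-only) patches are encoded
to d-dimensional vectors, and a k-means clustering over the embeddings
drives a stratified random sample of ``n_clusters x n_samples`` tokens so
that rare morphologies are not lost to uniform sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from skimage import color
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import nn
from .errors import ContractError

logger = logging.getLogger(__name__)

LOW_SCALE = 224
HIGH_SCALE = 512

__all__ = [
    "PatchRef", "PatchBag", "SamplerConfig", "tessellate", "tissue_fraction",
    "filter_patches", "label_tumor_patch", "encode_patches", "cluster_sample",
    "reinhard_normalize", "IdentityProjectionEncoder", "PassthroughEncoder",
    "TumorPatchClassifier", "train_tumor_classifier", "build_bag",
    "LOW_SCALE", "HIGH_SCALE",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchRef:
    """One tessellated patch: 0-based half-open pixel intervals
    [row0, row0+scale) x [col0, col0+scale)."""

    slide_id: str
    scale: int
    row0: int
    col0: int
    tissue_fraction: float = 1.0
    tumor_flag: bool | None = None

    def __post_init__(self):
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in [0, 1]")


@dataclass
class PatchBag:
    """Per-slide, per-scale embedding matrix with aligned patch references."""

    slide_id: str
    scale: int
    embeddings: np.ndarray          # (n_patches, d)
    patch_refs: list[PatchRef]
    cluster_ids: np.ndarray | None = None

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a 2-d matrix")
        if len(self.patch_refs) != self.embeddings.shape[0]:
            raise ValueError("patch_refs and embedding rows must align")

    @property
    def n_patches(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def save(self, prefix: str | Path) -> None:
        """Write the matrix as .npy plus a JSON sidecar with provenance."""
        prefix = Path(prefix)
        np.save(str(prefix) + ".npy", self.embeddings)
        sidecar = {
            "slide_id": self.slide_id,
            "scale": self.scale,
            "coords": [[r.row0, r.col0] for r in self.patch_refs],
            "tissue_fraction": [r.tissue_fraction for r in self.patch_refs],
        }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, prefix: str | Path) -> "PatchBag":
        prefix = Path(prefix)
        emb = np.load(str(prefix) + ".npy")
        with open(str(prefix) + ".json") as fh:
            meta = json.load(fh)
        refs = [PatchRef(meta["slide_id"], meta["scale"], r, c, tf)
                for (r, c), tf in zip(meta["coords"], meta["tissue_fraction"])]
        return cls(meta["slide_id"], meta["scale"], emb, refs)


@dataclass
class SamplerConfig:
    """Clustering-based sampler: n_clusters k-means centers, n_samples
    patches drawn uniformly per cluster (defaults 30 x 60 per scale)."""

    n_clusters: int = 30
    n_samples: int = 60
    seed: int = 0
    replace_small_clusters: bool = True

    def __post_init__(self):
        if self.n_clusters < 1 or self.n_samples < 1:
            raise ValueError("n_clusters and n_samples must be >= 1")


# ---------------------------------------------------------------------------
# tessellation and tissue filtering
# ---------------------------------------------------------------------------

def tessellate(image: np.ndarray, patch_size: int, stride: int | None = None,
               slide_id: str = "slide") -> tuple[list[PatchRef], np.ndarray]:
    """Cut `image` into a non-overlapping grid of square patches.

    Right/bottom remainders smaller than `patch_size` are discarded.
    Returns the patch references and the stacked pixel blocks
    (n, patch_size, patch_size, channels).
    """
    if stride is None:
        stride = patch_size
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        logger.warning("image %dx%d smaller than patch size %d: no patches",
                       h, w, patch_size)
        return [], np.empty((0, patch_size, patch_size) + image.shape[2:],
                            dtype=image.dtype)
    refs, blocks = [], []
    for r0 in range(0, h - patch_size + 1, stride):
        for c0 in range(0, w - patch_size + 1, stride):
            refs.append(PatchRef(slide_id, patch_size, r0, c0))
            blocks.append(image[r0:r0 + patch_size, c0:c0 + patch_size])
    return refs, np.stack(blocks)


def tissue_fraction(patch: np.ndarray, saturation_min: float = 0.05,
                    luminance_max: float = 0.9) -> float:
    """Fraction of pixels that look like stained tissue.

    A pixel counts as tissue when its HSV saturation exceeds
    `saturation_min` and its gray-level luminance is below `luminance_max`
    (background on a scanned slide is near-white: bright and unsaturated).
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("tissue_fraction expects an RGB patch (H, W, 3)")
    rgb = patch.astype(np.float64)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    sat = color.rgb2hsv(rgb)[..., 1]
    lum = color.rgb2gray(rgb)
    return float(np.mean((sat > saturation_min) & (lum < luminance_max)))


def filter_patches(refs: Sequence[PatchRef], blocks: np.ndarray,
                   min_tissue: float = 0.5,
                   ) -> tuple[list[PatchRef], np.ndarray]:
    """Drop patches whose tissue fraction is strictly below `min_tissue`.

    The boundary case (fraction exactly equal to the threshold) is kept:
    only patches with *less* than the minimum are excluded.
    """
    kept_refs, kept_idx = [], []
    for i, (ref, block) in enumerate(zip(refs, blocks)):
        tf = tissue_fraction(block)
        if tf < min_tissue:
            continue
        kept_refs.append(PatchRef(ref.slide_id, ref.scale, ref.row0, ref.col0,
                                  tissue_fraction=tf, tumor_flag=ref.tumor_flag))
        kept_idx.append(i)
    return kept_refs, blocks[kept_idx] if kept_idx else blocks[:0]


def label_tumor_patch(tumor_area_fraction: float) -> bool:
    """Tumor patch iff strictly more than 25% of its area is tumor."""
    if not 0.0 <= tumor_area_fraction <= 1.0:
        raise ValueError("tumor area fraction must lie in [0, 1]")
    return tumor_area_fraction > 0.25


def reinhard_normalize(patch: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reinhard color transfer: match LAB channel means/SDs to a reference."""
    src = color.rgb2lab(patch.astype(np.float64) / 255.0
                        if patch.max() > 1.0 else patch.astype(np.float64))
    ref = color.rgb2lab(reference.astype(np.float64) / 255.0
                        if reference.max() > 1.0 else reference.astype(np.float64))
    out = np.empty_like(src)
    for ch in range(3):
        s_mu, s_sd = src[..., ch].mean(), src[..., ch].std()
        r_mu, r_sd = ref[..., ch].mean(), ref[..., ch].std()
        scale = r_sd / s_sd if s_sd > 1e-12 else 1.0
        out[..., ch] = (src[..., ch] - s_mu) * scale + r_mu
    rgb = np.clip(color.lab2rgb(out), 0.0, 1.0)
    return (rgb * 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# patch encoders
# ---------------------------------------------------------------------------

class PatchEncoder(Protocol):
    output_dim: int

    def encode(self, patches: np.ndarray) -> np.ndarray: ...


class IdentityProjectionEncoder:
    """Deterministic test encoder: downsampled pixels through a fixed,
    seeded random projection to `output_dim` (default 768) dimensions.

    Stands in for a pretrained histopathology foundation encoder, which is
    pluggable through the same `encode` interface.
    """

    def __init__(self, output_dim: int = 768, downsample: int = 8, seed: int = 0):
        self.output_dim = output_dim
        self.downsample = downsample
        self.seed = seed
        self._proj: np.ndarray | None = None

    def encode(self, patches: np.ndarray) -> np.ndarray:
        if len(patches) == 0:
            return np.empty((0, self.output_dim))
        feats = np.stack([_downsample_features(p, self.downsample)
                          for p in patches])
        if self._proj is None or self._proj.shape[0] != feats.shape[1]:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((feats.shape[1], self.output_dim))
            self._proj /= np.sqrt(feats.shape[1])
        return feats @ self._proj


class PassthroughEncoder:
    """Accepts pre-computed embedding matrices unchanged."""

    def __init__(self, output_dim: int):
        self.output_dim = output_dim

    def encode(self, patches: np.ndarray) -> np.ndarray:
        return np.asarray(patches, dtype=np.float64)


def _downsample_features(patch: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample a patch and flatten (channels preserved)."""
    p = patch.astype(np.float64)
    if p.max() > 1.0:
        p = p / 255.0
    h, w = p.shape[:2]
    hh, ww = h - h % factor, w - w % factor
    p = p[:hh, :ww]
    if p.ndim == 2:
        p = p[..., None]
    blocks = p.reshape(hh // factor, factor, ww // factor, factor, p.shape[2])
    return blocks.mean(axis=(1, 3)).ravel()


def encode_patches(patches: np.ndarray, encoder: PatchEncoder) -> np.ndarray:
    """Encode pixel patches (or pass through a pre-computed matrix).

    The encoder declares its output dimension; a mismatch between the
    declaration and the produced matrix is a contract violation.
    """
    out = encoder.encode(patches)
    out = np.asarray(out, dtype=np.float64)
    if out.ndim != 2 or (out.shape[0] > 0 and out.shape[1] != encoder.output_dim):
        raise ContractError(
            f"encoder declared output_dim={encoder.output_dim} but produced "
            f"shape {out.shape}")
    if out.shape[0] == 0:
        return np.empty((0, encoder.output_dim))
    return out


# ---------------------------------------------------------------------------
# clustering-based sampling
# ---------------------------------------------------------------------------

def cluster_sample(bag: PatchBag, cfg: SamplerConfig,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random sample of tokens from a k-means clustering.

    k-means (k-means++ init, 10 restarts, tol 1e-4, seeded) partitions the
    bag's embeddings into `n_clusters` groups; `n_samples` patches are drawn
    uniformly from each (with replacement when a cluster is smaller than
    `n_samples`).  If the bag holds fewer patches than `n_clusters`, the
    cluster count is reduced to the patch count and logged.

    Returns ``(tokens, provenance)`` where provenance[i] is the row index in
    `bag.embeddings` each token came from; output has exactly
    ``n_clusters_effective * n_samples`` rows, ordered by cluster index.
    """
    if bag.n_patches == 0:
        raise ValueError("cannot sample from an empty bag")
    n_clusters = cfg.n_clusters
    if bag.n_patches < n_clusters:
        logger.info("bag %s has %d < %d patches; reducing cluster count",
                    bag.slide_id, bag.n_patches, n_clusters)
        n_clusters = bag.n_patches
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, tol=1e-4,
                random_state=cfg.seed % (2**32))
    labels = km.fit_predict(bag.embeddings)
    bag.cluster_ids = labels
    rng = np.random.default_rng(cfg.seed)
    provenance = []
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        replace = len(members) < cfg.n_samples
        if replace and not cfg.replace_small_clusters:
            raise ValueError(f"cluster {c} smaller than n_samples and "
                             "replacement disabled")
        chosen = rng.choice(members, size=cfg.n_samples, replace=replace)
        provenance.append(chosen)
    provenance = np.concatenate(provenance)
    return bag.embeddings[provenance], provenance


# ---------------------------------------------------------------------------
# tumor patch classifier
# ---------------------------------------------------------------------------

class TumorPatchClassifier(BaseEstimator, ClassifierMixin):
    """Binary tumor/non-tumor patch classifier with 5-fold model selection.

    A small multilayer perceptron over block-mean downsampled pixel features
    is trained with binary cross-entropy and an adaptive-moment optimiser
    with decoupled weight decay (defaults: lr 7e-4, weight decay 5e-4,
    batch 64, 100 epochs).  Each of the 5 stratified folds trains its own
    model; the fold with the highest validation AUC is kept.

    Attributes set by :meth:`fit`: ``model_`` (best fold's network),
    ``fold_aucs_`` (5 validation AUCs), ``best_fold_``, ``classes_``.
    """

    def __init__(self, hidden_sizes=(32,), downsample=8, lr=7e-4,
                 weight_decay=5e-4, batch_size=64, n_epochs=100, n_folds=5,
                 seed=0):
        self.hidden_sizes = hidden_sizes
        self.downsample = downsample
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.n_folds = n_folds
        self.seed = seed

    def _features(self, patches: np.ndarray) -> np.ndarray:
        return np.stack([_downsample_features(p, self.downsample)
                         for p in patches])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TumorPatchClassifier":
        y = np.asarray(y, dtype=np.float64)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training requires both tumor and non-tumor patches")
        self.classes_ = classes
        feats = self._features(X)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.seed % (2**32))
        fold_aucs, fold_models = [], []
        for fold, (tr, va) in enumerate(skf.split(feats, y)):
            rng = np.random.default_rng(self.seed + 1000 + fold)
            dims = [feats.shape[1], *self.hidden_sizes, 1]
            model = nn.MLP(dims, rng)
            opt = nn.AdamW(model.parameters(), lr=self.lr,
                           weight_decay=self.weight_decay)
            order_rng = np.random.default_rng(self.seed + 2000 + fold)
            for _ in range(self.n_epochs):
                order = order_rng.permutation(len(tr))
                for start in range(0, len(tr), self.batch_size):
                    idx = tr[order[start:start + self.batch_size]]
                    logits = model(nn.Tensor(feats[idx])).reshape(-1)
                    loss = nn.bce_with_logits(logits, y[idx])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
            model.eval()
            with nn.no_grad():
                va_logits = model(nn.Tensor(feats[va])).reshape(-1).data
            fold_aucs.append(roc_auc_score(y[va], va_logits))
            fold_models.append(model)
        self.fold_aucs_ = np.asarray(fold_aucs)
        self.best_fold_ = int(np.argmax(fold_aucs))
        self.model_ = fold_models[self.best_fold_]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        with nn.no_grad():
            return self.model_(nn.Tensor(self._features(X))).reshape(-1).data

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_tumor_classifier(patches: np.ndarray, labels: np.ndarray,
                           **kwargs) -> TumorPatchClassifier:
    """Functional wrapper over :class:`TumorPatchClassifier`."""
    return TumorPatchClassifier(**kwargs).fit(patches, labels)


def build_bag(refs: Sequence[PatchRef], blocks: np.ndarray,
              encoder: PatchEncoder, slide_id: str, scale: int,
              tumor_classifier: TumorPatchClassifier | None = None,
              ) -> PatchBag:
    """Assemble a PatchBag from filtered patches.

    When a tumor classifier is supplied, only patches it calls tumor enter
    the bag (segmentation precedes sampling); otherwise all tissue patches
    are used.
    """
    refs = list(refs)
    if tumor_classifier is not None and len(refs):
        flags = tumor_classifier.predict(blocks).astype(bool)
        refs = [PatchRef(r.slide_id, r.scale, r.row0, r.col0,
                         r.tissue_fraction, bool(f))
                for r, f in zip(refs, flags)]
        blocks = blocks[flags]
        refs = [r for r in refs if r.tumor_flag]
    emb = encode_patches(blocks, encoder)
    return PatchBag(slide_id, scale, emb, refs)
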