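"""Synthetic cohorts for every input the pipeline consumes.

The real study data (H&E whole-slide images of breast tumors with germline
BRCA1/2 carrier labels, matched electronic-health-record phenotypes, and
HoVer-Net-style nucleus maps) are not publicly downloadable, so this module
generates structurally faithful stand-ins with controllable signal:

* two-scale patch-embedding bags with a planted class-conditional mean
  shift along a hidden unit vector (the "signal subspace"),
* carrier/non-carrier labels at roughly the matched 1:2-3 case-control
  ratio of the clinical design (carrier fraction 0.3 by default),
* mixed continuous/categorical phenotype tables whose label log-odds
  follow user-supplied coefficients,
* toy slide rasters for the tessellation code, and
* typed nucleus instance/type maps with controllable densities and a
  ground-truth contact list for the interaction detector.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError, SchemaError
from .patches import HIGH_SCALE, LOW_SCALE, PatchBag, PatchRef

__all__ = [
    "FieldSpec", "SyntheticCohortSpec", "SyntheticNucleiSpec",
    "SlideSample", "SyntheticCohort", "default_pheno_schema",
    "gen_toy_slide", "gen_embedding_cohort", "gen_phenotypes",
    "gen_nuclei_mask", "gen_two_view_linear", "gen_multimodal_cohort",
    "NUCLEUS_TYPES",
]

NUCLEUS_TYPES = ("neoplastic", "inflammatory", "connective", "dead",
                 "non_neoplastic_stromal", "unlabeled")


# ---------------------------------------------------------------------------
# phenotype schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """One phenotype field: continuous (mean/sd) or categorical (levels
    with marginal probabilities)."""

    name: str
    kind: str                                   # "continuous" | "categorical"
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"unknown field kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise SchemaError(f"categorical field {self.name!r} needs >= 2 levels")


def _binary(name: str, p: float) -> FieldSpec:
    return FieldSpec(name, "categorical", levels=("no", "yes"), probs=(1 - p, p))


def default_pheno_schema() -> list[FieldSpec]:
    """Clinical phenotype fields of a breast-cancer EHR record, with
    marginal frequencies patterned on a hospital case-control cohort."""
    return [
        FieldSpec("age_at_diagnosis", "continuous", mean=41.2, sd=9.3),
        _binary("tumor_size_gt2cm", 0.44),
        FieldSpec("grade", "categorical", levels=("I", "II", "III"),
                  probs=(0.05, 0.45, 0.50)),
        _binary("lymph_node_positive", 0.50),
        _binary("er_positive", 0.41),
        _binary("pr_positive", 0.40),
        _binary("her2_positive", 0.10),
        _binary("ar_positive", 0.60),
        _binary("ki67_gt30", 0.55),
        _binary("personal_history_any_cancer", 0.07),
        _binary("personal_history_breast_cancer", 0.04),
        _binary("personal_history_ovarian_cancer", 0.006),
        _binary("family_history_any_cancer", 0.45),
        _binary("family_history_breast_cancer", 0.23),
        _binary("family_history_ovarian_cancer", 0.04),
        _binary("family_history_pancreatic_cancer", 0.025),
        _binary("family_history_male_breast_cancer", 0.004),
    ]


def default_pheno_signal() -> dict[str, float]:
    """Default label log-odds coefficients: carriers are enriched for
    family/personal cancer history and hormone-receptor negativity."""
    return {
        "family_history_breast_cancer": 1.2,
        "family_history_ovarian_cancer": 1.0,
        "family_history_any_cancer": 0.6,
        "personal_history_ovarian_cancer": 1.0,
        "er_positive": -0.4,
        "her2_positive": -0.8,
        "age_at_diagnosis": -0.3,
    }


# ---------------------------------------------------------------------------
# cohort spec and containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Controls for the embedding-bag + phenotype cohort generator.

    signal_strength is the class-conditional mean shift (in noise-SD units
    when noise_sd=1) along a hidden random unit vector shared across the
    cohort; signal_fraction is the fraction of patches per carrier slide
    that carry the shift (1.0 = every patch).
    """

    n_patients: int = 120
    slides_per_patient: tuple[float, ...] = (0.35, 0.25, 0.15, 0.10, 0.10, 0.05)
    carrier_fraction: float = 0.3
    patch_counts: dict[int, int] = field(
        default_factory=lambda: {LOW_SCALE: 96, HIGH_SCALE: 96})
    embed_dim: int = 768
    signal_strength: float = 2.0
    signal_fraction: float = 1.0
    noise_sd: float = 1.0
    pheno_schema: list[FieldSpec] = field(default_factory=default_pheno_schema)
    pheno_signal: dict[str, float] = field(default_factory=default_pheno_signal)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier_fraction must lie strictly in (0, 1)")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        names = {f.name for f in self.pheno_schema}
        for key in self.pheno_signal:
            if key not in names:
                raise SchemaError(f"pheno_signal names unknown field {key!r}")


@dataclass
class SlideSample:
    slide_id: str
    patient_id: str
    label: int
    bags: dict[int, PatchBag]
    signal_flags: dict[int, np.ndarray]     # per scale: bool per patch


@dataclass
class SyntheticCohort:
    slides: list[SlideSample]
    patient_labels: pd.Series               # index patient_id, values {0,1}
    signal_vector: np.ndarray               # hidden unit vector

    @property
    def slide_labels(self) -> np.ndarray:
        return np.array([s.label for s in self.slides])


# ---------------------------------------------------------------------------
# toy slide raster
# ---------------------------------------------------------------------------

def gen_toy_slide(height: int, width: int, n_blobs: int = 6,
                  blob_radius: tuple[float, float] = (60.0, 140.0),
                  patch_size: int = LOW_SCALE, seed: int = 0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render an H&E-like toy slide: pink/purple tissue blobs on a
    near-white background.  Returns (RGB uint8 image, boolean tissue mask).
    """
    if height < 2 * patch_size or width < 2 * patch_size:
        raise ValueError(
            f"canvas {height}x{width} must be at least twice the patch size "
            f"({patch_size}) in each dimension")
    rng = np.random.default_rng(seed)
    img = np.full((height, width, 3), 250, dtype=np.float64)
    img += rng.normal(0, 1.5, img.shape)
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = np.mgrid[0:height, 0:width]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, height), rng.uniform(0, width)
        rad = rng.uniform(*blob_radius)
        blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
        shade = rng.uniform(0.8, 1.2)
        tone = np.array([200, 120, 170]) * shade    # eosin-ish pink/purple
        img[blob] = tone + rng.normal(0, 6, (int(blob.sum()), 3))
        mask |= blob
    return np.clip(img, 0, 255).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# embedding cohort
# ---------------------------------------------------------------------------

def gen_embedding_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate labeled two-scale patch-embedding bags.

    Patch embeddings are isotropic Gaussian noise; on carrier slides a
    `signal_fraction` subset of patches is mean-shifted by
    ``signal_strength`` along a hidden unit vector shared by the cohort.
    Slides inherit their patient's label.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal(spec.embed_dim)
    u /= np.linalg.norm(u)
    p_slides = np.asarray(spec.slides_per_patient, dtype=np.float64)
    p_slides = p_slides / p_slides.sum()
    labels = (rng.random(spec.n_patients) < spec.carrier_fraction).astype(int)
    slides: list[SlideSample] = []
    patient_ids = [f"P{i:04d}" for i in range(spec.n_patients)]
    for pid, y in zip(patient_ids, labels):
        n_slides = rng.choice(np.arange(1, len(p_slides) + 1), p=p_slides)
        for s in range(n_slides):
            sid = f"{pid}_S{s}"
            bags, flags = {}, {}
            for scale, count in spec.patch_counts.items():
                E = spec.noise_sd * rng.standard_normal((count, spec.embed_dim))
                flag = np.zeros(count, dtype=bool)
                if y == 1 and spec.signal_strength > 0:
                    n_sig = max(1, int(round(spec.signal_fraction * count)))
                    sig_idx = rng.choice(count, size=n_sig, replace=False)
                    E[sig_idx] += spec.signal_strength * u
                    flag[sig_idx] = True
                side = int(np.ceil(np.sqrt(count)))
                refs = [PatchRef(sid, scale, (k // side) * scale,
                                 (k % side) * scale) for k in range(count)]
                bags[scale] = PatchBag(sid, scale, E, refs)
                flags[scale] = flag
            slides.append(SlideSample(sid, pid, int(y), bags, flags))
    return SyntheticCohort(
        slides=slides,
        patient_labels=pd.Series(labels, index=patient_ids, name="label"),
        signal_vector=u,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def gen_phenotypes(spec: SyntheticCohortSpec,
                   labels: np.ndarray | pd.Series | None = None,
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a phenotype table whose label log-odds follow
    ``spec.pheno_signal``.

    Conditional construction: for a continuous field with coefficient b,
    carriers' standardized values are shifted by +b (Gaussian discriminant
    identity: the induced logistic coefficient per SD equals b); for a
    binary field with coefficient b the level-"yes" probability is moved by
    +/- b/2 on the logit scale, giving a population log-odds-ratio of
    exactly b.  Missing cells are injected completely at random.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if not spec.pheno_schema:
        raise SchemaError("pheno_schema must be nonempty")
    if labels is None:
        y = (rng.random(spec.n_patients) < spec.carrier_fraction).astype(int)
        index = pd.Index([f"P{i:04d}" for i in range(spec.n_patients)],
                         name="patient_id")
    else:
        y = np.asarray(labels, dtype=int)
        index = (labels.index if isinstance(labels, pd.Series)
                 else pd.Index([f"P{i:04d}" for i in range(len(y))],
                               name="patient_id"))
    n = len(y)
    cols: dict[str, np.ndarray] = {}
    for f in spec.pheno_schema:
        beta = spec.pheno_signal.get(f.name, 0.0)
        if f.kind == "continuous":
            z = rng.standard_normal(n) + beta * y
            cols[f.name] = f.mean + f.sd * z
        else:
            probs = np.asarray(f.probs if f.probs else
                               np.full(len(f.levels), 1.0 / len(f.levels)))
            probs = probs / probs.sum()
            if beta != 0.0 and len(f.levels) == 2:
                logit = np.log(probs[1] / probs[0])
                p1 = 1.0 / (1.0 + np.exp(-(logit + beta / 2.0)))
                p0 = 1.0 / (1.0 + np.exp(-(logit - beta / 2.0)))
                p_yes = np.where(y == 1, p1, p0)
                draw = (rng.random(n) < p_yes).astype(int)
            elif beta != 0.0:
                raise SchemaError(
                    f"signal coefficient on multi-level categorical field "
                    f"{f.name!r} is not supported")
            else:
                draw = rng.choice(len(f.levels), size=n, p=probs)
            cols[f.name] = np.asarray(f.levels, dtype=object)[draw]
    df = pd.DataFrame(cols, index=index)
    if spec.missing_rate > 0:
        miss = rng.random(df.shape) < spec.missing_rate
        df = df.mask(miss)
    return df, y


# ---------------------------------------------------------------------------
# nuclei masks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNucleiSpec:
    """Controls for the typed-nuclei mask generator.

    densities: expected nuclei per 10^4 px^2 for each of the 6 types;
    contact_rate: fraction of nuclei placed in direct contact with an
    already-placed nucleus.
    """

    canvas_size: tuple[int, int] = (256, 256)
    densities: tuple[float, ...] = (8.0, 4.0, 3.0, 0.5, 2.0, 0.5)
    mean_radius: float = 5.0
    radius_sd: float = 1.0
    contact_rate: float = 0.1
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self):
        if len(self.densities) != len(NUCLEUS_TYPES):
            raise ValueError(f"densities must have {len(NUCLEUS_TYPES)} entries")
        if any(d < 0 for d in self.densities):
            raise ValueError("densities must be nonnegative")
        if self.mean_radius <= 0:
            raise ValueError("mean radius must be positive")


def _disk_pixels(cy: int, cx: int, r: float, shape: tuple[int, int]):
    r_int = int(np.ceil(r))
    rr, cc = np.mgrid[cy - r_int:cy + r_int + 1, cx - r_int:cx + r_int + 1]
    inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= r * r
    rr, cc = rr[inside], cc[inside]
    in_bounds = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[in_bounds], cc[in_bounds], bool(in_bounds.all())


def _chebyshev_dilate(rr: np.ndarray, cc: np.ndarray, k: int,
                      shape: tuple[int, int]):
    """Pixels within Chebyshev distance k of the given pixel set."""
    offs = np.arange(-k, k + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    r2 = (rr[:, None] + dr.ravel()[None, :]).ravel()
    c2 = (cc[:, None] + dc.ravel()[None, :]).ravel()
    ok = (r2 >= 0) & (r2 < shape[0]) & (c2 >= 0) & (c2 < shape[1])
    return r2[ok], c2[ok]


def gen_nuclei_mask(spec: SyntheticNucleiSpec,
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Place disk-shaped typed nuclei on a canvas.

    Returns ``(instance_map, type_map, contacts)``: integer instance labels
    (0 = background), per-pixel types in 1..6, and the ground-truth list of
    touching instance pairs (8-adjacent masks).  Isolated nuclei keep at
    least 2 background pixels from every other instance; contact nuclei are
    placed edge-adjacent to a random partner.
    """
    h, w = spec.canvas_size
    area_units = h * w / 1e4
    counts = [int(round(d * area_units)) for d in spec.densities]
    total = sum(counts)
    if total == 0:
        return (np.zeros((h, w), dtype=np.int32),
                np.zeros((h, w), dtype=np.uint8), [])
    if h < 4 * spec.mean_radius or w < 4 * spec.mean_radius:
        raise ValueError("canvas too small to fit a nucleus with margin")
    rng = np.random.default_rng(spec.seed)
    types = np.repeat(np.arange(1, len(NUCLEUS_TYPES) + 1), counts)
    rng.shuffle(types)
    inst = np.zeros((h, w), dtype=np.int32)
    typ = np.zeros((h, w), dtype=np.uint8)
    keepout = np.zeros((h, w), dtype=bool)      # occupied dilated by 2
    centers: list[tuple[int, int, float]] = []
    contacts: set[tuple[int, int]] = set()
    for i, t in enumerate(types, start=1):
        radius = max(2.0, rng.normal(spec.mean_radius, spec.radius_sd))
        touching = len(centers) > 0 and rng.random() < spec.contact_rate
        placed = False
        for _ in range(spec.max_retries):
            if touching:
                j = rng.integers(0, len(centers))
                cy0, cx0, r0 = centers[j]
                theta = rng.uniform(0, 2 * np.pi)
                base = r0 + radius
                for extra in (0.0, 1.0, -1.0, 2.0):
                    d = base + extra
                    cy = int(round(cy0 + d * np.sin(theta)))
                    cx = int(round(cx0 + d * np.cos(theta)))
                    rr, cc, fully = _disk_pixels(cy, cx, radius, (h, w))
                    if not fully or len(rr) == 0 or inst[rr, cc].any():
                        continue
                    nb_r, nb_c = _chebyshev_dilate(rr, cc, 1, (h, w))
                    neighbors = set(inst[nb_r, nb_c][inst[nb_r, nb_c] > 0])
                    if neighbors:
                        placed = True
                        break
                if placed:
                    break
            else:
                m = int(np.ceil(radius)) + 1
                if h - 2 * m <= 0 or w - 2 * m <= 0:
                    break
                cy = int(rng.integers(m, h - m))
                cx = int(rng.integers(m, w - m))
                rr, cc, fully = _disk_pixels(cy, cx, radius, (h, w))
                if fully and len(rr) and not keepout[rr, cc].any():
                    neighbors = set()
                    placed = True
                    break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i}/{total} after "
                f"{spec.max_retries} retries (density too high?)")
        inst[rr, cc] = i
        typ[rr, cc] = t
        k_r, k_c = _chebyshev_dilate(rr, cc, 2, (h, w))
        keepout[k_r, k_c] = True
        centers.append((cy, cx, radius))
        for other in neighbors:
            contacts.add((min(int(other), i), max(int(other), i)))
    return inst, typ, sorted(contacts)


# ---------------------------------------------------------------------------
# fusion benchmarks
# ---------------------------------------------------------------------------

def gen_two_view_linear(n: int, latent_dim: int = 4,
                        dims: tuple[int, int] = (20, 12),
                        noise_sd: float = 0.1, seed: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two linear-Gaussian views of a shared latent: X_i = Z A_i^T + noise.

    Ground truth Z is returned for latent-recovery checks.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, latent_dim))
    X = []
    for d in dims:
        A = rng.standard_normal((d, latent_dim))
        X.append(Z @ A.T + noise_sd * rng.standard_normal((n, d)))
    return X[0], X[1], Z


def gen_multimodal_cohort(n_patients: int = 600, patho_dim: int = 8,
                          patho_signal: float = 0.7,
                          n_factors: int = 0,
                          pheno_schema: Sequence[FieldSpec] | None = None,
                          pheno_signal: dict[str, float] | None = None,
                          carrier_fraction: float = 0.3,
                          noise_sd: float = 0.4, seed: int = 0,
                          ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Per-patient paired modalities carrying independent partial signal.

    The histopathology view is a compact summary of what a *trained* slide
    model knows — a low-dimensional Gaussian vector with a label shift
    along a hidden unit vector — rather than a wide raw embedding: for a
    fusion benchmark the class direction must sit above the unsupervised
    detectability edge (a direction whose variance excess falls below the
    Marchenko-Pastur noise edge at the given n/d cannot be retained by
    *any* unsupervised compressor, so a wide low-SNR design would test
    sample-covariance geometry, not fusion).  Optional `n_factors` adds
    channel-private high-variance structure for stress tests.  The
    phenotype table carries its own label signal through ``pheno_signal``.
    Returns (X_patho, phenotypes, labels).
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n_patients) < carrier_fraction).astype(int)
    u = rng.standard_normal(patho_dim)
    u /= np.linalg.norm(u)
    loadings = rng.standard_normal((patho_dim, n_factors))
    loadings -= np.outer(u, u @ loadings)       # factors orthogonal to signal
    loadings /= np.linalg.norm(loadings, axis=0, keepdims=True)
    factors = rng.standard_normal((n_patients, n_factors))
    X_patho = (noise_sd * rng.standard_normal((n_patients, patho_dim))
               + 1.5 * factors @ loadings.T)
    X_patho += patho_signal * np.outer(y, u)
    spec = SyntheticCohortSpec(
        n_patients=n_patients,
        carrier_fraction=carrier_fraction,
        pheno_schema=list(pheno_schema) if pheno_schema is not None
        else default_pheno_schema(),
        pheno_signal=pheno_signal if pheno_signal is not None
        else default_pheno_signal(),
        missing_rate=0.0,
        seed=seed + 7,
    )
    pheno, _ = gen_phenotypes(spec, labels=y)
    return X_patho, pheno, y
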