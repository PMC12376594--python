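"""Run configuration, deterministic seeding, and pipeline orchestration.

The configuration file is YAML with one section per pipeline stage; unknown
keys are rejected with the offending key path, and defaults reproduce the
published training recipes.  Every stochastic stage derives its own seed
from the global seed plus the stage name, so a full pipeline re-run with
the same config is reproducible artifact-for-artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DependencyError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "save_config", "stage_seed",
           "run_pipeline", "STAGE_ORDER"]


@dataclass
class SimulateConfig:
    n_patients: int = 120
    carrier_fraction: float = 0.3
    embed_dim: int = 768
    signal_strength: float = 2.0
    noise_sd: float = 1.0
    patch_count: int = 96


@dataclass
class SampleConfig:
    n_clusters: int = 30
    n_samples: int = 60
    n_draws: int = 1
    min_tissue: float = 0.5


@dataclass
class TrainWiseConfig:
    d: int = 768
    d_k: int = 64
    n_heads: int = 12
    n_blocks: int = 12
    lr: float = 1e-5
    weight_decay: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 20
    warmup_epochs: int = 5
    cosine_t_max: int = 95
    n_folds: int = 4


@dataclass
class AttributeConfig:
    n_draws: int = 500
    n_steps: int = 64


@dataclass
class TrainFusionConfig:
    latent_dim: int = 32
    beta: float = 1.0
    lr: float = 5e-4
    weight_decay: float = 5e-4
    batch_size: int = 32
    max_epochs: int = 2000
    patience: int = 100
    head_batch_size: int = 60
    head_dropout: float = 0.4


@dataclass
class EvaluateConfig:
    n_boot: int = 2000
    level: str = "patient"


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    sample: SampleConfig = field(default_factory=SampleConfig)
    train_wise: TrainWiseConfig = field(default_factory=TrainWiseConfig)
    attribute: AttributeConfig = field(default_factory=AttributeConfig)
    train_fusion: TrainFusionConfig = field(default_factory=TrainFusionConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {where}")
        f = fields[key]
        has_factory = f.default_factory is not dataclasses.MISSING
        if has_factory and dataclasses.is_dataclass(f.default_factory()):
            kwargs[key] = _from_dict(type(f.default_factory()), value, where)
            continue
        default = f.default if f.default is not dataclasses.MISSING \
            else f.default_factory()
        ok = (isinstance(value, bool) if isinstance(default, bool)
              else isinstance(value, int) and not isinstance(value, bool)
              if isinstance(default, int)
              else isinstance(value, (int, float)) and not isinstance(value, bool)
              if isinstance(default, float)
              else isinstance(value, str))
        if not ok:
            raise ConfigError(
                f"bad type for {where}: expected {type(default).__name__}, "
                f"got {type(value).__name__}")
        kwargs[key] = type(default)(value)
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill gaps."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return _from_dict(RunConfig, raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg),
                                         sort_keys=False))


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage deterministic seed below 2^31."""
    return (global_seed * 100003 + zlib.crc32(stage.encode())) % (2**31 - 1)


STAGE_ORDER = ["simulate", "sample", "train-wise", "evaluate"]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the desk-scale synthetic pipeline end to end.

    simulate: generate an embedding cohort; sample: cluster-sample bags
    into token sets; train-wise: fit the slide transformer; evaluate:
    slide- and patient-level AUC with bootstrap CIs.  Returns the manifest
    (also written to the output directory) recording per-stage seeds and
    output hashes.
    """
    from . import evaluation, simulate as sim, transformer
    from .patches import SamplerConfig, cluster_sample

    stages = stages or list(STAGE_ORDER)
    for s in stages:
        if s not in STAGE_ORDER:
            raise ConfigError(f"unknown stage {s!r}")
    order = [s for s in STAGE_ORDER if s in stages]
    if order != stages:
        raise DependencyError(
            f"stages must respect the order {STAGE_ORDER}, got {stages}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    state: dict = {}
    for stage in stages:
        seed = stage_seed(cfg.seed, stage)
        if stage == "simulate":
            spec = sim.SyntheticCohortSpec(
                n_patients=cfg.simulate.n_patients,
                carrier_fraction=cfg.simulate.carrier_fraction,
                embed_dim=cfg.simulate.embed_dim,
                signal_strength=cfg.simulate.signal_strength,
                noise_sd=cfg.simulate.noise_sd,
                patch_counts={224: cfg.simulate.patch_count,
                              512: cfg.simulate.patch_count},
                seed=seed)
            state["cohort"] = sim.gen_embedding_cohort(spec)
            labels_path = out / "labels.csv"
            rows = [{"slide_id": s.slide_id, "patient_id": s.patient_id,
                     "label": s.label} for s in state["cohort"].slides]
            import pandas as pd
            pd.DataFrame(rows).to_csv(labels_path, index=False)
            artifacts = [labels_path]
        elif stage == "sample":
            if "cohort" not in state:
                raise DependencyError("sample requires the simulate stage")
            tokens = []
            for s in state["cohort"].slides:
                scales = sorted(s.bags)
                tok_l, _ = cluster_sample(s.bags[scales[0]], SamplerConfig(
                    cfg.sample.n_clusters, cfg.sample.n_samples, seed=seed))
                tok_h, _ = cluster_sample(s.bags[scales[-1]], SamplerConfig(
                    cfg.sample.n_clusters, cfg.sample.n_samples,
                    seed=seed + 1))
                tokens.append((tok_l, tok_h))
            state["tokens"] = tokens
            artifacts = []
        elif stage == "train-wise":
            if "tokens" not in state:
                raise DependencyError("train-wise requires the sample stage")
            cohort = state["cohort"]
            tw = cfg.train_wise
            mcfg = transformer.ModelConfig(
                d=tw.d, d_k=tw.d_k, n_heads=tw.n_heads, n_blocks=tw.n_blocks,
                c_l=cfg.sample.n_clusters, s_l=cfg.sample.n_samples,
                c_h=cfg.sample.n_clusters, s_h=cfg.sample.n_samples,
                d_in_low=cfg.simulate.embed_dim,
                d_in_high=cfg.simulate.embed_dim, seed=seed)
            tcfg = transformer.TrainConfig(
                lr=tw.lr, weight_decay=tw.weight_decay,
                batch_size=tw.batch_size, max_epochs=tw.max_epochs,
                patience=tw.patience, warmup_epochs=tw.warmup_epochs,
                cosine_t_max=tw.cosine_t_max, n_folds=tw.n_folds, seed=seed)
            clf = transformer.CrossScaleTransformerClassifier(mcfg, tcfg)
            clf.fit(state["tokens"], cohort.slide_labels,
                    groups=[s.patient_id for s in cohort.slides])
            state["classifier"] = clf
            clf.save_checkpoint(out / "wise_checkpoint")
            scores_path = out / "slide_scores.csv"
            import pandas as pd
            probs = clf.predict_proba(state["tokens"])[:, 1]
            pd.DataFrame({
                "slide_id": [s.slide_id for s in cohort.slides],
                "patient_id": [s.patient_id for s in cohort.slides],
                "label": cohort.slide_labels,
                "score": probs,
            }).to_csv(scores_path, index=False)
            artifacts = [scores_path]
        elif stage == "evaluate":
            if "classifier" not in state:
                raise DependencyError("evaluate requires the train-wise stage")
            import pandas as pd
            scores = pd.read_csv(out / "slide_scores.csv")
            report = evaluation.auc_with_ci(
                scores["score"], scores["label"], n_boot=cfg.evaluate.n_boot,
                seed=seed, patient_ids=scores["patient_id"])
            report_path = out / "evaluation.json"
            report_path.write_text(json.dumps(dataclasses.asdict(report),
                                              indent=2))
            artifacts = [report_path]
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {p.name: _hash_file(p) for p in artifacts},
        }
        logger.info("stage %s done (seed %d)", stage, seed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
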