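"""Config-driven orchestration of the four pipeline variants.

* ``model1`` — CNN extractor, FC3 (max-merged FC1/FC2) features -> classifier
* ``model2`` — residual extractor, FC4 features -> classifier
* ``model3`` — CCA fusion of FC3 and FC4 -> classifier (no selection)
* ``model4`` — model3 + whale-optimization wrapper feature selection

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master_seed).spawn`` in a fixed stage order
(data, cnn, resnet, fusion, selection, evaluation), so any stage can be
reproduced in isolation. Every intermediate artifact is persisted under the
output directory along with a manifest echoing the config and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion as fusion_mod
from .evaluation import kfold_evaluate
from .extractors import (FeatureMatrix, TrainConfig, build_extractor,
                         extract_features, stack_features, train_extractor)
from .selection import FitnessSpec, OptimizerConfig, baseline_select, woa_select
from .synthetic import PhantomConfig, gen_volumes
from .volume_io import preprocess_volume, read_volume

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

MODELS = ("model1", "model2", "model3", "model4")
_STAGES = ("data", "cnn", "resnet", "fusion", "selection", "evaluation")


@dataclass
class PipelineConfig:
    model: str = "model4"
    # exactly one data source: phantom config dict, volume dir, or feature CSVs
    phantom: dict | None = None
    volume_dir: str | None = None
    label_manifest: str | None = None
    feature_csvs: tuple[str, str] | None = None
    input_shape: tuple[int, int, int] = (56, 56, 56)
    width_scale: float = 1.0
    fc_width: int = 1000
    cnn_train: dict = field(default_factory=dict)
    resnet_train: dict = field(default_factory=dict)
    fusion_lam: float = 1e-3
    fusion_d: int | None = None
    fusion_mode: str = "Z1_concat"
    optimizer: dict = field(default_factory=dict)
    fitness: dict = field(default_factory=dict)
    classifier: str = "gb"
    k_folds: int = 5
    out_dir: str = "volfuse_run"
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected {MODELS}")
        sources = [self.phantom is not None, self.volume_dir is not None,
                   self.feature_csvs is not None]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one data source (phantom | volume_dir | feature_csvs) "
                "must be configured")

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: int(c.generate_state(1)[0])
                for name, c in zip(_STAGES, children)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _save_features(fm: FeatureMatrix, y, path: Path) -> None:
    df = pd.DataFrame(fm.values,
                      columns=[f"f{i:04d}" for i in range(fm.n_features)])
    df.insert(0, "sample_id", fm.sample_ids)
    if y is not None:
        df.insert(1, "label", y)
    df.to_csv(path, index=False)


def load_feature_csv(path: str | Path) -> tuple[FeatureMatrix, np.ndarray | None]:
    df = pd.read_csv(path)
    ids = (df.pop("sample_id").astype(str).tolist()
           if "sample_id" in df else [str(i) for i in range(len(df))])
    y = df.pop("label").to_numpy() if "label" in df else None
    fm = FeatureMatrix(df.to_numpy(dtype=np.float64),
                       [("csv", c) for c in df.columns], ids)
    return fm, y


def _load_data(cfg: PipelineConfig, seeds: dict):
    """Returns (volumes or None, A, B, y); A/B set only for the CSV source."""
    if cfg.feature_csvs is not None:
        fa, ya = load_feature_csv(cfg.feature_csvs[0])
        fb, yb = load_feature_csv(cfg.feature_csvs[1])
        y = ya if ya is not None else yb
        if y is None:
            raise ValueError("feature CSVs must carry a 'label' column")
        return None, fa, fb, np.asarray(y)
    if cfg.phantom is not None:
        pcfg = PhantomConfig(**{"seed": seeds["data"], **cfg.phantom})
        volumes = gen_volumes(pcfg)
    else:
        vdir = Path(cfg.volume_dir)
        labels = {}
        if cfg.label_manifest:
            labels = {str(k): int(v) for k, v in
                      json.loads(Path(cfg.label_manifest).read_text()).items()}
        volumes = []
        for p in sorted(vdir.iterdir()):
            if p.name.startswith("."):
                continue
            label = labels.get(p.stem.replace(".nii", ""), labels.get(p.name))
            volumes.append(read_volume(p, label=label))
    volumes = [preprocess_volume(v, cfg.input_shape) for v in volumes]
    y = np.array([v.label for v in volumes])
    return volumes, None, None, y


def _train_and_tap(kind: str, tap: str, volumes, cfg: PipelineConfig,
                   train_overrides: dict, seed: int):
    spec = build_extractor(kind, cfg.input_shape, n_classes=3,
                           fc_width=cfg.fc_width, width_scale=cfg.width_scale,
                           seed=seed)
    tcfg = TrainConfig(**{"seed": seed, **train_overrides})
    spec, history = train_extractor(spec, volumes, tcfg)
    feats = extract_features(spec, volumes, tap)
    return spec, history, feats


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline variant; returns the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    report: dict = {"model": cfg.model, "seeds": seeds,
                    "config_hash": _config_hash(cfg), "artifacts": {}}
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("volfuse")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out, seeds, report)
    except Exception as exc:  # surface the failing stage by name
        stage = report.get("stage", "setup")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path, seeds: dict, report: dict) -> dict:
    t0 = time.time()
    report["stage"] = "data"
    volumes, fa, fb, y = _load_data(cfg, seeds)
    logger.info("stage=data n=%d", len(y))

    need_cnn = cfg.model in ("model1", "model3", "model4") and volumes is not None
    need_resnet = cfg.model in ("model2", "model3", "model4") and volumes is not None

    if need_cnn:
        report["stage"] = "cnn"
        _, hist, fa = _train_and_tap("cnn_variant3", "FC3", volumes, cfg,
                                     cfg.cnn_train, seeds["cnn"])
        pd.DataFrame({k: v for k, v in hist.items()
                      if isinstance(v, list)}).to_csv(
            out / "cnn_history.csv", index=False)
        _save_features(fa, y, out / "features_cnn_fc3.csv")
        report["artifacts"]["features_cnn_fc3"] = str(out / "features_cnn_fc3.csv")
        logger.info("stage=cnn epochs=%d", len(hist["epoch"]))
    if need_resnet:
        report["stage"] = "resnet"
        _, hist, fb = _train_and_tap("resnet15", "FC4", volumes, cfg,
                                     cfg.resnet_train, seeds["resnet"])
        pd.DataFrame({k: v for k, v in hist.items()
                      if isinstance(v, list)}).to_csv(
            out / "resnet_history.csv", index=False)
        _save_features(fb, y, out / "features_resnet_fc4.csv")
        report["artifacts"]["features_resnet_fc4"] = str(out / "features_resnet_fc4.csv")
        logger.info("stage=resnet epochs=%d", len(hist["epoch"]))

    if cfg.model == "model1":
        features = fa
    elif cfg.model == "model2":
        features = fb
    else:
        report["stage"] = "fusion"
        model = fusion_mod.fit_cca(fa, fb, lam=cfg.fusion_lam, d=cfg.fusion_d)
        fused = fusion_mod.fuse(model, fa, fb, mode=cfg.fusion_mode)
        model.save(out / "cca_model.zip")
        features = FeatureMatrix(
            fused.values,
            [("cca", cfg.fusion_mode)] * fused.values.shape[1],
            fa.sample_ids)
        _save_features(features, y, out / "features_fused.csv")
        report["artifacts"]["cca_model"] = str(out / "cca_model.zip")
        report["artifacts"]["features_fused"] = str(out / "features_fused.csv")
        report["fusion"] = {"d": model.d,
                            "correlations": model.correlations.tolist()}
        logger.info("stage=fusion d=%d", model.d)

    if cfg.model == "model4":
        report["stage"] = "selection"
        ocfg = OptimizerConfig(**{"seed": seeds["selection"], **cfg.optimizer})
        fspec = FitnessSpec(**{"split_seed": seeds["selection"], **cfg.fitness})
        if ocfg.algorithm == "woa":
            sel = woa_select(features, y, ocfg, fspec)
        else:
            sel = baseline_select(features, y, ocfg, fspec)
        (out / "selection.json").write_text(json.dumps(sel.to_dict(), indent=2))
        pd.DataFrame({"iteration": np.arange(len(sel.convergence)),
                      "best_fitness": sel.convergence}).to_csv(
            out / "selection_convergence.csv", index=False)
        report["artifacts"]["selection"] = str(out / "selection.json")
        report["selection"] = {"size": sel.selection_size,
                               "fitness": sel.fitness,
                               "convergence": sel.convergence.tolist()}
        keep = np.flatnonzero(sel.mask)
        features = FeatureMatrix(features.values[:, keep],
                                 [features.feature_provenance[i] for i in keep],
                                 features.sample_ids)
        logger.info("stage=selection size=%d", sel.selection_size)

    report["stage"] = "evaluation"
    eval_report = kfold_evaluate(features, y, classifier=cfg.classifier,
                                 k=cfg.k_folds, seed=seeds["evaluation"])
    eval_report.save(out / "evaluation.json")
    report["artifacts"]["evaluation"] = str(out / "evaluation.json")
    report["evaluation"] = eval_report.to_dict()
    report["elapsed_s"] = time.time() - t0
    del report["stage"]

    manifest = {"config": cfg.to_dict(), **report}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    report["artifacts"]["manifest"] = str(out / "manifest.json")
    return report
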