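"""End-to-end pipeline: simulate → train → predict → evaluate.

Every stage reads and writes files under one output directory so a run is
reproducible from its config and seed; ``run_pipeline`` executes the
stages in order and fails with a clear message when an upstream artifact
is missing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as ctio
from .evaluation import (compare_strategies, confusion_matrix,
                         confusion_from_predictions, metrics_from_counts)
from .network import ExtractorConfig, PhaseNet
from .phantom import EnhancementProfile, PhantomSpec, simulate_dataset
from .preprocess import WindowConfig, preprocess_exam
from .strategies import (calibrate_order, predict_one_step, predict_two_step)
from .training import TrainConfig, arterial_subset, train_model

STAGE_ARTIFACTS = {
    "simulate": "manifest.csv",
    "train": "model3.npz",
    "predict": "predictions.csv",
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (desk preset by default)."""

    out_dir: str = "ctphase-run"
    n_exams: int = 40
    grid: int = 32
    noise_sd: float = 5.0
    edge_case_fraction: float = 0.0
    seed: int = 0
    strategy: str = "two_step"
    calibrate: bool = True
    window_level: float = 50.0
    window_width: float = 600.0
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=12))

    def window(self) -> WindowConfig:
        return WindowConfig(self.window_level, self.window_width)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{stage}' stage first"
        )
    return path


def stage_simulate(cfg: RunConfig) -> Path:
    spec = PhantomSpec(shape=(cfg.grid,) * 3, seed=cfg.seed)
    profile = EnhancementProfile(noise_sd=cfg.noise_sd)
    exams = simulate_dataset(cfg.n_exams, spec, profile, seed=cfg.seed,
                             edge_case_fraction=cfg.edge_case_fraction)
    return ctio.save_exams(exams, cfg.out_dir)


def _load_preprocessed(cfg: RunConfig):
    manifest = _require(Path(cfg.out_dir) / "manifest.csv", "simulate")
    exams = ctio.read_manifest(manifest)
    shape = (cfg.grid,) * 3
    return [preprocess_exam(e, shape, cfg.window()) for e in exams]


def stage_train(cfg: RunConfig, classes: int, seed_offset: int = 0) -> Path:
    exams = _load_preprocessed(cfg)
    if classes == 2:
        exams = arterial_subset(exams)
    net = PhaseNet(ExtractorConfig.desk((cfg.grid,) * 3), n_classes=classes,
                   seed=cfg.seed + seed_offset)
    tcfg = TrainConfig(**{**asdict(cfg.train), "seed": cfg.seed + seed_offset})
    result = train_model(exams, net, tcfg)
    out = Path(cfg.out_dir) / f"model{classes}.npz"
    net.save(out)
    result.history.to_csv(Path(cfg.out_dir) / f"history{classes}.csv", index=False)
    return out


def stage_predict(cfg: RunConfig) -> Path:
    out_dir = Path(cfg.out_dir)
    exams = _load_preprocessed(cfg)
    if cfg.strategy == "two_step":
        model3 = PhaseNet.load(_require(out_dir / "model3.npz", "train --classes 3"))
        model2 = PhaseNet.load(_require(out_dir / "model2.npz", "train --classes 2"))
        preds = [predict_two_step(e, model3, model2) for e in exams]
    else:
        model4 = PhaseNet.load(_require(out_dir / "model4.npz", "train --classes 4"))
        preds = [predict_one_step(e, model4) for e in exams]
    if cfg.calibrate:
        preds = [calibrate_order(p, order_known=e.order_known)
                 for p, e in zip(preds, exams)]
    path = out_dir / "predictions.csv"
    ctio.write_predictions(preds, path)
    return path


def stage_evaluate(cfg: RunConfig) -> Path:
    import pandas as pd

    out_dir = Path(cfg.out_dir)
    pred_path = _require(out_dir / "predictions.csv", "predict")
    df = pd.read_csv(pred_path)
    if df["true_phase"].isna().any():
        raise ValueError("cannot evaluate: missing true phases")
    labels = df["label_raw"].tolist()
    truths = df["true_phase"].tolist()
    report = metrics_from_counts(confusion_from_predictions(labels, truths))
    cm = confusion_matrix(labels, truths)
    (out_dir / "confusion.txt").write_text(cm.to_string() + "\n")
    report.to_frame().to_csv(out_dir / "metrics.csv")
    payload = {
        "overall_accuracy_pct": report.overall_accuracy,
        "overall_fraction": list(report.overall_fraction),
        "ci_method": report.ci_method,
        "strategy": cfg.strategy,
        "seed": cfg.seed,
    }
    path = out_dir / "metrics.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Run simulate → train(3,2 or 4) → predict → evaluate; returns metrics path."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(
        json.dumps({**asdict(cfg)}, indent=2, default=str) + "\n"
    )
    stage_simulate(cfg)
    if cfg.strategy == "two_step":
        stage_train(cfg, 3)
        stage_train(cfg, 2, seed_offset=1)
    else:
        stage_train(cfg, 4)
    stage_predict(cfg)
    return stage_evaluate(cfg)
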