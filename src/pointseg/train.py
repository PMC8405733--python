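"""Training and evaluation orchestration.

Five method modes share one loop, selected purely by config:

* ``a_lcfcn`` — affinity refinement on, four-term LCFCN loss (the method);
* ``lcfcn``   — identical but with the affinity branch bypassed (ablation);
* ``pl_fcn``  — point-level cross-entropy baseline;
* ``fs_fcn``  — fully supervised student architecture on true masks;
* ``a_lcfcn_pm`` — train a_lcfcn, distill pseudo masks, train the student.

Protocol: batch size 1 with ADAM; for each learning rate in the sweep, train
with early stopping on the validation metric (patience in epochs), keep the
best-epoch parameters, and return the checkpoint of the learning rate with
the best validation score.  The validation metric defaults to mIoU when the
validation split carries masks and to GAME(4) otherwise (lower is better).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .data_model import DatasetManifest, Scene
from .distill import StudentModel, generate_pseudo_masks, student_loss
from .losses import lcfcn_loss, point_level_loss, PROB_FLOOR
from .metrics import MetricReport, evaluate_set
from .network import ModelConfig, ProbMap, SegModel

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "evaluate",
    "baseline_pl_fcn_loss",
    "train_student",
    "run_method",
]

METHODS = ("a_lcfcn", "lcfcn", "pl_fcn", "fs_fcn", "a_lcfcn_pm")


@dataclass
class TrainConfig:
    learning_rates: tuple[float, ...] = (1e-4, 1e-5, 1e-6)
    batch_size: int = 1
    max_epochs: int = 100
    patience: int = 10
    optimizer: str = "adam"
    seed: int = 0
    val_metric: str | None = None  # miou | game | mae | None (auto)
    method: str = "a_lcfcn"

    def __post_init__(self) -> None:
        if not self.learning_rates:
            raise ValueError("learning_rates must be non-empty")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.method not in METHODS:
            raise ValueError(f"unknown method '{self.method}'")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the ADAM optimizer is supported")


@dataclass
class TrainResult:
    model: object  # SegModel or StudentModel
    best_lr: float
    best_epoch: int
    best_val: float
    log: list[dict] = field(default_factory=list)


def baseline_pl_fcn_loss(probs: ProbMap, points: list[tuple[int, int]]) -> Tensor:
    """Point-level cross-entropy; mean background CE on empty images."""
    if points:
        return point_level_loss(probs, points)
    return -(probs.background.clamp_min(PROB_FLOOR).log()).mean()


def _loss_for(method: str, probs: ProbMap, scene: Scene):
    if method in ("a_lcfcn", "lcfcn"):
        report = lcfcn_loss(probs, scene.points)
        return report.total, report.as_dict()
    if method == "pl_fcn":
        loss = baseline_pl_fcn_loss(probs, scene.points)
        return loss, {"total": float(loss.data)}
    if method == "fs_fcn":
        if scene.mask is None:
            raise ValueError(f"scene {scene.id}: fs_fcn needs a ground-truth mask")
        loss = student_loss(probs, scene.mask)
        return loss, {"total": float(loss.data)}
    raise ValueError(method)


def _build(method: str, model_config: ModelConfig, seed: int):
    if method == "fs_fcn":
        return StudentModel(model_config, seed=seed)
    from dataclasses import replace

    cfg = replace(model_config, affinity_enabled=(method == "a_lcfcn"))
    return SegModel(cfg, seed=seed)


def _val_score(model, scenes: list[Scene], metric: str) -> tuple[float, bool]:
    """Return (score, higher_is_better)."""
    report = _evaluate_model(model, scenes)
    if metric == "miou":
        return report.miou, True
    if metric == "mae":
        return report.mae, False
    if metric == "game":
        return report.game[4], False
    raise ValueError(f"unknown validation metric '{metric}'")


def _evaluate_model(model, scenes: list[Scene],
                    game_levels=(0, 1, 2, 4)) -> MetricReport:
    preds = [model.predict_mask(s.image) for s in scenes]
    masks = [s.mask for s in scenes]
    true_masks = masks if all(m is not None for m in masks) and masks else None
    points = [s.points for s in scenes]
    return evaluate_set(preds, true_masks, points, game_levels)


def train(manifest: DatasetManifest, config: TrainConfig,
          model_config: ModelConfig | None = None,
          train_scenes: list[Scene] | None = None) -> TrainResult:
    """Early-stopped ADAM training with a learning-rate sweep."""
    model_config = model_config or ModelConfig()
    train_split = train_scenes if train_scenes is not None else manifest.split("train")
    val_split = manifest.split("val")
    if not train_split or not val_split:
        raise ValueError("train and val splits must be non-empty")

    metric = config.val_metric
    if metric is None:
        metric = "miou" if all(s.mask is not None for s in val_split) else "game"

    best: TrainResult | None = None
    log: list[dict] = []
    for lr in config.learning_rates:
        model = _build(config.method, model_config, config.seed)
        opt = Adam(model.parameters(), lr=lr)
        rng = np.random.default_rng(config.seed)
        best_val, best_state, best_epoch = None, None, -1
        stale = 0
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(train_split))
            epoch_losses: list[dict] = []
            for i in order:
                scene = train_split[i]
                probs = model.forward(scene.image)
                if hasattr(probs, "probs"):  # SegModel returns a ForwardResult
                    probs = probs.probs
                loss, parts = _loss_for(config.method, probs, scene)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, scene {scene.id}: "
                        f"{parts}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(parts)
            score, higher = _val_score(model, val_split, metric)
            mean_loss = {
                k: float(np.mean([p.get(k, 0.0) for p in epoch_losses]))
                for k in epoch_losses[0]
            }
            log.append({"lr": lr, "epoch": epoch, "val_" + metric: score,
                        **{"loss_" + k: v for k, v in mean_loss.items()}})
            improved = (
                best_val is None
                or (score > best_val if higher else score < best_val)
            )
            if improved:
                best_val, best_epoch = score, epoch
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        model.load_state_dict(best_state)
        better_lr = (
            best is None
            or (best_val > best.best_val if higher else best_val < best.best_val)
        )
        if better_lr:
            best = TrainResult(model, lr, best_epoch, best_val)
    best.log = log
    return best


def evaluate(model, manifest: DatasetManifest, split: str = "test",
             report_path: str | Path | None = None) -> MetricReport:
    """Argmax predictions on a split, pooled metric report, optional JSON."""
    scenes = manifest.split(split)
    report = _evaluate_model(model, scenes)
    if report_path is not None:
        path = Path(report_path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(report.as_dict(), indent=2))
    return report


def train_student(pseudo_masks, scenes: list[Scene], config: TrainConfig,
                  manifest: DatasetManifest,
                  model_config: ModelConfig | None = None) -> TrainResult:
    """Train the fully supervised student against pseudo ground truth."""
    if not scenes:
        raise ValueError("student training requires a non-empty train set")
    by_id = {pm.source_id: pm.mask for pm in pseudo_masks}
    with warnings.catch_warnings():
        # clicks may fall off an imperfect pseudo mask; that is expected here
        warnings.simplefilter("ignore")
        distill_scenes = [
            Scene(s.id, s.image, s.points, by_id[s.id], s.split)
            for s in scenes
            if s.id in by_id
        ]
    if len(distill_scenes) != len(scenes):
        raise ValueError("pseudo masks must cover the train split")
    student_cfg = TrainConfig(
        learning_rates=config.learning_rates, max_epochs=config.max_epochs,
        patience=config.patience, seed=config.seed,
        val_metric=config.val_metric, method="fs_fcn",
    )
    return train(manifest, student_cfg, model_config,
                 train_scenes=distill_scenes)


def run_method(manifest: DatasetManifest, config: TrainConfig,
               model_config: ModelConfig | None = None) -> TrainResult:
    """Dispatch a full experiment for any of the five method modes."""
    model_config = model_config or ModelConfig()
    if config.method != "a_lcfcn_pm":
        return train(manifest, config, model_config)
    from dataclasses import replace

    teacher_cfg = replace(config, method="a_lcfcn")
    teacher = train(manifest, teacher_cfg, model_config)
    pseudo = generate_pseudo_masks(teacher.model, manifest.split("train"))
    result = train_student(pseudo, manifest.split("train"), config,
                           manifest, model_config)
    result.log = teacher.log + result.log
    return result
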