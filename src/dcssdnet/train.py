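"""Training loop, learning-rate schedule, and checkpointing.

The published recipe: Adam (0.9, 0.999, 1e-8), initial learning rate
1e-4, batch size 32, 100 epochs of 500 steps, and a piecewise schedule —
1e-4 below epoch 80, 1e-5 below epoch 100, 1e-6 afterwards.  A
step-decay alternative (halving every 10 epochs) is retained as an
option.  All of this scales down: the smoke-scale configurations used in
the tests shrink the input size, batch, and step counts but change no
rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .backbone import ArchConfig
from .boxes import match_targets
from .data import AnnotatedFrame, load_frame, read_manifest
from .evaluation import evaluate_detections
from .loss import LossBreakdown, LossConfig, multibox_loss
from .nn import Adam
from .pyramid import DCSSDNet

__all__ = ["TrainConfig", "TrainLog", "lr_at_epoch", "train_model",
           "normalize_images", "prepare_frame", "save_checkpoint",
           "load_checkpoint"]

# fixed input normalization: [0,1] scaling then (x - 0.5) / 0.25
_NORM_MEAN = 0.5
_NORM_STD = 0.25


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    initial_lr: float = 1e-4
    schedule: str = "piecewise"  # or "step_decay"
    step_drop: float = 0.5
    epoch_drop: int = 10
    batch_size: int = 32
    epochs: int = 100
    steps_per_epoch: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.schedule not in ("piecewise", "step_decay"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class TrainLog:
    step_losses: list[LossBreakdown] = field(default_factory=list)
    val_map: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    checkpoint_path: str | None = None
    best_val_map: float = 0.0


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a (0-based) epoch index.

    piecewise: 1e-4 below epoch 80, 1e-5 below 100, 1e-6 otherwise.
    step_decay: initial_lr * step_drop ** floor(epoch / epoch_drop).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if cfg.schedule == "piecewise":
        if epoch < 80:
            return 1e-4
        if epoch < 100:
            return 1e-5
        return 1e-6
    return cfg.initial_lr * cfg.step_drop ** (epoch // cfg.epoch_drop)


def normalize_images(images: np.ndarray) -> np.ndarray:
    """uint8 frames -> standardized float input."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    return (x - _NORM_MEAN) / _NORM_STD


def prepare_frame(frame: AnnotatedFrame, input_size: int) -> AnnotatedFrame:
    """Resize a frame (and its boxes) to the network input size."""
    h, w = frame.image.shape[:2]
    if (h, w) == (input_size, input_size):
        return frame
    img = np.asarray(Image.fromarray(frame.image).resize(
        (input_size, input_size), Image.BILINEAR))
    boxes = frame.boxes.copy()
    if len(boxes):
        boxes[:, [0, 2]] *= input_size / w
        boxes[:, [1, 3]] *= input_size / h
    return AnnotatedFrame(img, boxes, list(frame.labels), frame.source_id)


def _resolve_dataset(dataset, input_size: int) -> list[AnnotatedFrame]:
    if isinstance(dataset, (str, Path)):
        rows = read_manifest(dataset)
        frames = [load_frame(r["image"], r["annotation"]) for r in rows]
    else:
        frames = list(dataset)
    if not frames:
        raise ValueError("empty training split")
    return [prepare_frame(f, input_size) for f in frames]


def train_model(arch: ArchConfig, train_cfg: TrainConfig, dataset,
                loss_cfg: LossConfig = LossConfig(),
                val_dataset=None, out_dir: str | Path | None = None,
                match_threshold: float = 0.5,
                ) -> tuple[DCSSDNet, TrainLog]:
    """Train a detector from scratch on an annotated dataset.

    ``dataset`` is a manifest CSV path or a list of
    :class:`AnnotatedFrame`.  Ground truths are matched to default boxes
    once up front; each step samples a batch, runs forward/backward, and
    takes an Adam step at the scheduled learning rate.  Validation mAP
    is computed after every epoch (on ``val_dataset`` or, failing that,
    the training frames) and the best-mAP weights are checkpointed.
    """
    size = arch.input_size
    frames = _resolve_dataset(dataset, size)
    val_frames = (_resolve_dataset(val_dataset, size)
                  if val_dataset is not None else frames)

    model = DCSSDNet(arch)
    matches = []
    for f in frames:
        gt = f.boxes / size  # normalized corners
        matches.append(match_targets(gt, model.default_boxes, match_threshold))
    images = normalize_images(np.stack([f.image for f in frames]))

    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(model.params(), lr=train_cfg.initial_lr,
                     beta1=train_cfg.beta1, beta2=train_cfg.beta2,
                     epsilon=train_cfg.epsilon)
    log = TrainLog()
    best_state = None
    for epoch in range(train_cfg.epochs):
        lr = lr_at_epoch(epoch, train_cfg)
        optimizer.lr = lr
        log.lr_trace.append(lr)
        for _ in range(train_cfg.steps_per_epoch):
            idx = rng.choice(len(frames),
                             size=min(train_cfg.batch_size, len(frames)),
                             replace=len(frames) < train_cfg.batch_size)
            batch_raw = model.forward(images[idx], train=True)
            breakdown, dloc, dconf = multibox_loss(
                batch_raw, [matches[i] for i in idx], loss_cfg,
                return_grads=True)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {breakdown}")
            optimizer.zero_grad()
            model.backward(dloc, dconf)
            optimizer.step()
            log.step_losses.append(breakdown)
        val_map = _validate(model, val_frames)
        log.val_map.append(val_map)
        if val_map >= log.best_val_map:
            log.best_val_map = val_map
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None and log.best_val_map > 0:
        model.load_state_dict(best_state)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt = out / "checkpoint.npz"
        save_checkpoint(model, ckpt)
        log.checkpoint_path = str(ckpt)
        with open(out / "train_log.jsonl", "w") as fh:
            for epoch, (vm, lr) in enumerate(zip(log.val_map, log.lr_trace)):
                fh.write(json.dumps({"epoch": epoch, "lr": lr,
                                     "val_map": vm}) + "\n")
    return model, log


def _validate(model: DCSSDNet, frames: list[AnnotatedFrame],
              score_threshold: float = 0.05) -> float:
    size = model.arch.input_size
    dets = model.predict(normalize_images(np.stack([f.image for f in frames])),
                         score_threshold=score_threshold)
    gts = [f.boxes / size for f in frames]
    return evaluate_detections(dets, gts).map


def save_checkpoint(model: DCSSDNet, path: str | Path) -> None:
    arch_json = json.dumps(asdict(model.arch))
    np.savez(path, __arch__=np.frombuffer(arch_json.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> DCSSDNet:
    with np.load(path) as data:
        arch_dict = json.loads(bytes(data["__arch__"]).decode())
        arch_dict["base_block_counts"] = tuple(arch_dict["base_block_counts"])
        model = DCSSDNet(ArchConfig(**arch_dict))
        state = {k: data[k] for k in data.files if k != "__arch__"}
    model.load_state_dict(state)
    return model
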