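"""Task training loops and the two-stage multitask inheritance scheme.

Both tasks share one architecture and one optimizer recipe: AdamW with
decoupled weight decay under a cosine-decay learning-rate schedule, MAE
loss for denoising and cross-entropy for segmentation.  The full-scale
recipe (lr 1e-4, batch 64, 300 epochs) is the documented default; tests
use desk-scale overrides.

Multitask inheritance runs two stages: stage one trains each task from
scratch; stage two re-trains each task with its encoder initialized from
the *other* task's stage-one encoder (then fine-tuned, not frozen), while
decoder and head start fresh.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import AdamW, Tensor, cosine_lr, cross_entropy_loss, mae_loss
from .ebtnet import ConfigError, EBTNet, ModelConfig
from .metrics import pointwise_prf, snr_imp

_TASK_LOSS = {"denoise": "mae", "segment": "cross_entropy"}


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    epochs: int = 300
    loss: str = "mae"
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")
        if self.epochs < 1:
            raise ConfigError("need at least one epoch")
        if self.loss not in ("mae", "cross_entropy"):
            raise ConfigError(f"unknown loss {self.loss!r}")


@dataclass
class TrainedModel:
    model: EBTNet
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    stage: str = "scratch"

    @property
    def best_val_loss(self) -> float:
        return min(h["val_loss"] for h in self.history)

    @property
    def best_val_metric(self) -> float:
        # metric is better-is-larger for both tasks (SNR_imp dB / CQRS F1 %)
        idx = int(np.argmin([h["val_loss"] for h in self.history]))
        return self.history[idx]["val_metric"]


def _val_metric(model: EBTNet, X: np.ndarray, Y: np.ndarray) -> float:
    pred = model.predict(X)
    if model.config.task == "denoise":
        if not np.all(np.isfinite(pred)):
            return float("-inf")
        try:
            imps = [snr_imp(y, x, p)[2] for x, y, p in zip(X, Y, pred)]
        except (ValueError, OverflowError):   # overflowing residual energy
            return float("-inf")
        return float(np.mean(imps))
    return pointwise_prf(pred.ravel(), Y.ravel())["CQRS"].f1


def _loss(model: EBTNet, xb: np.ndarray, yb: np.ndarray) -> Tensor:
    out = model.forward(xb)
    if model.config.task == "denoise":
        return mae_loss(out, yb)
    return cross_entropy_loss(out, yb)


def encoder_hash(state: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(state):
        h.update(key.encode())
        h.update(np.ascontiguousarray(state[key]).tobytes())
    return h.hexdigest()


def train_task(
    task: str,
    datasets: dict[str, tuple[np.ndarray, np.ndarray]],
    train_config: TrainConfig,
    model_config: ModelConfig,
    encoder_init: dict[str, np.ndarray] | None = None,
) -> TrainedModel:
    """Train one task; returns the best-validation-loss checkpoint.

    ``datasets`` maps "train"/"val" to (input, target) arrays: (noisy,
    clean) signal pairs for denoising, (signal, integer mask) pairs for
    segmentation.  ``encoder_init`` copies encoder parameters from a donor
    before training (they remain trainable); decoder and head are always
    freshly initialized.  Deterministic for a fixed seed.
    """
    if task not in _TASK_LOSS:
        raise ConfigError(f"unknown task {task!r}")
    if train_config.loss != _TASK_LOSS[task]:
        raise ConfigError(
            f"loss {train_config.loss!r} does not match task {task!r} "
            f"(expected {_TASK_LOSS[task]!r})")
    if model_config.task != task:
        model_config = replace(model_config, task=task)

    rng = np.random.default_rng(train_config.seed)
    model = EBTNet(model_config, seed=train_config.seed)
    stage = "scratch"
    if encoder_init is not None:
        model.load_encoder(encoder_init)
        stage = "inherited"

    X_train, Y_train = datasets["train"]
    X_val, Y_val = datasets["val"]
    params = model.parameters()
    opt = AdamW(params, lr=train_config.lr,
                weight_decay=train_config.weight_decay)

    history: list[dict] = []
    best_loss = np.inf
    best_state = model.state_dict()
    n = X_train.shape[0]
    for epoch in range(train_config.epochs):
        opt.lr = cosine_lr(train_config.lr, epoch, train_config.epochs)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            loss = _loss(model, X_train[idx], Y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(task={task}, lr={opt.lr:.2e}); aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = float(_loss(model, X_val, Y_val).data)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        record = {
            "epoch": epoch,
            "lr": float(opt.lr),
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_metric": _val_metric(model, X_val, Y_val),
        }
        history.append(record)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainedModel(model=model, train_config=train_config,
                        history=history, stage=stage)


def multitask_inheritance(
    datasets_denoise: dict[str, tuple[np.ndarray, np.ndarray]],
    datasets_segment: dict[str, tuple[np.ndarray, np.ndarray]],
    train_config: TrainConfig,
    model_config: ModelConfig,
) -> dict[str, dict[str, TrainedModel]]:
    """Two-stage cross-task encoder inheritance.

    Stage 1 trains denoise and segment from scratch.  Stage 2 re-trains
    denoise with the stage-1 *segment* encoder as initialization and
    segment with the stage-1 *denoise* encoder.  Returns
    ``{"stage1": {task: TrainedModel}, "stage2": {...}}``.
    """
    cfg_d = replace(train_config, loss="mae")
    cfg_s = replace(train_config, loss="cross_entropy")
    stage1 = {
        "denoise": train_task("denoise", datasets_denoise, cfg_d, model_config),
        "segment": train_task("segment", datasets_segment, cfg_s, model_config),
    }
    stage2 = {
        "denoise": train_task(
            "denoise", datasets_denoise, cfg_d, model_config,
            encoder_init=stage1["segment"].model.encoder_state_dict()),
        "segment": train_task(
            "segment", datasets_segment, cfg_s, model_config,
            encoder_init=stage1["denoise"].model.encoder_state_dict()),
    }
    return {"stage1": stage1, "stage2": stage2}


def history_to_csv(history: list[dict], path) -> None:
    """Write per-epoch training history as a flat CSV file."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "lr", "train_loss", "val_loss", "val_metric"])
        writer.writeheader()
        writer.writerows(history)
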